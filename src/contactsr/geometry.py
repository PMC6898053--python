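"""Superposition-based model assessment: Kabsch RMSD, TM-score, chirality.

Model and native are the same chain at the same length, so residue
correspondence is by index and no alignment search is needed.  Distance
geometry cannot fix handedness from distance information alone, so every
embedded model is also scored as its point reflection and the better
enantiomer is reported (:func:`score_with_mirror`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ParameterError
from .model import CaTrace

__all__ = [
    "SuperpositionScore",
    "kabsch_rmsd",
    "tm_score",
    "tm_d0",
    "score_with_mirror",
    "RMSD_SUCCESS_THRESHOLD",
    "TM_SUCCESS_THRESHOLD",
]

# a reconstruction "resembles the native fold" below/above these
RMSD_SUCCESS_THRESHOLD = 4.0  # Å
TM_SUCCESS_THRESHOLD = 0.5


@dataclass(frozen=True)
class SuperpositionScore:
    """Outcome of scoring a model against the native structure."""

    rmsd: float
    tm_score: float
    mirrored: bool


def _as_coords(x) -> np.ndarray:
    coords = x.coords if isinstance(x, CaTrace) else np.asarray(x, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ParameterError(f"expected (L, 3) coordinates, got shape {coords.shape}")
    return coords


def _check_lengths(model: np.ndarray, native: np.ndarray) -> None:
    if model.shape[0] != native.shape[0]:
        raise ParameterError(
            f"length mismatch: model {model.shape[0]} vs native {native.shape[0]}"
        )


def _kabsch(model: np.ndarray, native: np.ndarray):
    """Optimal proper rotation: returns (rotated centered model, centered native)."""
    mc = model - model.mean(axis=0)
    nc = native - native.mean(axis=0)
    rotation, _ = Rotation.align_vectors(nc, mc)
    return rotation.apply(mc), nc


def kabsch_rmsd(model, native) -> float:
    """Minimal RMSD over proper rotations and translations (no reflection)."""
    model, native = _as_coords(model), _as_coords(native)
    _check_lengths(model, native)
    rotated, nc = _kabsch(model, native)
    return float(np.sqrt(np.mean(np.sum((rotated - nc) ** 2, axis=1))))


def tm_d0(length: int) -> float:
    """Length-dependent TM-score normalisation d0 = 1.24·(L−15)^⅓ − 1.8."""
    if length < 16:
        raise ParameterError(f"TM-score d0 undefined for length {length} < 16")
    return 1.24 * (length - 15) ** (1.0 / 3.0) - 1.8


def tm_score(model, native) -> float:
    """Length-normalised structural similarity in (0, 1].

    TM = max over superpositions of (1/L)·Σᵢ 1/(1 + (dᵢ/d0)²).  The maximum
    is approximated by the Kabsch superposition followed by iterative-cutoff
    refinement: repeatedly re-superimpose on the residues currently within a
    distance cutoff and keep the best score seen.  For same-length models
    this matches the exhaustive search closely; it is an approximation, not
    the published dynamic-programming search over alignments.
    """
    model, native = _as_coords(model), _as_coords(native)
    _check_lengths(model, native)
    L = model.shape[0]
    d0 = tm_d0(L)

    def _score_for(subset: np.ndarray) -> tuple[float, np.ndarray]:
        mc = model - model[subset].mean(axis=0)
        nc = native - native[subset].mean(axis=0)
        rotation, _ = Rotation.align_vectors(nc[subset], mc[subset])
        d = np.linalg.norm(rotation.apply(mc) - nc, axis=1)
        return float(np.mean(1.0 / (1.0 + (d / d0) ** 2))), d

    best, d = _score_for(np.arange(L))
    for cutoff in (d0 + 4.0, d0 + 2.0, max(d0, 3.0)):
        subset = np.flatnonzero(d < cutoff)
        for _ in range(20):
            if subset.size < 4:
                break
            score, d_new = _score_for(subset)
            best = max(best, score)
            new_subset = np.flatnonzero(d_new < cutoff)
            if new_subset.size < 4 or np.array_equal(new_subset, subset):
                break
            subset, d = new_subset, d_new
    return best


def score_with_mirror(model, native) -> SuperpositionScore:
    """Score a model and its point reflection; report the better enantiomer.

    The TM-score is evaluated for the chosen enantiomer only; for chains
    shorter than 16 residues (where d0 is undefined) it is NaN.
    """
    model, native = _as_coords(model), _as_coords(native)
    _check_lengths(model, native)
    rmsd_direct = kabsch_rmsd(model, native)
    rmsd_mirror = kabsch_rmsd(-model, native)
    mirrored = rmsd_mirror < rmsd_direct
    chosen = -model if mirrored else model
    rmsd = rmsd_mirror if mirrored else rmsd_direct
    tm = tm_score(chosen, native) if model.shape[0] >= 16 else float("nan")
    return SuperpositionScore(rmsd=rmsd, tm_score=tm, mirrored=mirrored)
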