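"""Contact-guided Cα reconstruction by distance geometry.

The engine follows the classical metric-matrix (EMBED-style) pipeline:

1. **Bound compilation** — the contact map, chain connectivity and optional
   helix annotation are translated into per-pair distance bounds.
2. **Triangle smoothing** — upper bounds are tightened to all-pairs shortest
   paths; lower bounds are raised by the inverse triangle inequality.
3. **Metrization + embedding** — a trial distance matrix is sampled
   uniformly within the bounds and embedded into 3-D via the top three
   eigenpairs of the double-centered Gram matrix (classical MDS).
4. **Refinement** — coordinates are relaxed by quasi-Newton minimisation of
   the squared bound-violation energy.

Several independent candidates are generated per reconstruction; the
``top_k`` lowest-energy models form the reported ensemble.  Distances carry
no handedness, so models are mirror-resolved against the native structure
when one is provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .config import DistillerConfig
from .contacts import ContactMap
from .errors import InfeasibleBoundsError, NumericalError, ParameterError
from .geometry import SuperpositionScore, score_with_mirror
from .model import CaTrace

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceBounds",
    "SseAnnotation",
    "ReconstructionResult",
    "compile_bounds",
    "smooth_bounds",
    "embed",
    "refine",
    "reconstruct",
]

# virtual Cα–Cα bond and geometric constants of the restraint set (Å)
SEQ_LOWER, SEQ_UPPER = 3.7, 3.9
SEQ2_LOWER, SEQ2_UPPER = 5.0, 7.3
CONTACT_LOWER = 3.8
GENERIC_LOWER = 4.0
HELIX_I3 = (4.5, 5.5)
HELIX_I4 = (5.5, 6.5)
DMAX_PER_RESIDUE = 3.9  # chain-length bound: D_max = 3.9 · L


class SseAnnotation:
    """Per-residue secondary-structure classes in {H, E, C}.

    Only helices (H) generate distance bounds: runs of H add the canonical
    (i, i+3) and (i, i+4) Cα distances.  Strand partners cannot be inferred
    from a per-residue string, so E adds no bounds.
    """

    ALPHABET = frozenset("HEC")

    def __init__(self, classes: str):
        classes = classes.strip().upper()
        bad = set(classes) - self.ALPHABET
        if bad:
            raise ParameterError(f"invalid SSE classes {sorted(bad)}; allowed: H, E, C")
        self.classes = classes

    def __len__(self) -> int:
        return len(self.classes)

    def __eq__(self, other) -> bool:
        return isinstance(other, SseAnnotation) and self.classes == other.classes

    @classmethod
    def from_file(cls, path) -> "SseAnnotation":
        with open(path) as fh:
            return cls("".join(fh.read().split()))

    def helix_windows(self, width: int):
        """Start indices i such that residues i .. i+width are all H."""
        for i in range(len(self.classes) - width):
            if all(c == "H" for c in self.classes[i : i + width + 1]):
                yield i


@dataclass
class DistanceBounds:
    """Symmetric per-pair lower/upper distance bounds (Å), zero diagonal."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        L = self.lower.shape[0]
        if self.lower.shape != (L, L) or self.upper.shape != (L, L):
            raise ParameterError("bounds must be square matrices of equal shape")
        if not (np.allclose(self.lower, self.lower.T) and np.allclose(self.upper, self.upper.T)):
            raise ParameterError("bounds must be symmetric")
        if not (np.allclose(np.diag(self.lower), 0) and np.allclose(np.diag(self.upper), 0)):
            raise ParameterError("bound diagonals must be zero")
        if np.any(self.lower > self.upper + 1e-9):
            raise InfeasibleBoundsError("lower bound exceeds upper bound")

    @property
    def length(self) -> int:
        return self.lower.shape[0]

    def copy(self) -> "DistanceBounds":
        return DistanceBounds(self.lower.copy(), self.upper.copy())


def _set_pair(lower, upper, i, j, lo, hi):
    lower[i, j] = lower[j, i] = lo
    upper[i, j] = upper[j, i] = hi


def compile_bounds(
    length: int,
    cmap: ContactMap,
    sse: SseAnnotation | None = None,
    cutoff: float = 8.0,
) -> DistanceBounds:
    """Translate a contact map (and optional helix annotation) into smoothed
    distance bounds.

    Restraints, in increasing priority: every pair starts at
    [4.0, 3.9·L] (excluded volume / chain-length bound); helical (i, i+3)
    and (i, i+4) pairs get the canonical α-helix windows; contact pairs get
    [3.8, cutoff]; sequential (i, i+1) and next-nearest (i, i+2) pairs get
    the virtual-bond geometry.  The result is triangle-smoothed.
    """
    if cmap.length != length:
        raise ParameterError(
            f"contact map length {cmap.length} does not match {length}"
        )
    if sse is not None and len(sse) != length:
        raise ParameterError(
            f"SSE annotation length {len(sse)} does not match chain length {length}"
        )
    d_max = DMAX_PER_RESIDUE * length
    lower = np.full((length, length), GENERIC_LOWER)
    upper = np.full((length, length), d_max)
    np.fill_diagonal(lower, 0.0)
    np.fill_diagonal(upper, 0.0)

    if sse is not None:
        for i in sse.helix_windows(3):
            _set_pair(lower, upper, i, i + 3, *HELIX_I3)
        for i in sse.helix_windows(4):
            _set_pair(lower, upper, i, i + 4, *HELIX_I4)
    for c in cmap:
        _set_pair(lower, upper, c.i, c.j, CONTACT_LOWER, cutoff)
    for i in range(length - 2):
        _set_pair(lower, upper, i, i + 2, SEQ2_LOWER, SEQ2_UPPER)
    for i in range(length - 1):
        _set_pair(lower, upper, i, i + 1, SEQ_LOWER, SEQ_UPPER)

    return smooth_bounds(DistanceBounds(lower, upper))


def smooth_bounds(bounds: DistanceBounds) -> DistanceBounds:
    """Triangle smoothing of distance bounds (Floyd–Warshall order).

    Uppers become all-pairs shortest paths (u_ij ≤ u_ik + u_kj); lowers are
    raised by the inverse triangle inequality
    (l_ij ≥ max_k(l_ik − u_kj, l_kj − u_ik)).  Idempotent on consistent
    input; raises :class:`InfeasibleBoundsError` if a lower bound ends up
    above its smoothed upper.
    """
    upper = bounds.upper.copy()
    lower = bounds.lower.copy()
    L = bounds.length
    for k in range(L):
        uk_row = upper[k, :]
        upper = np.minimum(upper, upper[:, k][:, None] + uk_row[None, :])
        lower = np.maximum(
            lower,
            np.maximum(
                lower[:, k][:, None] - uk_row[None, :],
                lower[k, :][None, :] - upper[:, k][:, None],
            ),
        )
    if np.any(lower > upper + 1e-9):
        raise InfeasibleBoundsError(
            "bounds are triangle-inconsistent after smoothing"
        )
    lower = np.minimum(lower, upper)  # clip 1e-9-scale float fuzz
    return DistanceBounds(lower, upper)


def _trace_from_coords(coords: np.ndarray, chain_id: str = "A") -> CaTrace:
    L = coords.shape[0]
    return CaTrace(
        chain_id=chain_id,
        residue_numbers=np.arange(1, L + 1),
        residue_names=("ALA",) * L,
        coords=coords,
    )


def embed(bounds: DistanceBounds, rng_seed: int) -> CaTrace:
    """Metrize and embed bounds into 3-D coordinates (classical MDS).

    A trial distance matrix is drawn uniformly and independently per pair
    within [lower, upper], double-centered into a Gram matrix, and projected
    onto its top three eigenpairs (negative eigenvalues clamped to zero).
    Exact for a degenerate (lower = upper) Euclidean distance matrix.
    """
    rng = np.random.default_rng(rng_seed)
    L = bounds.length
    iu = np.triu_indices(L, k=1)
    d = np.zeros((L, L))
    d[iu] = rng.uniform(bounds.lower[iu], bounds.upper[iu])
    d = d + d.T
    # classical MDS: B = -1/2 · J D² J
    d2 = d**2
    b = -0.5 * (
        d2
        - d2.mean(axis=0, keepdims=True)
        - d2.mean(axis=1, keepdims=True)
        + d2.mean()
    )
    eigvals, eigvecs = np.linalg.eigh(b)
    top = eigvals[-3:][::-1]
    vecs = eigvecs[:, -3:][:, ::-1]
    coords = vecs * np.sqrt(np.clip(top, 0.0, None))
    return _trace_from_coords(coords)


def _violation_energy(x: np.ndarray, lower: np.ndarray, upper: np.ndarray):
    """Squared bound-violation energy over all pairs, with gradient."""
    L = lower.shape[0]
    coords = x.reshape(L, 3)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=2))
    np.fill_diagonal(dist, 1.0)  # diagonal excluded below
    viol_low = np.clip(lower - dist, 0.0, None)
    viol_up = np.clip(dist - upper, 0.0, None)
    np.fill_diagonal(viol_low, 0.0)
    np.fill_diagonal(viol_up, 0.0)
    # each unordered pair appears twice in the matrices
    energy = 0.5 * float(np.sum(viol_low**2) + np.sum(viol_up**2))
    coeff = 2.0 * (viol_up - viol_low) / dist
    grad = np.sum(coeff[:, :, None] * diff, axis=1)
    return energy, grad.ravel()


def _alternate_project(
    coords: np.ndarray, lower: np.ndarray, upper: np.ndarray, n_iter: int
) -> np.ndarray:
    """Alternating metric projection between distance space and 3-D.

    Clip the current distance matrix into the bounds, re-embed it by
    classical MDS, repeat.  A cheap global conditioner that pulls a rough
    embedding out of the deep local minima a pure gradient scheme gets
    trapped in; the subsequent descent phase does the precise work.
    """
    for _ in range(n_iter):
        diff = coords[:, None, :] - coords[None, :, :]
        d = np.sqrt(np.sum(diff**2, axis=2))
        d = np.clip(d, lower, upper)
        d2 = d**2
        b = -0.5 * (
            d2
            - d2.mean(axis=0, keepdims=True)
            - d2.mean(axis=1, keepdims=True)
            + d2.mean()
        )
        eigvals, eigvecs = np.linalg.eigh(b)
        coords = eigvecs[:, -3:] * np.sqrt(np.clip(eigvals[-3:], 0.0, None))
    return coords


def refine(
    trace: CaTrace,
    bounds: DistanceBounds,
    steps: int = 2000,
    energy_tol: float = 1e-4,
    n_project: int = 50,
) -> tuple[CaTrace, float]:
    """Relax coordinates against the bounds.

    Two stages: ``n_project`` rounds of alternating metric projection
    condition the embedding, then L-BFGS minimisation of the squared
    violation energy polishes it.  Returns the refined trace and its final
    energy; over the descent phase the energy is non-increasing across
    accepted iterates and stops early once below ``energy_tol``.
    Coordinates already satisfying all bounds are returned unchanged.
    """
    lower, upper = bounds.lower, bounds.upper
    x0 = np.asarray(trace.coords, dtype=float).ravel()

    e0, _ = _violation_energy(x0, lower, upper)
    if e0 <= energy_tol:
        return trace, float(e0)
    if n_project > 0:
        x0 = _alternate_project(x0.reshape(-1, 3), lower, upper, n_project).ravel()
        e0, _ = _violation_energy(x0, lower, upper)
        if e0 <= energy_tol:
            return trace.with_coords(x0.reshape(-1, 3)), float(e0)

    def callback(xk):
        e, _ = _violation_energy(xk, lower, upper)
        if e < energy_tol:
            raise StopIteration  # converged: scipy terminates gracefully

    result = minimize(
        _violation_energy,
        x0,
        args=(lower, upper),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": steps, "ftol": 1e-12, "gtol": 1e-10},
        callback=callback,
    )
    x_final = result.x
    energy, _ = _violation_energy(x_final, lower, upper)
    if not np.isfinite(energy) or not np.all(np.isfinite(x_final)):
        raise NumericalError(
            f"refinement diverged (energy={energy!r}); check bound consistency"
        )
    return trace.with_coords(x_final.reshape(-1, 3)), float(energy)


@dataclass
class ReconstructionResult:
    """Ensemble of reconstructed models plus scores against the native.

    ``models`` are the ``top_k`` lowest-energy candidates, ascending by
    ``energies``.  ``rmsd``/``tm`` are the mean mirror-resolved scores of
    the kept models against the native structure (NaN when no native was
    supplied).  ``satisfied_fraction`` is the share of input contacts
    realised below the cutoff in the best model.
    """

    models: list[CaTrace]
    energies: np.ndarray
    rmsd: float
    tm: float
    satisfied_fraction: float
    model_scores: list[SuperpositionScore] = field(default_factory=list)
    candidate_energies: np.ndarray = field(default_factory=lambda: np.array([]))


def _candidate_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def reconstruct(
    cmap: ContactMap,
    sse: SseAnnotation | None = None,
    native: CaTrace | None = None,
    config: DistillerConfig = DistillerConfig(),
    seed: int | None = None,
) -> ReconstructionResult:
    """Reconstruct a Cα ensemble from a contact map.

    ``config.n_candidates`` independent embed+refine runs are generated from
    sub-seeds derived deterministically from ``seed`` (default:
    ``config.seed``); the ``top_k`` lowest-energy models are kept.  With a
    native structure given, the ensemble is scored by the mean
    mirror-resolved RMSD and TM-score of the kept models.
    """
    run_seed = config.seed if seed is None else seed
    bounds = compile_bounds(cmap.length, cmap, sse=sse, cutoff=config.cutoff)

    candidates = []
    for cand_seed in _candidate_seeds(run_seed, config.n_candidates):
        initial = embed(bounds, cand_seed)
        refined, energy = refine(
            initial, bounds, steps=config.refine_steps, energy_tol=config.energy_tol
        )
        candidates.append((energy, refined))
    candidates.sort(key=lambda pair: pair[0])
    kept = candidates[: config.top_k]
    models = [trace for _, trace in kept]
    energies = np.array([energy for energy, _ in kept])
    candidate_energies = np.array([energy for energy, _ in candidates])

    scores: list[SuperpositionScore] = []
    rmsd = tm = float("nan")
    if native is not None:
        if len(native) != cmap.length:
            raise ParameterError(
                f"native length {len(native)} does not match map length {cmap.length}"
            )
        scores = [score_with_mirror(m, native) for m in models]
        # mirror-resolve the stored models too, so written ensembles match
        models = [
            m.with_coords(-m.coords) if s.mirrored else m
            for m, s in zip(models, scores)
        ]
        rmsd = float(np.mean([s.rmsd for s in scores]))
        tm = float(np.mean([s.tm_score for s in scores]))

    best = models[0]
    if len(cmap) > 0:
        pairs = np.array(cmap.pairs())
        d = np.linalg.norm(best.coords[pairs[:, 0]] - best.coords[pairs[:, 1]], axis=1)
        satisfied = float(np.mean(d < config.cutoff + 1e-3))
    else:
        satisfied = 1.0

    return ReconstructionResult(
        models=models,
        energies=energies,
        rmsd=rmsd,
        tm=tm,
        satisfied_fraction=satisfied,
        model_scores=scores,
        candidate_energies=candidate_energies,
    )
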