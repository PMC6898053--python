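"""Synthetic Cα fixtures with known ground truth.

Three families of single-chain, single-domain test structures in the size
range of small fast-folding proteins:

* ideal α-helices (radius 2.3 Å, rise 1.5 Å/residue, 100°/residue);
* antiparallel helix bundles — segments packed at ~10 Å axis separation and
  joined by loops whose consecutive Cα spacing respects the 3.8 Å virtual
  bond, so the native trace satisfies the reconstruction engine's own
  sequential bounds;
* self-avoiding random coils (3.8 Å steps, 4.0 Å excluded volume).

A fourth builder plants a *unique* inter-segment contact: two compressed
spirals (which, unlike ideal α-helices, have intra-segment contacts at
sequence separations 6–7) are placed just close enough that exactly one
residue pair bridges them.  That single contact is the only constraint on
the segments' relative placement — the synthetic analogue of a contact
isolated from all others in the map, whose relevance a scoring run should
rank first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .contacts import Contact, ContactMap, compute_contact_map
from .errors import GenerationError, ParameterError
from .model import CaTrace
from .reconstruct import SseAnnotation

__all__ = [
    "make_helix",
    "make_bundle",
    "make_bundle_fixture",
    "make_unique_contact_bundle",
    "make_coil",
    "BundleFixture",
]

HELIX_RADIUS = 2.3  # Å
HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST = 100.0  # degrees per residue
BOND = 3.8  # virtual Cα–Cα bond, Å
EXCLUDED = 4.0  # excluded-volume floor for non-bonded pairs, Å


def _helix_coords(
    length: int,
    origin: np.ndarray,
    direction: int,
    phase: float,
    radius: float = HELIX_RADIUS,
    rise: float = HELIX_RISE,
    twist: float = HELIX_TWIST,
) -> np.ndarray:
    """Cα spiral around a vertical axis through ``origin``.

    ``direction`` +1 builds upward in z, −1 downward; ``phase`` in radians.
    """
    m = np.arange(length)
    theta = phase + np.deg2rad(twist) * m
    return np.column_stack(
        [
            origin[0] + radius * np.cos(theta),
            origin[1] + radius * np.sin(theta),
            origin[2] + direction * rise * m,
        ]
    )


def _as_trace(coords: np.ndarray, names=None, chain_id: str = "A") -> CaTrace:
    L = coords.shape[0]
    if names is None:
        names = ("ALA",) * L
    return CaTrace(
        chain_id=chain_id,
        residue_numbers=np.arange(1, L + 1),
        residue_names=tuple(names),
        coords=coords,
    )


def make_helix(length: int, seed: int | None = None) -> CaTrace:
    """Ideal α-helical Cα spiral; deterministic (the seed is ignored).

    Consecutive Cα distance is √((2·2.3·sin 50°)² + 1.5²) ≈ 3.83 Å.
    """
    if length < 4:
        raise ParameterError(f"helix length must be >= 4, got {length}")
    return _as_trace(_helix_coords(length, np.zeros(3), +1, 0.0))


# ---------------------------------------------------------------------------
# loop construction: chord-stepping along a Bézier arc


def _bezier(p0, c1, c2, p3, t):
    t = t[:, None]
    return (
        (1 - t) ** 3 * p0
        + 3 * (1 - t) ** 2 * t * c1
        + 3 * (1 - t) * t**2 * c2
        + t**3 * p3
    )


def _chord_walk(samples: np.ndarray, target: np.ndarray) -> list[np.ndarray] | None:
    """Place points along a densely sampled curve at exact 3.8 Å chord steps.

    Walking starts from ``samples[0]``; succeeds when the gap from the last
    placed point to ``target`` falls inside the virtual-bond window
    [3.7, 3.9].  Returns the interior points, or None if the walk cannot
    close the gap.
    """
    placed: list[np.ndarray] = []
    p = samples[0]
    idx = 1
    for _ in range(40):
        gap = float(np.linalg.norm(target - p))
        if 3.7 <= gap <= 3.9:
            return placed
        if gap < 3.7:
            return None
        # first dense sample at least one bond away from p
        while idx < len(samples) and np.linalg.norm(samples[idx] - p) < BOND:
            idx += 1
        if idx >= len(samples):
            return None
        a, b = samples[idx - 1], samples[idx]
        lo, hi = 0.0, 1.0
        for _ in range(40):  # bisect the bracketing segment
            mid = 0.5 * (lo + hi)
            if np.linalg.norm(a + mid * (b - a) - p) < BOND:
                lo = mid
            else:
                hi = mid
        p = a + hi * (b - a)
        placed.append(p)
    return None


def _build_loop(p_start, t_start, p_end, t_end) -> list[np.ndarray] | None:
    """Loop residues joining two segment termini with ~3.8 Å spacing.

    A cubic Bézier leaves ``p_start`` along ``t_start`` and arrives at
    ``p_end`` along ``t_end``; the control-arm length is scanned until
    chord-stepping closes the gap within the bond window.
    """
    for h in np.arange(1.5, 9.01, 0.25):
        c1 = p_start + h * t_start
        c2 = p_end - h * t_end
        t = np.linspace(0.0, 1.0, 800)
        samples = _bezier(p_start, c1, c2, p_end, t)
        points = _chord_walk(samples, p_end)
        if points is not None:
            return points
    return None


def _self_avoiding(coords: np.ndarray, floor: float = EXCLUDED) -> bool:
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    ii, jj = np.triu_indices(len(coords), k=2)
    return bool(np.all(d[ii, jj] >= floor))


def _segment_centers(n_segments: int, axis_sep: float) -> np.ndarray:
    """Centers of segment axes: a pair for 2, a regular polygon for >= 3
    (adjacent centers at ``axis_sep``)."""
    if n_segments == 2:
        return np.array([[0.0, 0.0], [axis_sep, 0.0]])
    circumradius = axis_sep / (2.0 * math.sin(math.pi / n_segments))
    angles = 2.0 * math.pi * np.arange(n_segments) / n_segments
    return circumradius * np.column_stack([np.cos(angles), np.sin(angles)])


@dataclass
class BundleFixture:
    """A helix bundle with ground truth: trace, helix annotation, segment
    membership and the inter-segment contacts present in its map."""

    trace: CaTrace
    sse: SseAnnotation
    segment_of: np.ndarray  # -1 for loop residues
    planted_contacts: list[Contact]
    contact_map: ContactMap


def _assemble_bundle(
    n_segments: int,
    seg_length: int,
    phases: np.ndarray,
    axis_sep: float,
    radius: float = HELIX_RADIUS,
    rise: float = HELIX_RISE,
    twist: float = HELIX_TWIST,
) -> tuple[np.ndarray, np.ndarray] | None:
    centers = _segment_centers(n_segments, axis_sep)
    z_top = rise * (seg_length - 1)
    pieces: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    prev_end = None
    for k in range(n_segments):
        direction = +1 if k % 2 == 0 else -1
        z0 = 0.0 if direction > 0 else z_top
        origin = np.array([centers[k, 0], centers[k, 1], z0])
        helix = _helix_coords(
            seg_length, origin, direction, phases[k],
            radius=radius, rise=rise, twist=twist,
        )
        if prev_end is not None:
            t_prev = np.array([0.0, 0.0, float(+1 if (k - 1) % 2 == 0 else -1)])
            t_next = np.array([0.0, 0.0, float(direction)])
            loop = _build_loop(prev_end, t_prev, helix[0], t_next)
            if loop is None:
                return None
            if loop:
                pieces.append(np.array(loop))
                labels.append(np.full(len(loop), -1))
        pieces.append(helix)
        labels.append(np.full(seg_length, k))
        prev_end = helix[-1]
    return np.vstack(pieces), np.concatenate(labels)


def make_bundle_fixture(
    n_segments: int = 2,
    seg_length: int = 25,
    seed: int = 0,
    axis_sep: float = 10.0,
    max_retries: int = 20,
) -> BundleFixture:
    """Antiparallel helix bundle with known contacts.

    Helix phases are drawn from the seed; generation retries with fresh
    phases until the assembled trace is self-avoiding and its contact map
    holds at least one inter-segment contact.
    """
    if n_segments < 2:
        raise ParameterError(f"need >= 2 segments, got {n_segments}")
    if seg_length < 6:
        raise ParameterError(f"segment length must be >= 6, got {seg_length}")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        phases = rng.uniform(0.0, 2.0 * math.pi, size=n_segments)
        assembled = _assemble_bundle(n_segments, seg_length, phases, axis_sep)
        if assembled is None:
            continue
        coords, labels = assembled
        if not _self_avoiding(coords):
            continue
        names = tuple("ALA" if s >= 0 else "GLY" for s in labels)
        trace = _as_trace(coords, names=names)
        cmap = compute_contact_map(trace)
        planted = [
            c
            for c in cmap
            if labels[c.i] >= 0 and labels[c.j] >= 0 and labels[c.i] != labels[c.j]
        ]
        if not planted:
            continue
        sse = SseAnnotation("".join("H" if s >= 0 else "C" for s in labels))
        return BundleFixture(trace, sse, labels, planted, cmap)
    raise GenerationError(
        f"could not pack a {n_segments}x{seg_length} bundle after {max_retries} tries"
    )


def make_bundle(
    n_segments: int, seg_length: int, seed: int = 0, axis_sep: float = 10.0
) -> tuple[CaTrace, list[Contact]]:
    """Bundle trace plus the inter-segment contacts present in its map."""
    fixture = make_bundle_fixture(n_segments, seg_length, seed, axis_sep)
    return fixture.trace, fixture.planted_contacts


def make_unique_contact_bundle(
    seg_length: int = 14, seed: int = 0, splay_deg: float = 8.0
) -> BundleFixture:
    """Two compressed spirals bridged by exactly one inter-segment contact.

    A spiral with 1.0 Å rise and 97°/residue twist (bond kept at 3.8 Å)
    contacts itself at separations 6 and 7, so each segment contributes
    redundant short-range contacts.  The second segment is splayed away by
    a few degrees, so the segments approach each other only at their free
    (bottom) ends — far from the hinge, where the loop itself provides no
    coupling.  Axis separation and second-segment phase are scanned until
    precisely one long-range residue pair bridges the segments and no loop
    residue participates in any contact.  ``planted_contacts`` holds that
    single bridging contact.
    """
    rise, twist = 1.0, 97.0
    radius = math.sqrt(BOND**2 - rise**2) / (2.0 * math.sin(math.radians(twist / 2)))
    rng = np.random.default_rng(seed)
    phase1 = rng.uniform(0.0, 2.0 * math.pi)
    beta = math.radians(splay_deg)
    rot = np.array(
        [
            [math.cos(beta), 0.0, math.sin(beta)],
            [0.0, 1.0, 0.0],
            [-math.sin(beta), 0.0, math.cos(beta)],
        ]
    )
    z_top = rise * (seg_length - 1)
    seg1 = _helix_coords(
        seg_length, np.zeros(3), +1, phase1, radius=radius, rise=rise, twist=twist
    )
    for axis_sep in np.arange(12.0, 13.81, 0.1):
        for phase2 in np.linspace(0.0, 2.0 * math.pi, 48, endpoint=False):
            seg2 = _helix_coords(
                seg_length,
                np.array([0.0, 0.0, z_top]),
                -1,
                phase2,
                radius=radius,
                rise=rise,
                twist=twist,
            )
            # splay about the bottom axis point, then shift beside segment 1
            seg2 = seg2 @ rot.T + np.array([axis_sep, 0.0, 0.0])
            t_next = rot @ np.array([0.0, 0.0, -1.0])
            loop = _build_loop(
                seg1[-1], np.array([0.0, 0.0, 1.0]), seg2[0], t_next
            )
            if loop is None:
                continue
            pieces = [seg1] + ([np.array(loop)] if loop else []) + [seg2]
            labels = np.concatenate(
                [
                    np.zeros(seg_length, dtype=int),
                    np.full(len(loop), -1),
                    np.ones(seg_length, dtype=int),
                ]
            )
            coords = np.vstack(pieces)
            if not _self_avoiding(coords, floor=3.8):
                continue
            trace = _as_trace(
                coords, names=tuple("ALA" if s >= 0 else "GLY" for s in labels)
            )
            cmap = compute_contact_map(trace)
            bridging = [
                c for c in cmap
                if labels[c.i] == -1
                or labels[c.j] == -1
                or labels[c.i] != labels[c.j]
            ]
            intra = [c for c in cmap if c not in bridging]
            if (
                len(bridging) == 1
                and bridging[0].range_class == "long"
                and len(intra) >= 4
            ):
                sse = SseAnnotation("C" * len(trace))  # not an ideal α-helix
                return BundleFixture(trace, sse, labels, bridging, cmap)
    raise GenerationError(
        "no axis separation / phase combination yields a unique bridging contact"
    )


def make_coil(length: int, seed: int = 0) -> CaTrace:
    """Self-avoiding random walk: 3.8 Å steps, non-bonded pairs >= 4.0 Å."""
    if length < 2:
        raise ParameterError(f"coil length must be >= 2, got {length}")
    rng = np.random.default_rng(seed)
    for _ in range(60):  # whole-chain restarts
        coords = [np.zeros(3)]
        ok = True
        for _ in range(length - 1):
            placed = False
            for _ in range(120):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                candidate = coords[-1] + BOND * u
                if len(coords) < 2 or np.all(
                    np.linalg.norm(np.array(coords[:-1]) - candidate, axis=1)
                    >= EXCLUDED
                ):
                    coords.append(candidate)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return _as_trace(np.array(coords))
    raise GenerationError(f"self-avoiding walk of length {length} exceeded retry budget")
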