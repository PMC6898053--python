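"""Rational contact-subset selection, coverage sweeps and noise injection.

All percentage-to-count conversions share one rule — banker's rounding with
a floor of one contact — applied identically across strategies, sweeps and
noise bins.  Selections are always drawn from the contacts in ascending
(i, j) order, so results are independent of input ordering; relevance
sorting breaks ties the same way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DistillerConfig
from .contacts import Contact, ContactMap, compute_contact_map
from .distiller import ContactSR, _round_count
from .errors import CandidateExhaustionError, ParameterError, ShortfallError
from .model import CaTrace, FeatureTable
from .reconstruct import SseAnnotation, reconstruct
from .stats import mann_whitney_u

__all__ = [
    "StrategySpec",
    "NoisySelection",
    "STRATEGY_NAMES",
    "select",
    "coverage_sweep",
    "inject_nonnative",
    "compare_strategies",
    "noise_sweep",
]

STRATEGY_NAMES = (
    "random",
    "most_relevant",
    "least_relevant",
    "short_range",
    "non_short",
    "long_range",
    "non_long",
    "hbond",
    "non_hbond",
    "hydrophobic",
    "non_hydrophobic",
)

_FEATURE_STRATEGIES = {"hbond", "non_hbond", "hydrophobic", "non_hydrophobic"}
_RELEVANCE_STRATEGIES = {"most_relevant", "least_relevant"}


@dataclass(frozen=True)
class StrategySpec:
    """A named subset-selection rule.

    ``size`` defaults to 30% of the native contact count (the sensitivity
    sweet spot); complement bins (``non_*``) should be size-matched to their
    feature bin by the caller.
    """

    name: str
    size: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.name not in STRATEGY_NAMES:
            raise ParameterError(
                f"unknown strategy {self.name!r}; known: {', '.join(STRATEGY_NAMES)}"
            )
        if self.size is not None and self.size < 1:
            raise ParameterError(f"strategy size must be >= 1, got {self.size}")

    def resolve_size(self, cmap: ContactMap) -> int:
        if self.size is not None:
            return self.size
        return _round_count(0.30 * len(cmap))


@dataclass(frozen=True)
class NoisySelection:
    """A contact selection diluted with non-native contacts."""

    kept: tuple[Contact, ...]
    injected: tuple[Contact, ...]
    fraction: float
    length: int

    def combined(self) -> ContactMap:
        return ContactMap(self.length, self.kept + self.injected)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _sample(contacts: list[Contact], size: int, rng: np.random.Generator):
    idx = rng.choice(len(contacts), size=size, replace=False)
    return [contacts[i] for i in idx]


def select(
    spec: StrategySpec,
    cmap: ContactMap,
    scores: list[ContactSR] | None = None,
    features: FeatureTable | None = None,
) -> ContactMap:
    """Select contacts according to a strategy.

    Relevance strategies sort by SR (ties broken by ascending (i, j));
    range and feature bins sample uniformly within the bin; ``non_*``
    complements sample from outside it.  A bin smaller than the requested
    size raises :class:`ShortfallError` naming the deficit.
    """
    size = spec.resolve_size(cmap)
    ordered = sorted(cmap.contacts)
    if size > len(ordered):
        raise ShortfallError(spec.name, len(ordered), size)
    rng = _rng(spec.seed, 0)

    if spec.name == "random":
        chosen = _sample(ordered, size, rng)
    elif spec.name in _RELEVANCE_STRATEGIES:
        if scores is None:
            raise ParameterError(f"strategy {spec.name!r} requires SR scores")
        sr_of = {s.contact: s.sr_rmsd for s in scores}
        missing = [c for c in ordered if c not in sr_of]
        if missing:
            raise ParameterError(
                f"SR scores missing for {len(missing)} contacts (e.g. {missing[0]})"
            )
        reverse = spec.name == "most_relevant"
        ranked = sorted(
            ordered, key=lambda c: (-sr_of[c] if reverse else sr_of[c], c.i, c.j)
        )
        chosen = ranked[:size]
    elif spec.name in {"short_range", "non_short", "long_range", "non_long"}:
        target = "short" if "short" in spec.name else "long"
        in_bin = [c for c in ordered if c.range_class == target]
        pool = (
            [c for c in ordered if c not in set(in_bin)]
            if spec.name.startswith("non_")
            else in_bin
        )
        if len(pool) < size:
            raise ShortfallError(spec.name, len(pool), size)
        chosen = _sample(pool, size, rng)
    elif spec.name in _FEATURE_STRATEGIES:
        if features is None:
            raise ParameterError(f"strategy {spec.name!r} requires a pair feature table")
        column = "hbond" if "hbond" in spec.name else "hydrophobic"
        flagged = features.pair_flags(column)
        in_bin = [c for c in ordered if (c.i, c.j) in flagged]
        pool = (
            [c for c in ordered if (c.i, c.j) not in flagged]
            if spec.name.startswith("non_")
            else in_bin
        )
        if len(pool) < size:
            raise ShortfallError(spec.name, len(pool), size)
        chosen = _sample(pool, size, rng)
    else:  # pragma: no cover - guarded by StrategySpec validation
        raise ParameterError(f"unknown strategy {spec.name!r}")
    return cmap.with_contacts(chosen)


def coverage_sweep(
    native: CaTrace,
    fractions: list[float],
    n_rep: int,
    config: DistillerConfig = DistillerConfig(),
    sse: SseAnnotation | None = None,
    engine=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reconstruction error as a function of contact-map coverage.

    For every fraction, ``n_rep`` random subsets are reconstructed and
    scored against the native.  Returns per-replicate rows and a
    per-fraction summary (median and quartiles).
    """
    if engine is None:
        engine = reconstruct
    for f in fractions:
        if not 0.0 < f <= 1.0:
            raise ParameterError(f"coverage fraction {f} outside (0, 1]")
    cmap = compute_contact_map(native, cutoff=config.cutoff, min_sep=config.min_sep)
    ordered = sorted(cmap.contacts)
    rows = []
    for fi, fraction in enumerate(fractions):
        size = _round_count(fraction * len(cmap))
        for rep in range(n_rep):
            rng = _rng(config.seed, 10, fi, rep)
            subset = cmap.with_contacts(_sample(ordered, size, rng))
            seed = int(rng.integers(2**31))
            result = engine(subset, sse, native, config, seed)
            rows.append(
                {
                    "fraction": fraction,
                    "replicate": rep,
                    "n_contacts": size,
                    "rmsd": result.rmsd,
                    "tm": result.tm,
                }
            )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("fraction")["rmsd"]
        .agg(
            median="median",
            q1=lambda s: float(np.percentile(s, 25)),
            q3=lambda s: float(np.percentile(s, 75)),
        )
        .reset_index()
    )
    summary["tm_median"] = table.groupby("fraction")["tm"].median().to_numpy()
    return table, summary


def inject_nonnative(
    selection: ContactMap,
    native: ContactMap,
    f: float,
    seed: int = 0,
) -> NoisySelection:
    """Replace a fraction ``f`` of a selection by non-native contacts.

    ``round(f · |selection|)`` members are removed uniformly and replaced by
    uniformly drawn residue pairs with sequence separation greater than five
    that are absent from the native map; the selection size is preserved.
    """
    if not 0.0 <= f <= 1.0:
        raise ParameterError(f"noise fraction {f} outside [0, 1]")
    if selection.length != native.length:
        raise ParameterError("selection and native map lengths differ")
    ordered = sorted(selection.contacts)
    m = round(f * len(ordered))
    if m == 0:
        return NoisySelection(tuple(ordered), (), f, selection.length)

    L = native.length
    native_pairs = {(c.i, c.j) for c in native.contacts}
    candidates = [
        (i, j)
        for i in range(L)
        for j in range(i + 6, L)  # separation > 5
        if (i, j) not in native_pairs
    ]
    if len(candidates) < m:
        raise CandidateExhaustionError(
            f"only {len(candidates)} non-native pairs available, need {m}"
        )
    rng = _rng(seed, 20)
    drop = set(rng.choice(len(ordered), size=m, replace=False).tolist())
    kept = tuple(c for idx, c in enumerate(ordered) if idx not in drop)
    picked = rng.choice(len(candidates), size=m, replace=False)
    injected = tuple(Contact(*candidates[i]) for i in picked)
    return NoisySelection(kept, injected, f, selection.length)


def compare_strategies(
    native: CaTrace,
    specs: list[StrategySpec],
    n_rep: int,
    config: DistillerConfig = DistillerConfig(),
    scores: list[ContactSR] | None = None,
    features: FeatureTable | None = None,
    sse: SseAnnotation | None = None,
    engine=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reconstruction performance of several selection strategies.

    Every stochastic bin re-samples its selection per replicate.  The
    summary carries per-strategy mean, std and median RMSD plus the
    two-tailed Mann-Whitney p-value against the ``random`` strategy (when
    present and more than one replicate was run).
    """
    if engine is None:
        engine = reconstruct
    cmap = compute_contact_map(native, cutoff=config.cutoff, min_sep=config.min_sep)
    rows = []
    for si, spec in enumerate(specs):
        for rep in range(n_rep):
            rep_spec = StrategySpec(
                spec.name,
                size=spec.size,
                seed=int(_rng(spec.seed, 30, si, rep).integers(2**31)),
            )
            selection = select(rep_spec, cmap, scores=scores, features=features)
            seed = int(_rng(config.seed, 31, si, rep).integers(2**31))
            result = engine(selection, sse, native, config, seed)
            rows.append(
                {
                    "strategy": spec.name,
                    "replicate": rep,
                    "f_nonnative": 0.0,
                    "rmsd": result.rmsd,
                    "tm": result.tm,
                    "n_contacts": len(selection),
                }
            )
    table = pd.DataFrame(rows)
    summary_rows = []
    random_rmsd = table.loc[table["strategy"] == "random", "rmsd"]
    for spec in specs:
        rmsd = table.loc[table["strategy"] == spec.name, "rmsd"]
        p_vs_random = float("nan")
        if spec.name != "random" and len(random_rmsd) > 0 and n_rep > 1:
            _, p_vs_random = mann_whitney_u(rmsd.to_numpy(), random_rmsd.to_numpy())
        summary_rows.append(
            {
                "strategy": spec.name,
                "mean_rmsd": float(rmsd.mean()),
                "std_rmsd": float(rmsd.std(ddof=1)) if len(rmsd) > 1 else 0.0,
                "median_rmsd": float(rmsd.median()),
                "median_tm": float(
                    table.loc[table["strategy"] == spec.name, "tm"].median()
                ),
                "p_vs_random": p_vs_random,
            }
        )
    return table, pd.DataFrame(summary_rows)


def noise_sweep(
    native: CaTrace,
    base_strategy: StrategySpec,
    fractions: list[float],
    n_rep: int,
    config: DistillerConfig = DistillerConfig(),
    scores: list[ContactSR] | None = None,
    sse: SseAnnotation | None = None,
    engine=None,
) -> pd.DataFrame:
    """Reconstruction error under increasing non-native contact fractions.

    For each fraction, the base selection (re-sampled per replicate for
    stochastic strategies) is diluted by :func:`inject_nonnative` and
    reconstructed.
    """
    if engine is None:
        engine = reconstruct
    cmap = compute_contact_map(native, cutoff=config.cutoff, min_sep=config.min_sep)
    rows = []
    for fi, f in enumerate(fractions):
        for rep in range(n_rep):
            rep_spec = StrategySpec(
                base_strategy.name,
                size=base_strategy.size,
                seed=int(_rng(base_strategy.seed, 40, fi, rep).integers(2**31)),
            )
            selection = select(rep_spec, cmap, scores=scores)
            noisy = inject_nonnative(
                selection, cmap, f,
                seed=int(_rng(config.seed, 41, fi, rep).integers(2**31)),
            )
            seed = int(_rng(config.seed, 42, fi, rep).integers(2**31))
            result = engine(noisy.combined(), sse, native, config, seed)
            rows.append(
                {
                    "strategy": base_strategy.name,
                    "replicate": rep,
                    "f_nonnative": f,
                    "n_injected": len(noisy.injected),
                    "rmsd": result.rmsd,
                    "tm": result.tm,
                    "n_contacts": len(noisy.combined()),
                }
            )
    return pd.DataFrame(rows)
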