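"""Per-contact structural-relevance (SR) scoring.

The SR of a contact is the mean improvement in reconstruction error
(ΔRMSD, Å) that knowledge of that contact confers when it is toggled within
sparse baseline subsets of the native contact map:

1. Sample ``r`` random baseline subsets covering 30% of the native map and
   reconstruct each (``RMSD_baseline``).
2. For every native contact and every baseline, toggle the contact — remove
   it if present, add it if absent — and reconstruct (``RMSD_toggle``).
3. ΔRMSD = RMSD_baseline − RMSD_toggle when the contact was added, and the
   negation when it was removed, so positive SR always means the contact
   helps.  Per-contact SR is the unweighted mean over the ``r`` toggles.

30% coverage places baselines near the fold/no-fold boundary, where a
single contact has maximal leverage.  An analogous score in TM-score units
(positive = helpful) is tracked alongside.  The reconstruction engine is an
injectable dependency, so any backend with the
``engine(cmap, sse, native, config, seed)`` signature can be scored — and
closed-form stub engines make the aggregation exactly testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .config import DistillerConfig
from .contacts import Contact, ContactMap, compute_contact_map
from .errors import ContactSrError, ParameterError
from .model import CaTrace
from .reconstruct import ReconstructionResult, SseAnnotation, reconstruct

logger = logging.getLogger(__name__)

__all__ = [
    "DistillerConfig",
    "ContactSR",
    "ResidueSR",
    "sample_baselines",
    "toggle",
    "delta_rmsd",
    "structural_relevance",
    "aggregate_residue_sr",
    "contact_sr_table",
    "residue_sr_table",
]

Engine = Callable[..., ReconstructionResult]


@dataclass(frozen=True)
class ContactSR:
    """Aggregated structural relevance of one contact.

    ``sr_rmsd`` is the mean ΔRMSD (Å) over the ``r`` toggles, ``sr_tm`` the
    TM-score analogue; ``n_removed``/``n_added`` count how many baselines
    contained / lacked the contact (they sum to the redundancy actually
    realised for this contact).
    """

    contact: Contact
    sr_rmsd: float
    sr_tm: float
    std: float
    n_removed: int
    n_added: int


@dataclass(frozen=True)
class ResidueSR:
    """Structural relevance aggregated over a residue's incident contacts."""

    residue: int
    mean_sr: float
    sum_sr: float
    n_contacts: int

    @property
    def no_contacts(self) -> bool:
        return self.n_contacts == 0


def _round_count(x: float) -> int:
    """Percentage→count conversion used everywhere: banker's round, min 1."""
    return max(1, round(x))


def _baseline_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1, index)))


def _baseline_engine_seed(seed: int, index: int) -> int:
    state = np.random.SeedSequence(seed, spawn_key=(2, index)).generate_state(1)[0]
    return int(state % (2**31))


def sample_baselines(cmap: ContactMap, config: DistillerConfig) -> list[ContactMap]:
    """``r`` independent uniform subsets of the native map, each holding
    ``round(coverage · |map|)`` contacts (at least one)."""
    n = len(cmap)
    if n < 2:
        raise ParameterError(f"need at least 2 contacts to distil, got {n}")
    if config.coverage * n < 1:
        raise ParameterError(
            f"coverage {config.coverage} selects no contact from a map of {n}"
        )
    k = _round_count(config.coverage * n)
    ordered = sorted(cmap.contacts)
    subsets = []
    for i in range(config.redundancy):
        rng = _baseline_rng(config.seed, i)
        chosen = rng.choice(n, size=k, replace=False)
        subsets.append(cmap.with_contacts([ordered[j] for j in chosen]))
    return subsets


def toggle(
    subset: ContactMap, contact: Contact, native: ContactMap | None = None
) -> tuple[ContactMap, str]:
    """Remove the contact if present in the subset, add it otherwise.

    Involution: toggling twice restores the subset.  When the native map is
    supplied, contacts outside it are rejected.
    """
    if native is not None and contact not in native:
        raise ParameterError(
            f"contact ({contact.i}, {contact.j}) is not part of the native map"
        )
    if contact in subset:
        return subset.remove(contact), "removed"
    return subset.add(contact), "added"


def delta_rmsd(
    baseline: ReconstructionResult, toggled: ReconstructionResult, action: str
) -> float:
    """ΔRMSD of one toggle, signed so that positive means the contact helps."""
    if action == "added":
        return baseline.rmsd - toggled.rmsd
    if action == "removed":
        return toggled.rmsd - baseline.rmsd
    raise ParameterError(f"unknown toggle action {action!r}")


def _delta_tm(
    baseline: ReconstructionResult, toggled: ReconstructionResult, action: str
) -> float:
    # TM increases for good models: sign mirrors delta_rmsd's convention
    if action == "added":
        return toggled.tm - baseline.tm
    return baseline.tm - toggled.tm


def structural_relevance(
    native: CaTrace,
    sse: SseAnnotation | None = None,
    config: DistillerConfig = DistillerConfig(),
    engine: Engine | None = None,
    n_jobs: int = 1,
) -> tuple[list[ContactSR], list[ResidueSR]]:
    """Score every native contact by toggling it within ``r`` baselines.

    Exactly ``r · (|C_native| + 1)`` engine calls are made.  Toggle runs
    reuse the engine seed of their baseline so that the baseline/toggle
    difference reflects the contact, not the random stream.  With
    ``n_jobs > 1`` toggle reconstructions run in parallel worker processes;
    seeds are pre-derived, so results are identical to serial execution.

    Returns per-contact scores (ascending ``(i, j)``) and per-residue
    aggregates.
    """
    if engine is None:
        engine = reconstruct
    cmap = compute_contact_map(native, cutoff=config.cutoff, min_sep=config.min_sep)
    if len(cmap) == 0:
        raise ParameterError("native structure has an empty contact map")
    baselines = sample_baselines(cmap, config)
    seeds = [_baseline_engine_seed(config.seed, i) for i in range(len(baselines))]

    baseline_results = [
        engine(subset, sse, native, config, seed)
        for subset, seed in zip(baselines, seeds)
    ]
    contacts = sorted(cmap.contacts)

    jobs = []  # (contact, baseline index, toggled map, action)
    for c in contacts:
        for i, subset in enumerate(baselines):
            toggled, action = toggle(subset, c, native=cmap)
            jobs.append((c, i, toggled, action))

    if n_jobs > 1:
        from joblib import Parallel, delayed

        toggle_results = Parallel(n_jobs=n_jobs)(
            delayed(engine)(toggled, sse, native, config, seeds[i])
            for _, i, toggled, _ in jobs
        )
    else:
        toggle_results = [
            engine(toggled, sse, native, config, seeds[i])
            for _, i, toggled, _ in jobs
        ]

    per_contact: dict[Contact, dict] = {
        c: {"rmsd": [], "tm": [], "removed": 0, "added": 0} for c in contacts
    }
    for (c, i, _, action), result in zip(jobs, toggle_results):
        if result is None:
            continue
        try:
            d_rmsd = delta_rmsd(baseline_results[i], result, action)
            d_tm = _delta_tm(baseline_results[i], result, action)
        except ContactSrError:
            raise
        except Exception:  # engine-side scoring failure: drop this toggle
            logger.exception(
                "toggle of (%d, %d) in baseline %d failed; excluded", c.i, c.j, i
            )
            continue
        acc = per_contact[c]
        acc["rmsd"].append(d_rmsd)
        acc["tm"].append(d_tm)
        acc[action] += 1

    scores = []
    for c in contacts:
        acc = per_contact[c]
        deltas = np.array(acc["rmsd"])
        if deltas.size == 0:
            logger.warning("contact (%d, %d): all toggles failed", c.i, c.j)
            scores.append(ContactSR(c, float("nan"), float("nan"), float("nan"), 0, 0))
            continue
        scores.append(
            ContactSR(
                contact=c,
                sr_rmsd=float(deltas.mean()),
                sr_tm=float(np.mean(acc["tm"])),
                std=float(deltas.std(ddof=1)) if deltas.size > 1 else 0.0,
                n_removed=acc["removed"],
                n_added=acc["added"],
            )
        )
    residues = aggregate_residue_sr(scores, len(native))
    return scores, residues


def aggregate_residue_sr(scores: list[ContactSR], length: int) -> list[ResidueSR]:
    """Aggregate contact SR onto residues.

    Both the mean and the sum over incident contacts are reported.  Residues
    without contacts get zero relevance and a flag; downstream statistics
    exclude them.
    """
    incident: dict[int, list[float]] = {r: [] for r in range(length)}
    for s in scores:
        if s.contact.j >= length:
            raise ParameterError(
                f"contact ({s.contact.i}, {s.contact.j}) outside length {length}"
            )
        incident[s.contact.i].append(s.sr_rmsd)
        incident[s.contact.j].append(s.sr_rmsd)
    out = []
    for r in range(length):
        values = incident[r]
        if values:
            out.append(ResidueSR(r, float(np.mean(values)), float(np.sum(values)), len(values)))
        else:
            out.append(ResidueSR(r, 0.0, 0.0, 0))
    return out


def contact_sr_table(scores: list[ContactSR]) -> pd.DataFrame:
    rows = [
        {
            "i": s.contact.i,
            "j": s.contact.j,
            "separation": s.contact.separation,
            "range_class": s.contact.range_class,
            "sr_rmsd": s.sr_rmsd,
            "sr_tm": s.sr_tm,
            "std": s.std,
            "n_removed": s.n_removed,
            "n_added": s.n_added,
        }
        for s in scores
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "i", "j", "separation", "range_class",
            "sr_rmsd", "sr_tm", "std", "n_removed", "n_added",
        ],
    )


def residue_sr_table(residues: list[ResidueSR]) -> pd.DataFrame:
    rows = [
        {
            "residue": r.residue,
            "mean_sr": r.mean_sr,
            "sum_sr": r.sum_sr,
            "n_contacts": r.n_contacts,
            "no_contacts_flag": r.no_contacts,
        }
        for r in residues
    ]
    return pd.DataFrame(
        rows, columns=["residue", "mean_sr", "sum_sr", "n_contacts", "no_contacts_flag"]
    )
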