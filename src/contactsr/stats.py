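"""Statistical layer: Mann-Whitney U tests, trend tables, notched summaries.

Group comparisons use the two-tailed Mann-Whitney U test throughout, exact
for small tie-free samples and tie-corrected asymptotic (with continuity
correction) otherwise.  Feature-vs-relevance trend tables split scored
contacts or residues by a boolean annotation and report group sizes, means,
standard deviations and the significance of the difference; no
multiple-testing correction is applied by default (an optional
Benjamini-Hochberg flag is provided).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy import stats as sps

from .distiller import ContactSR, ResidueSR
from .errors import DegenerateSplitError, ParameterError
from .model import FeatureTable

__all__ = [
    "TrendRow",
    "mann_whitney_u",
    "trend_table",
    "notched_summary",
]

EXACT_MAX_COMBINED_N = 20


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test.

    Exact enumeration of the U null distribution when the combined sample
    size is at most 20 and there are no ties; tie-corrected normal
    approximation with continuity correction otherwise.  Returns
    ``(U_x, p)`` where ``U_x + U_y = |x|·|y|``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("Mann-Whitney U requires two non-empty samples")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    if combined.size <= EXACT_MAX_COMBINED_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    result = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(result.statistic), float(result.pvalue)


@dataclass(frozen=True)
class TrendRow:
    """One feature's association with structural relevance.

    ``trend`` is ``up``/``down`` for a significant (p < alpha) higher/lower
    mean in the feature-present group, and ``-`` otherwise.
    """

    feature: str
    n_present: int
    n_absent: int
    mean_present: float
    mean_absent: float
    std_present: float
    std_absent: float
    trend: str
    p_value: float


Scored = Union[ContactSR, ResidueSR]


def _score_value(item: Scored) -> float:
    return item.sr_rmsd if isinstance(item, ContactSR) else item.mean_sr


def _flag_for(item: Scored, features: FeatureTable, column: str) -> bool | None:
    """Feature flag for a scored item; None when the table has no row for it."""
    if isinstance(item, ContactSR):
        flagged = features.pair_flags(column)
        return (item.contact.i, item.contact.j) in flagged
    flags = features.residue_flags(column)
    return flags.get(item.residue)


def trend_table(
    scores: Sequence[Scored],
    features: FeatureTable,
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> list[TrendRow]:
    """Split scored items by each boolean feature and test the difference.

    Residues flagged as having no contacts are excluded.  A feature present
    for all (or none) of the items yields no split and raises
    :class:`DegenerateSplitError`.  With ``bh_correction`` the p-values are
    Benjamini-Hochberg adjusted across features before the trend call.
    """
    usable = [
        s for s in scores if not (isinstance(s, ResidueSR) and s.no_contacts)
    ]
    if not usable:
        raise ParameterError("no scored items left after excluding contact-free residues")

    raw_rows = []
    for column in features.feature_columns:
        present, absent = [], []
        for item in usable:
            flag = _flag_for(item, features, column)
            if flag is None:
                continue
            (present if flag else absent).append(_score_value(item))
        if not present or not absent:
            raise DegenerateSplitError(
                f"feature {column!r} does not split the observations "
                f"({len(present)} present / {len(absent)} absent)"
            )
        _, p = mann_whitney_u(present, absent)
        raw_rows.append((column, np.array(present), np.array(absent), p))

    p_values = np.array([r[3] for r in raw_rows])
    if bh_correction:
        p_values = np.minimum(1.0, sps.false_discovery_control(p_values, method="bh"))

    rows = []
    for (column, present, absent, _), p in zip(raw_rows, p_values):
        diff = present.mean() - absent.mean()
        if p < alpha:
            trend = "up" if diff > 0 else "down"
        else:
            trend = "-"
        rows.append(
            TrendRow(
                feature=column,
                n_present=present.size,
                n_absent=absent.size,
                mean_present=float(present.mean()),
                mean_absent=float(absent.mean()),
                std_present=float(present.std(ddof=1)) if present.size > 1 else 0.0,
                std_absent=float(absent.std(ddof=1)) if absent.size > 1 else 0.0,
                trend=trend,
                p_value=float(p),
            )
        )
    return rows


def notched_summary(sample: Sequence[float]) -> tuple[float, float, float, float, float]:
    """Median, quartiles and the 95% notch around the median.

    The notch follows the McGill rule: median ± 1.57·IQR/√n.  Returns
    ``(median, q1, q3, notch_low, notch_high)``.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.size < 5:
        raise ParameterError(f"notched summary needs >= 5 observations, got {sample.size}")
    median = float(np.median(sample))
    q1, q3 = (float(q) for q in np.percentile(sample, [25, 75]))
    half_width = 1.57 * (q3 - q1) / np.sqrt(sample.size)
    return median, q1, q3, median - half_width, median + half_width
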