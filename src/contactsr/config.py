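"""Run configuration shared by the reconstruction engine and the scoring loop."""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

from .errors import ParameterError

__all__ = ["DistillerConfig"]


@dataclass(frozen=True)
class DistillerConfig:
    """All tunable parameters of a structural-relevance run.

    Attributes
    ----------
    coverage:
        Fraction of the native contact map sampled into each baseline
        subset.  30% keeps the reconstruction near the fold/no-fold boundary
        and therefore maximally sensitive to a single toggled contact.
    redundancy:
        Number of independent baseline subsets (``r``).  Each contact is
        toggled once per baseline, so per-contact scores average ``r``
        ΔRMSD observations.
    cutoff:
        Cα–Cα contact cutoff in Å (strict ``<``).
    min_sep:
        Minimum sequence separation of a contact.
    rmsd_success / tm_success:
        Thresholds below/above which a reconstruction is considered to
        resemble the native fold (4.0 Å, TM 0.5).
    top_k:
        Models kept (and averaged) per reconstruction, ranked by
        constraint-violation energy.
    n_candidates:
        Independent embed+refine runs per reconstruction.
    refine_steps:
        Iteration budget of the bound-violation minimiser per candidate.
    energy_tol:
        Early-stop energy: a candidate whose violation energy falls below
        this is accepted as converged.
    seed:
        Master seed; every random stream in a run derives from it.
    """

    coverage: float = 0.30
    redundancy: int = 10
    cutoff: float = 8.0
    min_sep: int = 6
    rmsd_success: float = 4.0
    tm_success: float = 0.5
    top_k: int = 5
    n_candidates: int = 20
    refine_steps: int = 2000
    energy_tol: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.coverage <= 1.0:
            raise ParameterError(f"coverage must be in (0, 1], got {self.coverage}")
        if self.redundancy < 1:
            raise ParameterError(f"redundancy must be >= 1, got {self.redundancy}")
        if self.cutoff <= 0:
            raise ParameterError(f"cutoff must be positive, got {self.cutoff}")
        if self.min_sep < 1:
            raise ParameterError(f"min_sep must be >= 1, got {self.min_sep}")
        for name in ("rmsd_success", "tm_success", "energy_tol"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("top_k", "n_candidates", "refine_steps"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if self.top_k > self.n_candidates:
            raise ParameterError("top_k cannot exceed n_candidates")

    def replace(self, **changes) -> "DistillerConfig":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)
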