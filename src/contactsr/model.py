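"""Domain types for protein structures and legacy-PDB I/O.

The package works exclusively on Cα traces of single chains of single-domain
proteins.  :class:`CaTrace` is the in-memory representation; :func:`read_pdb`
and :func:`write_ca_pdb` convert between it and legacy PDB files (ATOM
records only on output; input tolerates full PDB files with ligands,
alternate locations and arbitrary extra records).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import (
    FeatureTableError,
    HetatmOnlyChainError,
    InsertionCodeError,
    MissingChainError,
    TooFewResiduesError,
)

logger = logging.getLogger(__name__)

__all__ = ["CaTrace", "FeatureTable", "read_pdb", "write_ca_pdb"]


@dataclass(frozen=True)
class CaTrace:
    """Ordered Cα coordinates of one protein chain.

    Parameters
    ----------
    chain_id:
        Author chain identifier.
    residue_numbers:
        Author residue numbering, strictly increasing.  Chain breaks
        (missing interior residues) are permitted; all sequence-separation
        logic in this package operates on the *position within the trace*,
        never on author numbering, so breaks do not create spurious
        long-range pairs.
    residue_names:
        Three-letter residue codes.
    coords:
        ``(L, 3)`` float array of Cα positions in Ångström.
    """

    chain_id: str
    residue_numbers: np.ndarray
    residue_names: tuple[str, ...]
    coords: np.ndarray = field(repr=False)

    def __post_init__(self):
        numbers = np.asarray(self.residue_numbers, dtype=int)
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "residue_numbers", numbers)
        object.__setattr__(self, "residue_names", tuple(self.residue_names))
        object.__setattr__(self, "coords", coords)
        if numbers.ndim != 1 or len(numbers) < 2:
            raise ValueError("a CaTrace needs at least two residues")
        if coords.shape != (len(numbers), 3):
            raise ValueError(
                f"coords shape {coords.shape} inconsistent with "
                f"{len(numbers)} residues"
            )
        if len(self.residue_names) != len(numbers):
            raise ValueError("residue_names length mismatch")
        if not np.all(np.diff(numbers) > 0):
            raise ValueError("residue numbers must be strictly increasing")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.residue_numbers)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CaTrace):
            return NotImplemented
        return (
            self.chain_id == other.chain_id
            and np.array_equal(self.residue_numbers, other.residue_numbers)
            and self.residue_names == other.residue_names
            and np.array_equal(self.coords, other.coords)
        )

    def isclose(self, other: "CaTrace", atol: float = 1e-3) -> bool:
        """Equality up to a coordinate tolerance (PDB files carry 3 decimals)."""
        return (
            self.chain_id == other.chain_id
            and np.array_equal(self.residue_numbers, other.residue_numbers)
            and self.residue_names == other.residue_names
            and np.allclose(self.coords, other.coords, atol=atol, rtol=0.0)
        )

    def with_coords(self, coords: np.ndarray) -> "CaTrace":
        """A copy of this trace carrying different coordinates."""
        return CaTrace(self.chain_id, self.residue_numbers, self.residue_names, coords)


def read_pdb(path, chain: str = "A") -> CaTrace:
    """Read the Cα trace of one chain from a legacy PDB file.

    Alternate locations: the blank altloc or ``A`` is kept, all others are
    dropped, yielding a deterministic single-conformer trace.  Residues with
    insertion codes are rejected.  Residues lacking a Cα atom are skipped
    with a warning.

    Raises
    ------
    MissingChainError
        The chain identifier does not occur in the file.
    HetatmOnlyChainError
        The chain holds only HETATM records (e.g. a ligand-only chain).
    TooFewResiduesError
        Fewer than two Cα atoms remain after filtering.
    InsertionCodeError
        The chain uses residue insertion codes.
    """
    pdb_file = PDBFile.read(str(path))
    atoms = pdb_file.get_structure(model=1, altloc="first", extra_fields=[])

    on_chain = atoms[atoms.chain_id == chain]
    if on_chain.array_length() == 0:
        raise MissingChainError(f"chain {chain!r} not present in {path}")
    polymer = on_chain[~on_chain.hetero]
    if polymer.array_length() == 0:
        raise HetatmOnlyChainError(
            f"chain {chain!r} in {path} holds only HETATM records"
        )
    if np.any(polymer.ins_code != ""):
        raise InsertionCodeError(
            f"chain {chain!r} in {path} uses insertion codes, which are unsupported"
        )

    ca = polymer[polymer.atom_name == "CA"]
    # report residues that have backbone atoms but no Cα
    all_res = set(polymer.res_id.tolist())
    ca_res = set(ca.res_id.tolist())
    for res_id in sorted(all_res - ca_res):
        logger.warning("chain %s residue %d has no CA atom; skipped", chain, res_id)
    if ca.array_length() < 2:
        raise TooFewResiduesError(
            f"chain {chain!r} in {path} has {ca.array_length()} CA atoms; need >= 2"
        )

    # one Cα per residue: with altloc filtering applied, keep first occurrence
    res_ids = ca.res_id
    _, first = np.unique(res_ids, return_index=True)
    keep = np.sort(first)
    return CaTrace(
        chain_id=chain,
        residue_numbers=res_ids[keep],
        residue_names=tuple(ca.res_name[keep].tolist()),
        coords=ca.coord[keep],
    )


def write_ca_pdb(trace: CaTrace, path) -> None:
    """Write a Cα trace as a legacy PDB file (ATOM records only).

    Occupancy is 1.00, the B-factor 0.00 and the element column ``C``;
    :func:`read_pdb` inverts the operation exactly (coordinates to the
    3-decimal precision of the format).
    """
    n = len(trace)
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(trace.coords, dtype=np.float32)
    atoms.chain_id = np.full(n, trace.chain_id)
    atoms.res_id = trace.residue_numbers
    atoms.res_name = np.array(trace.residue_names)
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.hetero = np.full(n, False)
    atoms.set_annotation("occupancy", np.ones(n))
    atoms.set_annotation("b_factor", np.zeros(n))
    pdb_file = PDBFile()
    pdb_file.set_structure(atoms)
    pdb_file.write(str(path))


class FeatureTable:
    """Externally produced residue or residue-pair annotations.

    Tab-separated with a header row.  Residue tables key rows by
    ``residue_number`` (author numbering); pair tables by ``residue_i`` and
    ``residue_j``.  Remaining columns carry boolean flags (accepted
    spellings: ``1/0``, ``true/false``, ``yes/no``) or free text.  Every key
    must resolve to a residue of the associated trace.
    """

    RESIDUE_KEY = "residue_number"
    PAIR_KEYS = ("residue_i", "residue_j")

    def __init__(self, data: pd.DataFrame, trace: CaTrace):
        self.trace = trace
        known = set(trace.residue_numbers.tolist())
        if self.RESIDUE_KEY in data.columns:
            self.kind = "residue"
            bad = set(data[self.RESIDUE_KEY]) - known
        elif all(k in data.columns for k in self.PAIR_KEYS):
            self.kind = "pair"
            bad = (set(data["residue_i"]) | set(data["residue_j"])) - known
        else:
            raise FeatureTableError(
                "feature table must have a 'residue_number' column or "
                "'residue_i'/'residue_j' columns"
            )
        if bad:
            raise FeatureTableError(
                f"feature table references unknown residues: {sorted(bad)[:10]}"
            )
        self.data = data.reset_index(drop=True)
        # author residue number -> 0-based trace index
        self._index_of = {int(r): i for i, r in enumerate(trace.residue_numbers)}

    @classmethod
    def from_tsv(cls, path, trace: CaTrace) -> "FeatureTable":
        data = pd.read_csv(path, sep="\t")
        return cls(data, trace)

    @property
    def feature_columns(self) -> list[str]:
        keys = {self.RESIDUE_KEY, *self.PAIR_KEYS}
        return [c for c in self.data.columns if c not in keys]

    def boolean_column(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise FeatureTableError(f"no feature column {name!r}")
        col = self.data[name]
        if col.dtype == bool:
            return col.to_numpy()
        mapping = {
            "1": True, "0": False, "true": True, "false": False,
            "yes": True, "no": False,
        }
        try:
            return np.array(
                [mapping[str(v).strip().lower()] for v in col], dtype=bool
            )
        except KeyError as exc:
            raise FeatureTableError(
                f"column {name!r} is not boolean (offending value {exc})"
            ) from None

    def residue_flags(self, name: str) -> dict[int, bool]:
        """Trace-index -> flag mapping for a boolean residue column."""
        if self.kind != "residue":
            raise FeatureTableError("residue_flags requires a residue table")
        flags = self.boolean_column(name)
        return {
            self._index_of[int(r)]: bool(f)
            for r, f in zip(self.data[self.RESIDUE_KEY], flags)
        }

    def pair_flags(self, name: str) -> set[tuple[int, int]]:
        """Set of flagged (i, j) trace-index pairs (i < j) for a pair column."""
        if self.kind != "pair":
            raise FeatureTableError("pair_flags requires a pair table")
        flags = self.boolean_column(name)
        pairs = set()
        for ri, rj, f in zip(self.data["residue_i"], self.data["residue_j"], flags):
            if f:
                i, j = self._index_of[int(ri)], self._index_of[int(rj)]
                pairs.add((min(i, j), max(i, j)))
        return pairs
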