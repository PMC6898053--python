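"""Contact maps: computation, range classification and CASP-RR (de)serialization.

A contact is a pair of residues whose Cα atoms lie strictly closer than a
cutoff (default 8 Å) and which are at least six positions apart in sequence;
closer pairs merely stabilise secondary structure and are ignored.  Sequence
separation is measured on the position within the trace, not on author
residue numbering, so chain breaks do not inflate separations.  Remaining
contacts are short-range (separation 6–11), medium-range (12–23) or
long-range (>23).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import ParameterError, RRFormatError
from .model import CaTrace

__all__ = [
    "Contact",
    "ContactMap",
    "classify_range",
    "compute_contact_map",
    "read_rr",
    "write_rr",
    "contact_map_to_tsv",
]

MIN_SEPARATION = 6
SHORT_MAX = 11
MEDIUM_MAX = 23


def classify_range(separation: int) -> str:
    """Classify a sequence separation as ``short``, ``medium`` or ``long``."""
    if separation < MIN_SEPARATION:
        raise ParameterError(
            f"separation {separation} < {MIN_SEPARATION}: such pairs are not contacts"
        )
    if separation <= SHORT_MAX:
        return "short"
    if separation <= MEDIUM_MAX:
        return "medium"
    return "long"


@dataclass(frozen=True, order=True)
class Contact:
    """A residue pair (0-based trace indices, ``i < j``) in spatial contact."""

    i: int
    j: int

    def __post_init__(self):
        if not 0 <= self.i < self.j:
            raise ParameterError(f"need 0 <= i < j, got ({self.i}, {self.j})")
        if self.separation < MIN_SEPARATION:
            raise ParameterError(
                f"contact ({self.i}, {self.j}) has separation "
                f"{self.separation} < {MIN_SEPARATION}"
            )

    @property
    def separation(self) -> int:
        return self.j - self.i

    @property
    def range_class(self) -> str:
        return classify_range(self.separation)


class ContactMap:
    """A set of contacts over a chain of ``length`` residues.

    Contacts are stored once with ``i < j``; construction deduplicates and
    validates indices.  Iteration is always in ascending ``(i, j)`` order so
    every downstream operation is independent of input ordering.
    """

    def __init__(self, length: int, contacts: Iterable[Contact] = ()):
        if length < 2:
            raise ParameterError(f"map length {length} < 2")
        self.length = int(length)
        frozen = frozenset(contacts)
        for c in frozen:
            if c.j >= self.length:
                raise ParameterError(
                    f"contact ({c.i}, {c.j}) outside chain of length {self.length}"
                )
        self.contacts = frozen

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    def __len__(self) -> int:
        return len(self.contacts)

    def __contains__(self, contact: Contact) -> bool:
        return contact in self.contacts

    def __iter__(self) -> Iterator[Contact]:
        return iter(sorted(self.contacts))

    def __eq__(self, other) -> bool:
        if not isinstance(other, ContactMap):
            return NotImplemented
        return self.length == other.length and self.contacts == other.contacts

    def __hash__(self) -> int:
        return hash((self.length, self.contacts))

    def __repr__(self) -> str:
        return f"ContactMap(length={self.length}, n_contacts={len(self)})"

    def with_contacts(self, contacts: Iterable[Contact]) -> "ContactMap":
        """A map over the same chain holding a different contact set."""
        return ContactMap(self.length, contacts)

    def add(self, contact: Contact) -> "ContactMap":
        return self.with_contacts(self.contacts | {contact})

    def remove(self, contact: Contact) -> "ContactMap":
        return self.with_contacts(self.contacts - {contact})

    def pairs(self) -> list[tuple[int, int]]:
        return [(c.i, c.j) for c in self]

    def by_range(self, range_class: str) -> list[Contact]:
        return [c for c in self if c.range_class == range_class]


def compute_contact_map(
    trace: CaTrace, cutoff: float = 8.0, min_sep: int = MIN_SEPARATION
) -> ContactMap:
    """All residue pairs with Cα distance strictly below ``cutoff`` and
    trace-index separation of at least ``min_sep``.

    The cutoff comparison is strict: a pair at exactly 8.0 Å is *not* a
    contact under the default definition.
    """
    if cutoff <= 0:
        raise ParameterError(f"cutoff must be positive, got {cutoff}")
    if min_sep < 1:
        raise ParameterError(f"min_sep must be >= 1, got {min_sep}")
    dist = squareform(pdist(trace.coords))
    L = len(trace)
    ii, jj = np.triu_indices(L, k=min_sep)
    close = dist[ii, jj] < cutoff
    contacts = [Contact(int(i), int(j)) for i, j in zip(ii[close], jj[close])]
    return ContactMap(L, contacts)


def read_rr(path, length: int) -> ContactMap:
    """Read a CASP-RR contact list (1-based residue indices).

    Lines are ``i j d_low d_high confidence``; index order within a line is
    normalized, blank lines and the optional ``PFRMAT``/``TARGET``/``MODEL``/
    ``END`` headers are skipped.  Malformed or out-of-range lines raise
    :class:`RRFormatError` carrying the line number.
    """
    contacts = []
    header_words = ("PFRMAT", "TARGET", "AUTHOR", "METHOD", "MODEL", "REMARK", "END")
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.split()[0].upper() in header_words:
                continue
            parts = line.split()
            if len(parts) < 2:
                raise RRFormatError(f"cannot parse {line!r}", line_no)
            try:
                a, b = int(parts[0]), int(parts[1])
            except ValueError:
                raise RRFormatError(f"non-integer residue index in {line!r}", line_no)
            i, j = min(a, b) - 1, max(a, b) - 1
            if a == b:
                raise RRFormatError(f"self-contact {a}", line_no)
            if i < 0 or j >= length:
                raise RRFormatError(
                    f"residue pair ({a}, {b}) outside chain of length {length}", line_no
                )
            if j - i < MIN_SEPARATION:
                raise RRFormatError(
                    f"pair ({a}, {b}) has separation {j - i} < {MIN_SEPARATION}", line_no
                )
            contacts.append(Contact(i, j))
    return ContactMap(length, contacts)


def write_rr(cmap: ContactMap, path) -> None:
    """Write a contact map as CASP-RR lines ``i j 0 8.0 1.0`` (1-based)."""
    with open(path, "w") as fh:
        for c in cmap:
            fh.write(f"{c.i + 1} {c.j + 1} 0 8.0 1.0\n")


def contact_map_to_tsv(cmap: ContactMap, trace: CaTrace | None = None) -> pd.DataFrame:
    """Tabular export with per-contact separation, range class and, when a
    trace is supplied, the actual Cα distance."""
    rows = []
    for c in cmap:
        row = {
            "i": c.i,
            "j": c.j,
            "separation": c.separation,
            "range_class": c.range_class,
        }
        if trace is not None:
            row["distance"] = float(
                np.linalg.norm(trace.coords[c.i] - trace.coords[c.j])
            )
        rows.append(row)
    columns = ["i", "j", "separation", "range_class"]
    if trace is not None:
        columns.append("distance")
    return pd.DataFrame(rows, columns=columns)
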