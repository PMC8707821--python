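"""Allosteric-site conservation scoring across aligned CYP sequences.

The H1 allosteric site is defined by 18 residues of the CYP2D6 reference
sequence (author numbering): S137, T138, L139, R140, N141, L142, G143,
L144, G145, K146, L149, L189, P268, R269, D270, L271, A274, A277.  Given
a multiple sequence alignment of the catalytic domains, the site columns
are located through the reference and each pair of enzymes is scored per
position: 1.0 for identical residues, 0.5 for different residues in the
same physicochemical group, 0 otherwise (gaps score 0 against anything).
The site-averaged pair scores form a symmetric conservation matrix with
unit diagonal, alongside a plain percent-identity matrix over the same
columns.

Alignment computation itself is delegated: this module consumes an
already-aligned FASTA (e.g. from ClustalW or MAFFT).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment

__all__ = [
    "GAP",
    "GroupScheme",
    "SiteDefinition",
    "ConservationMatrix",
    "h1_site_cyp2d6",
    "load_alignment",
    "pair_score",
    "map_site",
    "site_conservation",
]

GAP = "-"

_AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

# Residue list of the H1 site on the CYP2D6 reference (1-based author
# numbering with expected one-letter codes).
_H1_RESIDUES: tuple[tuple[int, str], ...] = (
    (137, "S"), (138, "T"), (139, "L"), (140, "R"), (141, "N"), (142, "L"),
    (143, "G"), (144, "L"), (145, "G"), (146, "K"), (149, "L"), (189, "L"),
    (268, "P"), (269, "R"), (270, "D"), (271, "L"), (274, "A"), (277, "A"),
)


@dataclass(frozen=True)
class GroupScheme:
    """Partition of the 20 amino acids into physicochemical classes.

    The default is a standard partition — aliphatic, aromatic, polar,
    basic, acidic, and the conformationally special G/P — and is fully
    configurable, since published schemes differ in detail.  Every
    residue must belong to exactly one group.
    """

    groups: tuple[tuple[str, frozenset[str]], ...] = (
        ("aliphatic", frozenset("AVLIMC")),
        ("aromatic", frozenset("FWY")),
        ("polar", frozenset("STNQ")),
        ("basic", frozenset("KRH")),
        ("acidic", frozenset("DE")),
        ("special", frozenset("GP")),
    )

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for _, members in self.groups:
            if seen & members:
                raise ValueError(f"residues {seen & members} appear in more than one group")
            seen |= members
        if seen != _AMINO_ACIDS:
            raise ValueError(f"group scheme must cover all 20 amino acids; missing {_AMINO_ACIDS - seen}")

    def group_of(self, residue: str) -> str:
        r = residue.upper()
        for name, members in self.groups:
            if r in members:
                return name
        raise KeyError(f"unknown residue code: {residue!r}")


@dataclass(frozen=True)
class SiteDefinition:
    """An ordered residue set on a reference sequence.

    ``residues`` holds (position, expected one-letter code) pairs with
    strictly increasing 1-based positions in the reference's own
    (ungapped, author) numbering.
    """

    reference_id: str
    residues: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        positions = [p for p, _ in self.residues]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("site positions must be strictly increasing")
        for p, code in self.residues:
            if code.upper() not in _AMINO_ACIDS:
                raise ValueError(f"invalid expected residue code {code!r} at position {p}")

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(p for p, _ in self.residues)

    @property
    def expected_codes(self) -> str:
        return "".join(c for _, c in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


def h1_site_cyp2d6(reference_id: str = "CYP2D6") -> SiteDefinition:
    """The 18-residue H1 allosteric-site definition on CYP2D6."""
    return SiteDefinition(reference_id=reference_id, residues=_H1_RESIDUES)


@dataclass
class ConservationMatrix:
    """Pairwise site conservation (c in [0,1]) and percent identity."""

    labels: list[str]
    c: np.ndarray
    identity: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        self.c = np.asarray(self.c, dtype=float)
        self.identity = np.asarray(self.identity, dtype=float)
        if self.c.shape != (n, n) or self.identity.shape != (n, n):
            raise ValueError("matrix shapes must match label count")

    def to_dataframe(self, which: str = "c") -> pd.DataFrame:
        values = self.c if which == "c" else self.identity
        return pd.DataFrame(values, index=self.labels, columns=self.labels)


def load_alignment(path: str | Path) -> MultipleSeqAlignment:
    """Read an aligned FASTA file."""
    return AlignIO.read(str(path), "fasta")


def pair_score(a: str, b: str, scheme: GroupScheme | None = None) -> float:
    """Conservation value of one aligned residue pair: 1.0, 0.5, or 0.

    Identical residues score 1.0; non-identical residues in the same
    physicochemical group score 0.5; everything else — including any
    pairing that involves a gap — scores 0.  A gap carries no conserved
    residue, so even gap-versus-gap scores 0.
    """
    scheme = scheme or GroupScheme()
    a, b = a.upper(), b.upper()
    for code in (a, b):
        if code != GAP and code not in _AMINO_ACIDS:
            raise KeyError(f"unknown residue code: {code!r}")
    if a == GAP or b == GAP:
        return 0.0
    if a == b:
        return 1.0
    if scheme.group_of(a) == scheme.group_of(b):
        return 0.5
    return 0.0


def _alignment_columns_for_site(
    alignment: MultipleSeqAlignment, site: SiteDefinition
) -> list[int]:
    """Alignment column index of each site position, via the reference."""
    ref = None
    for record in alignment:
        if record.id == site.reference_id:
            ref = str(record.seq).upper()
            break
    if ref is None:
        raise ValueError(f"reference {site.reference_id!r} not found in alignment")
    # ungapped position -> column
    col_of: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(ref):
        if ch != GAP:
            pos += 1
            col_of[pos] = col
    columns = []
    for position, expected in site.residues:
        if position not in col_of:
            raise ValueError(
                f"site position {position} beyond reference length {pos}"
            )
        col = col_of[position]
        if ref[col] != expected.upper():
            raise ValueError(
                f"reference mismatch at position {position}: "
                f"expected {expected!r}, found {ref[col]!r}"
            )
        columns.append(col)
    return columns


def map_site(
    alignment: MultipleSeqAlignment, site: SiteDefinition
) -> dict[str, str]:
    """Residues of each aligned sequence at the site columns.

    Site positions are located on the reference's ungapped sequence and
    read off the same alignment columns in every other sequence; a gap
    at a site column is returned as ``-``.  A mismatch between the
    reference and the expected site codes raises with the offending
    position named.
    """
    columns = _alignment_columns_for_site(alignment, site)
    return {
        record.id: "".join(str(record.seq)[c].upper() for c in columns)
        for record in alignment
    }


def site_conservation(
    alignment: MultipleSeqAlignment,
    site: SiteDefinition,
    scheme: GroupScheme | None = None,
) -> ConservationMatrix:
    """Pairwise site-mean conservation and percent identity matrices.

    ``c[i, j]`` is the mean of :func:`pair_score` over the mapped site
    positions of sequences i and j; ``identity[i, j]`` is
    ``100 * identical positions / site length``.  Both matrices are
    symmetric; the diagonal is fixed at 1.0 / 100 by definition.
    """
    if len(alignment) < 2:
        raise ValueError("site conservation requires at least 2 sequences")
    scheme = scheme or GroupScheme()
    mapped = map_site(alignment, site)
    labels = [record.id for record in alignment]
    n = len(labels)
    L = len(site)
    c = np.eye(n)
    identity = np.eye(n) * 100.0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = mapped[labels[i]], mapped[labels[j]]
            scores = [pair_score(x, y, scheme) for x, y in zip(a, b)]
            ident = sum(1 for x, y in zip(a, b) if x == y and x != GAP)
            c[i, j] = c[j, i] = float(np.mean(scores))
            identity[i, j] = identity[j, i] = 100.0 * ident / L
    return ConservationMatrix(labels=labels, c=c, identity=identity)
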