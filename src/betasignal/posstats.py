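"""Position-frequency matrices and percent-at-position statistics.

The per-position residue statistics quantify the positional preferences of
the insertion signal: positively charged residues (Arg/Lys) at +2, His at +3
in porin-rich beta-proteobacteria, and Tyr at +5 in Helicobacter-like taxa.
Positions use the +k convention (+1 = C-terminal residue).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .extraction import STANDARD_AA, Peptide, dedupe_peptides

#: residue classes recorded as logo-color metadata
HYDROPHOBIC = frozenset("AVILMFWYC")
POLAR = frozenset("RNDQEGHKPST")


@dataclass(frozen=True)
class PositionQuery:
    """A residue set at a +k position (k counted from the C-terminus)."""

    position: int
    residue_set: frozenset[str]

    def __post_init__(self) -> None:
        if not 1 <= self.position <= 10:
            raise ValueError("position must be in 1..10 (+k convention)")
        if not self.residue_set:
            raise ValueError("residue set must be non-empty")
        bad = set(self.residue_set) - set(STANDARD_AA)
        if bad:
            raise ValueError(f"non-standard residue(s) in query: {sorted(bad)}")

    @classmethod
    def make(cls, position: int, residues: Iterable[str]) -> "PositionQuery":
        return cls(position=position, residue_set=frozenset(residues))


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """20 x 10 per-position relative residue frequencies (unique peptides).

    Columns are N-to-C indices 1..10; ``column_for_position`` maps the +k
    convention onto them.  Every column sums to 1.
    """

    frequencies: pd.DataFrame
    n_peptides: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.frequencies.shape != (20, 10):
            raise ValueError("PFM must be 20 x 10")
        sums = self.frequencies.sum(axis=0).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("PFM columns must each sum to 1")

    @staticmethod
    def column_for_position(position_from_cterm: int) -> int:
        """N-to-C column index (1-based) of position +k."""
        return 11 - position_from_cterm

    def column(self, position_from_cterm: int) -> pd.Series:
        return self.frequencies[self.column_for_position(position_from_cterm)]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# label={self.label} n_unique_peptides={self.n_peptides}\n")
            fh.write("# columns: N-to-C residue index 1..10 (+k position = column 11-k)\n")
            hyd = "".join(sorted(HYDROPHOBIC))
            fh.write(f"# color classes: hydrophobic={hyd} polar={''.join(sorted(POLAR))}\n")
            self.frequencies.to_csv(fh, sep="\t")


def frequency_matrix(peptides: Sequence[Peptide], label: str = "") -> PositionFrequencyMatrix:
    """Position-frequency matrix over the unique decamers of a group.

    Deduplication happens within the supplied group (pooled strains are
    deduped after pooling), so identical decamers contribute once.
    """
    unique = dedupe_peptides(peptides, scope="global")
    if not unique:
        raise ValueError("no peptides supplied")
    counts = np.zeros((20, 10))
    aa_index = {aa: i for i, aa in enumerate(STANDARD_AA)}
    for p in unique:
        for pos, aa in enumerate(p.sequence):
            counts[aa_index[aa], pos] += 1
    freqs = counts / counts.sum(axis=0, keepdims=True)
    frame = pd.DataFrame(freqs, index=list(STANDARD_AA), columns=range(1, 11))
    return PositionFrequencyMatrix(frequencies=frame, n_peptides=len(unique), label=label)


def percent_at_position(peptides: Sequence[Peptide], query: PositionQuery) -> float:
    """Percentage of peptides whose +k residue is in the query set.

    Computed on the peptides exactly as supplied — the caller decides whether
    to pass all peptides or unique ones.
    """
    peptides = list(peptides)
    if not peptides:
        raise ValueError("no peptides supplied")
    hits = sum(1 for p in peptides if p.residue_at(query.position) in query.residue_set)
    return 100.0 * hits / len(peptides)


def per_organism_position_profile(
    organisms: Mapping[str, Sequence[Peptide]],
    query: PositionQuery,
    taxa: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-organism percent-at-position table over unique peptides.

    One row per organism with the number of unique decamers and the
    percentage of them carrying a query residue at the query position;
    an optional organism -> taxon map adds a taxon column.
    """
    rows = []
    for org, plist in organisms.items():
        unique = dedupe_peptides(plist, scope="global")
        pct = percent_at_position(unique, query)
        rows.append(
            {
                "organism_id": org,
                "taxon": (taxa or {}).get(org, ""),
                "n_unique": len(unique),
                "percent": pct,
            }
        )
    return pd.DataFrame(rows, columns=["organism_id", "taxon", "n_unique", "percent"])
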