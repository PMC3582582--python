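"""Physicochemical encoding of decamers.

Each amino acid is represented by five principal-property scales (z1..z5,
principal components of a large panel of measured physicochemical variables,
interpretable as lipophilicity, steric bulk/polarizability, polarity and two
electronic properties).  A 10-residue peptide thus becomes a 50-dimensional
vector: block k of 5 columns (N-to-C order) holds the descriptors of residue
k.  The packaged default table can be replaced by any 20x5 scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .extraction import STANDARD_AA, Peptide

N_SCALES = 5
SCALE_NAMES = [f"z{i}" for i in range(1, N_SCALES + 1)]


@dataclass(frozen=True)
class DescriptorTable:
    """A 20 x 5 amino-acid property table (rows: residues, columns: scales)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if sorted(df.index) != sorted(STANDARD_AA):
            missing = set(STANDARD_AA) - set(df.index)
            extra = set(df.index) - set(STANDARD_AA)
            if missing:
                raise ValueError(f"missing residue(s): {', '.join(sorted(missing))}")
            raise ValueError(f"unexpected residue row(s): {', '.join(map(str, sorted(extra)))}")
        if df.shape != (20, N_SCALES):
            raise ValueError(f"descriptor table must be 20x{N_SCALES}, got {df.shape}")
        if df.isna().any().any():
            raise ValueError("descriptor table contains missing values")

    def vector(self, residue: str) -> np.ndarray:
        """The 5-vector for one residue."""
        try:
            return self.values.loc[residue].to_numpy(dtype=float)
        except KeyError:
            raise KeyError(f"unknown residue {residue!r}") from None


def load_descriptor_table(path: str | Path | None = None) -> DescriptorTable:
    """Load a descriptor table from TSV (columns: residue, z1..z5).

    With no path, loads the packaged default z-scales.
    """
    if path is None:
        source = resources.files("betasignal.data").joinpath("zscales.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    if "residue" not in df.columns:
        raise ValueError("descriptor table must have a 'residue' column")
    if df["residue"].duplicated().any():
        dupes = df.loc[df["residue"].duplicated(), "residue"].tolist()
        raise ValueError(f"duplicate residue row(s): {', '.join(dupes)}")
    df = df.set_index("residue")
    scale_cols = [c for c in df.columns if c != "residue"]
    numeric = df[scale_cols].apply(pd.to_numeric, errors="raise")
    return DescriptorTable(values=numeric)


@dataclass(frozen=True)
class EncodedPeptideMatrix:
    """n_peptides x 50 encoding with row-aligned provenance.

    ``data[i, 5*(k-1):5*k]`` holds the descriptors of the residue at N-to-C
    index k of peptide i.
    """

    data: np.ndarray
    peptides: tuple[Peptide, ...]

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[1] != 10 * N_SCALES:
            raise ValueError(f"encoded matrix must have {10 * N_SCALES} columns")
        if self.data.shape[0] != len(self.peptides):
            raise ValueError("row count does not match peptide count")

    @property
    def n_peptides(self) -> int:
        return self.data.shape[0]

    @property
    def column_names(self) -> list[str]:
        return [f"r{k:02d}_{s}" for k in range(1, 11) for s in SCALE_NAMES]

    def organism_ids(self) -> np.ndarray:
        return np.array([p.organism_id for p in self.peptides])

    def to_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "organism_id": [p.organism_id for p in self.peptides],
                "protein_id": [p.protein_id for p in self.peptides],
                "peptide": [p.sequence for p in self.peptides],
            }
        )
        values = pd.DataFrame(self.data, columns=self.column_names)
        return pd.concat([meta, values], axis=1)


def encode_peptides(
    peptides: Sequence[Peptide] | Iterable[Peptide], table: DescriptorTable | None = None
) -> EncodedPeptideMatrix:
    """Encode decamers as rows of a n x 50 matrix (N-to-C block layout)."""
    table = table or load_descriptor_table()
    peptides = tuple(peptides)
    lookup = {aa: table.values.loc[aa].to_numpy(dtype=float) for aa in STANDARD_AA}
    rows = np.empty((len(peptides), 10 * N_SCALES))
    for i, p in enumerate(peptides):
        try:
            rows[i] = np.concatenate([lookup[aa] for aa in p.sequence])
        except KeyError as err:
            raise KeyError(f"peptide {p.sequence!r} contains unknown residue {err.args[0]!r}") from None
    return EncodedPeptideMatrix(data=rows, peptides=peptides)
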