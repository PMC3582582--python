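"""Extraction of C-terminal beta-strand decamers from annotated OMP sequences.

Outer-membrane beta-barrel proteins (OMPs) of Gram-negative bacteria carry a
recognition motif for the BAM insertion machinery in their last transmembrane
beta-strand, which typically ends in an aromatic residue.  This module turns
per-residue strand annotations (a barrel-topology track and a secondary-
structure track) into fixed-length 10-residue peptides ("decamers") suitable
for downstream physicochemical encoding.

The extraction procedure, applied per protein:

1. take the last strand segment of the barrel-topology track;
2. require that at least ``min_strand_fraction`` of its residues are also
   annotated as strand by the secondary-structure track;
3. if the protein C-terminus lies more than ``max_cterm_extension`` residues
   beyond the segment, extend C-terminally by up to that many residues looking
   for an aromatic residue (F/Y/W); otherwise extend to the protein C-terminus;
4. if the motif is still shorter than 10 residues, extend it N-terminally;
5. trim the motif to its 10 C-terminal residues;
6. require a match of the alternating-hydrophobic pattern typical of
   transmembrane beta-strands.

Positions are counted from the C-terminus throughout the package: +1 is the
C-terminal residue, +2 the penultimate one, and in a decamer indexed 1..10
(N to C) position +k is index 11-k.
"""

from __future__ import annotations

import logging
import re
from collections import OrderedDict
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Alternating-hydrophobic pattern of the C-terminal insertion signal
#: (an updated variant of the classic C-terminal beta-signal pattern).
CTERM_PATTERN = r"[^C][YFWKLHVITMADGRE][^C][YFWKLHVITMADGRE][^C][YFWKLHVITMADGRE][^C].[^C][YFWHILM]"
_CTERM_RE = re.compile(CTERM_PATTERN)

#: Strand-number based OMP family labels.
OMP_CLASSES = frozenset(
    {"OMP.8", "OMP.10", "OMP.12", "OMP.14", "OMP.16", "OMP.18", "OMP.22", "OMP.nn", "OMP.hypo"}
)


class RejectionReason(Enum):
    """Why a protein yielded no decamer."""

    NO_STRAND = "no_strand"
    STRAND_FRACTION = "strand_fraction"
    REGEX_FAIL = "regex_fail"
    TOO_SHORT = "too_short"
    NON_STANDARD_RESIDUE = "non_standard_residue"


@dataclass(frozen=True)
class AnnotatedProtein:
    """A protein sequence with per-residue strand annotation tracks.

    ``barrel_track`` marks transmembrane strands predicted by a barrel
    topology predictor; ``ss_track`` marks strands from a generic secondary
    structure predictor.  Both use 'S' for strand and any other character
    (conventionally '-') for non-strand, and must have the same length as
    the sequence.
    """

    protein_id: str
    organism_id: str
    sequence: str
    barrel_track: str
    ss_track: str
    omp_class: str | None = None

    def __post_init__(self) -> None:
        if len(self.barrel_track) != len(self.sequence):
            raise ValueError(
                f"{self.protein_id}: barrel track length {len(self.barrel_track)} "
                f"!= sequence length {len(self.sequence)}"
            )
        if len(self.ss_track) != len(self.sequence):
            raise ValueError(
                f"{self.protein_id}: secondary-structure track length "
                f"{len(self.ss_track)} != sequence length {len(self.sequence)}"
            )
        if self.omp_class is not None and self.omp_class not in OMP_CLASSES:
            raise ValueError(f"{self.protein_id}: unknown OMP class {self.omp_class!r}")


@dataclass(frozen=True)
class Peptide:
    """One extracted 10-residue C-terminal beta-strand with provenance."""

    sequence: str
    organism_id: str
    protein_id: str
    omp_class: str | None = None
    is_protein_cterminal: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) != 10:
            raise ValueError(f"peptide must be a decamer, got {self.sequence!r}")

    def residue_at(self, position_from_cterm: int) -> str:
        """Residue at position +k (k counted from the C-terminus, +1 terminal)."""
        if not 1 <= position_from_cterm <= 10:
            raise ValueError("position must be in 1..10")
        return self.sequence[10 - position_from_cterm]


@dataclass(frozen=True)
class ExtractionConfig:
    """Tunable parameters of the decamer extraction procedure."""

    min_strand_fraction: float = 0.70
    max_cterm_extension: int = 4
    aromatic_set: frozenset[str] = frozenset("FYW")
    target_length: int = 10
    pattern: str = CTERM_PATTERN

    def __post_init__(self) -> None:
        if not 0.0 < self.min_strand_fraction <= 1.0:
            raise ValueError("min_strand_fraction must be in (0, 1]")
        if self.target_length != 10:
            raise ValueError("target_length must be 10")

    @property
    def regex(self) -> re.Pattern:
        return re.compile(self.pattern)


@dataclass(frozen=True)
class ExtractionResult:
    """Outcome of extraction on one protein: a peptide or a rejection reason."""

    peptide: Peptide | None = None
    rejection_reason: RejectionReason | None = None

    def __post_init__(self) -> None:
        if (self.peptide is None) == (self.rejection_reason is None):
            raise ValueError("exactly one of peptide / rejection_reason must be set")

    @property
    def rejected(self) -> bool:
        return self.peptide is None


def _parse_annotation_file(path: str | Path) -> "OrderedDict[str, tuple[str, str]]":
    """Parse the plain-text annotation track file.

    Format: per record, an identifier line starting with '>' followed by one
    or two track lines.  A track line is either a bare track string or
    ``name<whitespace>track`` where name is 'barrel' or 'ss'.  With a single
    track it is used for both the barrel and the secondary-structure role.
    """
    records: "OrderedDict[str, list[tuple[str | None, str]]]" = OrderedDict()
    current: str | None = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                current = line[1:].split()[0]
                if current in records:
                    raise ValueError(f"duplicate annotation identifier {current!r}")
                records[current] = []
            else:
                if current is None:
                    raise ValueError("annotation track line before any identifier")
                parts = line.split(None, 1)
                if len(parts) == 2 and parts[0].lower() in ("barrel", "ss"):
                    records[current].append((parts[0].lower(), parts[1].strip()))
                else:
                    records[current].append((None, line))

    out: "OrderedDict[str, tuple[str, str]]" = OrderedDict()
    for rid, tracks in records.items():
        if not tracks:
            raise ValueError(f"record {rid!r} has no annotation tracks")
        if len(tracks) == 1:
            logger.info("record %s: single annotation track used for both roles", rid)
            out[rid] = (tracks[0][1], tracks[0][1])
        else:
            named = {name: trk for name, trk in tracks if name is not None}
            if "barrel" in named and "ss" in named:
                out[rid] = (named["barrel"], named["ss"])
            else:
                out[rid] = (tracks[0][1], tracks[1][1])
    return out


def read_annotated_fasta(
    fasta_path: str | Path,
    annotation_path: str | Path,
    class_table_path: str | Path | None = None,
) -> list[AnnotatedProtein]:
    """Read sequences, annotation tracks and optional OMP-class labels.

    The FASTA identifier is expected as ``organism_id|protein_id``; a plain
    identifier is used for both fields.  Records with a missing or
    length-mismatched annotation are skipped with a warning.
    """
    tracks = _parse_annotation_file(annotation_path)

    classes: Mapping[str, str] = {}
    if class_table_path is not None:
        ct = pd.read_csv(class_table_path, sep="\t", header=None, comment="#",
                         names=["protein_id", "omp_class"], dtype=str)
        classes = dict(zip(ct["protein_id"], ct["omp_class"]))

    proteins: list[AnnotatedProtein] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        rid = record.id
        if rid in seen:
            raise ValueError(f"identifier collision in FASTA: {rid!r}")
        seen.add(rid)
        if rid not in tracks:
            logger.warning("record %s: no annotation tracks, skipped", rid)
            continue
        barrel, ss = tracks[rid]
        seq = str(record.seq).upper()
        if len(barrel) != len(seq) or len(ss) != len(seq):
            logger.warning("record %s: annotation length mismatch, skipped", rid)
            continue
        if "|" in rid:
            organism_id, protein_id = rid.split("|", 1)
        else:
            organism_id = protein_id = rid
        proteins.append(
            AnnotatedProtein(
                protein_id=protein_id,
                organism_id=organism_id,
                sequence=seq,
                barrel_track=barrel,
                ss_track=ss,
                omp_class=classes.get(protein_id) or classes.get(rid),
            )
        )
    return proteins


def _last_strand_segment(track: str) -> tuple[int, int] | None:
    """(start, end) half-open indices of the last run of 'S', or None."""
    end = None
    for i in range(len(track) - 1, -1, -1):
        if track[i] == "S":
            end = i + 1
            break
    if end is None:
        return None
    start = end - 1
    while start > 0 and track[start - 1] == "S":
        start -= 1
    return start, end


def extract_cterminal_strand(
    protein: AnnotatedProtein, config: ExtractionConfig | None = None
) -> ExtractionResult:
    """Extract the C-terminal insertion-signal decamer from one protein.

    Returns an :class:`ExtractionResult` holding either the decamer
    :class:`Peptide` or the reason the protein was rejected.
    """
    cfg = config or ExtractionConfig()
    seq = protein.sequence
    n = len(seq)

    seg = _last_strand_segment(protein.barrel_track)
    if seg is None:
        return ExtractionResult(rejection_reason=RejectionReason.NO_STRAND)
    start, end = seg

    # filter: secondary-structure support for the predicted strand
    ss_hits = sum(1 for c in protein.ss_track[start:end] if c == "S")
    if ss_hits / (end - start) < cfg.min_strand_fraction:
        return ExtractionResult(rejection_reason=RejectionReason.STRAND_FRACTION)

    # C-terminal extension
    tail = n - end
    if tail > cfg.max_cterm_extension:
        for j in range(end, min(end + cfg.max_cterm_extension, n)):
            if seq[j] in cfg.aromatic_set:
                end = j + 1
                break
    else:
        end = n

    # N-terminal extension to reach the target length
    if end - start < cfg.target_length:
        start = max(0, end - cfg.target_length)
    if end - start < cfg.target_length:
        return ExtractionResult(rejection_reason=RejectionReason.TOO_SHORT)

    decamer = seq[end - cfg.target_length : end]

    if any(c not in STANDARD_AA for c in decamer):
        return ExtractionResult(rejection_reason=RejectionReason.NON_STANDARD_RESIDUE)
    if cfg.regex.fullmatch(decamer) is None:
        return ExtractionResult(rejection_reason=RejectionReason.REGEX_FAIL)

    return ExtractionResult(
        peptide=Peptide(
            sequence=decamer,
            organism_id=protein.organism_id,
            protein_id=protein.protein_id,
            omp_class=protein.omp_class,
            is_protein_cterminal=(end == n),
        )
    )


def extract_all(
    proteins: Iterable[AnnotatedProtein], config: ExtractionConfig | None = None
) -> tuple[list[Peptide], dict[RejectionReason, int]]:
    """Run extraction over many proteins; return peptides and rejection tallies."""
    peptides: list[Peptide] = []
    tallies: dict[RejectionReason, int] = {}
    for protein in proteins:
        result = extract_cterminal_strand(protein, config)
        if result.rejected:
            tallies[result.rejection_reason] = tallies.get(result.rejection_reason, 0) + 1
        else:
            peptides.append(result.peptide)
    return peptides, tallies


def dedupe_peptides(peptides: Iterable[Peptide], scope: str = "per_organism") -> list[Peptide]:
    """Drop exact-sequence duplicates, keeping the first occurrence.

    ``scope='per_organism'`` deduplicates within each organism (the same
    decamer in two organisms is kept twice); ``scope='global'`` deduplicates
    across the whole set.
    """
    if scope not in ("per_organism", "global"):
        raise ValueError("scope must be 'per_organism' or 'global'")
    seen: set = set()
    out: list[Peptide] = []
    for p in peptides:
        key = p.sequence if scope == "global" else (p.organism_id, p.sequence)
        if key in seen:
            continue
        seen.add(key)
        out.append(p)
    return out


def filter_organisms(
    peptides: Iterable[Peptide], min_unique: int = 21
) -> "OrderedDict[str, list[Peptide]]":
    """Group peptides by organism, keeping organisms with >= min_unique unique decamers."""
    by_org: "OrderedDict[str, list[Peptide]]" = OrderedDict()
    for p in peptides:
        by_org.setdefault(p.organism_id, []).append(p)
    return OrderedDict(
        (org, plist)
        for org, plist in by_org.items()
        if len({p.sequence for p in plist}) >= min_unique
    )


# ---------------------------------------------------------------------------
# Tabular I/O

PEPTIDE_COLUMNS = ["organism_id", "protein_id", "omp_class", "peptide", "is_protein_cterminal"]


def peptides_to_frame(peptides: Iterable[Peptide]) -> pd.DataFrame:
    rows = [
        (p.organism_id, p.protein_id, p.omp_class or "", p.sequence, p.is_protein_cterminal)
        for p in peptides
    ]
    return pd.DataFrame(rows, columns=PEPTIDE_COLUMNS)


def frame_to_peptides(frame: pd.DataFrame) -> list[Peptide]:
    out = []
    for row in frame.itertuples(index=False):
        omp = getattr(row, "omp_class", "") or None
        if isinstance(omp, float):  # NaN from pandas
            omp = None
        out.append(
            Peptide(
                sequence=row.peptide,
                organism_id=str(row.organism_id),
                protein_id=str(row.protein_id),
                omp_class=omp,
                is_protein_cterminal=bool(getattr(row, "is_protein_cterminal", True)),
            )
        )
    return out


def write_peptides_tsv(peptides: Iterable[Peptide], path: str | Path) -> None:
    peptides_to_frame(peptides).to_csv(path, sep="\t", index=False)


def read_peptides_tsv(path: str | Path) -> list[Peptide]:
    frame = pd.read_csv(path, sep="\t", dtype={"omp_class": str}, keep_default_na=False)
    frame["omp_class"] = frame["omp_class"].replace("", None)
    return frame_to_peptides(frame)
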