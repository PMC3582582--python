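"""Seeded synthetic datasets with planted taxon-specific positional signals.

The generator emulates the statistical structure the analysis assumes:
organisms grouped into taxa, each organism contributing 21-171 unique
C-terminal decamers whose per-position residue distributions respect the
alternating-hydrophobic pattern of transmembrane beta-strands.  The default
taxa plant the documented positional biases:

* a *Neisseria-like* taxon with P(Arg or Lys at +2) = 0.65 — the "more than
  60% positively charged at the penultimate position" phenotype;
* a *beta-like* taxon dominated by 16-stranded porins (OMP.16) whose OMP.16
  peptides carry His at +3 with probability 0.5;
* a *Helicobacter-like* taxon with P(Tyr at +5) = 0.5;
* a background taxon with P(Arg or Lys at +2) = 0.30, the typical level.

Background distributions at each position are built from the extraction
regex's own position classes, so generated decamers are regex-plausible by
construction; with ``regex_conform`` they are rejection-sampled to match it
exactly.  Everything is deterministic given the spec seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .extraction import CTERM_PATTERN, STANDARD_AA, Peptide

_REGEX = re.compile(CTERM_PATTERN)

NON_C = [aa for aa in STANDARD_AA if aa != "C"]
ALT_HYDRO = list("YFWKLHVITMADGRE")       # N-to-C indices 2, 4, 6
TERMINAL = list("YFWHILM")                # N-to-C index 10 (+1)

#: allowed residues per N-to-C index, mirroring the extraction pattern
POSITION_CLASSES: dict[int, list[str]] = {
    1: NON_C, 2: ALT_HYDRO, 3: NON_C, 4: ALT_HYDRO, 5: NON_C,
    6: ALT_HYDRO, 7: NON_C, 8: NON_C, 9: NON_C, 10: TERMINAL,
}

DEFAULT_CLASS_MIX = {
    "OMP.8": 0.12, "OMP.12": 0.08, "OMP.14": 0.05, "OMP.16": 0.12,
    "OMP.18": 0.03, "OMP.22": 0.30, "OMP.nn": 0.28, "OMP.hypo": 0.02,
}


def _uniform(residues: Sequence[str]) -> dict[str, float]:
    p = 1.0 / len(residues)
    return {aa: p for aa in residues}


def _with_signal(base: Mapping[str, float], residues: Sequence[str], mass: float) -> dict[str, float]:
    """Reassign total probability ``mass`` to ``residues``, rescaling the rest."""
    rest = {aa: p for aa, p in base.items() if aa not in residues}
    scale = (1.0 - mass) / sum(rest.values())
    out = {aa: p * scale for aa, p in rest.items()}
    for aa in residues:
        out[aa] = mass / len(residues)
    return out


def background_position_distributions() -> dict[int, dict[str, float]]:
    """Per-position (+k convention) residue distributions of the background taxon.

    Uniform over each position's allowed class, except +2 which carries the
    typical 30% Arg/Lys mass.
    """
    dists: dict[int, dict[str, float]] = {}
    for idx, allowed in POSITION_CLASSES.items():
        k = 11 - idx
        dists[k] = _uniform(allowed)
    dists[2] = _with_signal(dists[2], ["R", "K"], 0.30)
    return dists


@dataclass(frozen=True)
class TaxonProfile:
    """Positional residue distributions and OMP-class mix of one taxon."""

    name: str
    position_distributions: dict[int, dict[str, float]]
    class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    class_overrides: dict[str, dict[int, dict[str, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, dist in self.position_distributions.items():
            if not np.isclose(sum(dist.values()), 1.0):
                raise ValueError(f"{self.name}: distribution at +{k} does not sum to 1")
        if not np.isclose(sum(self.class_mix.values()), 1.0):
            raise ValueError(f"{self.name}: class mix does not sum to 1")
        for cls in self.class_overrides:
            if cls not in self.class_mix:
                raise ValueError(f"{self.name}: override for class {cls!r} absent from mix")


@dataclass(frozen=True)
class SimSpec:
    """Full description of one synthetic dataset."""

    taxa: tuple[TaxonProfile, ...]
    organisms_per_taxon: int = 10
    peptides_per_organism: tuple[int, int] = (21, 171)
    seed: int = 0
    regex_conform: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.peptides_per_organism
        if lo <= 0 or hi < lo:
            raise ValueError("peptides_per_organism must be a positive range")
        if self.organisms_per_taxon <= 0:
            raise ValueError("organisms_per_taxon must be positive")


def default_spec(seed: int = 0) -> SimSpec:
    """The default four-taxon study design (see module docstring)."""
    bg = background_position_distributions()

    neisseria = dict(bg)
    neisseria[2] = _with_signal(bg[2], ["R", "K"], 0.65)

    helicobacter = dict(bg)
    helicobacter[5] = _with_signal(bg[5], ["Y"], 0.50)

    beta_mix = {"OMP.8": 0.05, "OMP.12": 0.05, "OMP.16": 0.60,
                "OMP.22": 0.10, "OMP.nn": 0.18, "OMP.hypo": 0.02}
    beta_override = {"OMP.16": {3: _with_signal(bg[3], ["H"], 0.50)}}

    taxa = (
        TaxonProfile("neisseria_like", neisseria),
        TaxonProfile("beta_like", dict(bg), class_mix=beta_mix, class_overrides=beta_override),
        TaxonProfile("helicobacter_like", helicobacter),
        TaxonProfile("background", dict(bg)),
    )
    return SimSpec(taxa=taxa, seed=seed)


@dataclass(frozen=True)
class SimulatedDataset:
    """Generated peptides plus organism/taxon and class tables."""

    peptides: tuple[Peptide, ...]
    organisms: pd.DataFrame          # organism_id, taxon
    classes: pd.DataFrame            # protein_id, omp_class
    spec: SimSpec

    @property
    def taxon_of(self) -> dict[str, str]:
        return dict(zip(self.organisms["organism_id"], self.organisms["taxon"]))


def _sample_decamer(
    rng: np.random.Generator,
    dists: Mapping[int, Mapping[str, float]],
    regex_conform: bool,
) -> str:
    choices = {}
    for idx in range(1, 11):
        k = 11 - idx
        dist = dists[k]
        choices[idx] = (list(dist.keys()), np.array(list(dist.values())))
    for _ in range(10_000):
        seq = "".join(
            rng.choice(choices[idx][0], p=choices[idx][1]) for idx in range(1, 11)
        )
        if not regex_conform or _REGEX.fullmatch(seq):
            return seq
    raise RuntimeError("rejection sampling failed: profile incompatible with the pattern")


def generate(spec: SimSpec) -> SimulatedDataset:
    """Draw the dataset described by ``spec`` (deterministic given its seed)."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.peptides_per_organism
    peptides: list[Peptide] = []
    org_rows, class_rows = [], []
    protein_counter = 0
    for taxon in spec.taxa:
        class_names = list(taxon.class_mix.keys())
        class_probs = np.array(list(taxon.class_mix.values()))
        for o in range(spec.organisms_per_taxon):
            org = f"{taxon.name}_org{o:02d}"
            org_rows.append({"organism_id": org, "taxon": taxon.name})
            n = int(rng.integers(lo, hi + 1))
            for _ in range(n):
                omp_class = str(rng.choice(class_names, p=class_probs))
                dists = dict(taxon.position_distributions)
                for k, dist in taxon.class_overrides.get(omp_class, {}).items():
                    dists[k] = dist
                seq = _sample_decamer(rng, dists, spec.regex_conform)
                protein_counter += 1
                pid = f"prot{protein_counter:06d}"
                peptides.append(
                    Peptide(sequence=seq, organism_id=org, protein_id=pid,
                            omp_class=omp_class, is_protein_cterminal=True)
                )
                class_rows.append({"protein_id": pid, "omp_class": omp_class})
    return SimulatedDataset(
        peptides=tuple(peptides),
        organisms=pd.DataFrame(org_rows),
        classes=pd.DataFrame(class_rows),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Wrapped proteins for end-to-end extraction testing


def wrap_as_proteins(
    dataset: SimulatedDataset,
    seed: int | None = None,
    flank_range: tuple[int, int] = (30, 80),
) -> tuple[list[str], list[str]]:
    """Embed each decamer at the C-terminus of a padded protein.

    Returns (fasta_lines, annotation_lines) in the package's file dialect:
    the decamer is marked 'S' in both the barrel and secondary-structure
    tracks, flanking residues are drawn from the non-Cys alphabet and left
    unannotated.
    """
    rng = np.random.default_rng(dataset.spec.seed + 1 if seed is None else seed)
    flank_alphabet = np.array(NON_C)
    fasta, annot = [], []
    for p in dataset.peptides:
        n_flank = int(rng.integers(*flank_range))
        flank = "".join(rng.choice(flank_alphabet, size=n_flank))
        seq = flank + p.sequence
        track = "-" * n_flank + "S" * 10
        rid = f"{p.organism_id}|{p.protein_id}"
        fasta.append(f">{rid}")
        fasta.append(seq)
        annot.append(f">{rid}")
        annot.append(f"barrel\t{track}")
        annot.append(f"ss\t{track}")
    return fasta, annot


def write_dataset(dataset: SimulatedDataset, outdir: str | Path, fasta: bool = False) -> None:
    """Write peptides.tsv, organisms.tsv, classes.tsv (and optional FASTA + tracks)."""
    from .extraction import write_peptides_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_peptides_tsv(dataset.peptides, outdir / "peptides.tsv")
    dataset.organisms.to_csv(outdir / "organisms.tsv", sep="\t", index=False)
    dataset.classes.to_csv(outdir / "classes.tsv", sep="\t", index=False)
    if fasta:
        fasta_lines, annot_lines = wrap_as_proteins(dataset)
        (outdir / "proteins.fasta").write_text("\n".join(fasta_lines) + "\n")
        (outdir / "tracks.txt").write_text("\n".join(annot_lines) + "\n")
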