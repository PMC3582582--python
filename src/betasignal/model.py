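"""Model/Results interface over the sequence-space analysis.

`SequenceSpaceModel` is built from a peptide table (or a list of
:class:`~betasignal.extraction.Peptide`); `fit()` runs the encoding ->
PCA -> per-entity Gaussian pipeline and returns a
:class:`SequenceSpaceResults` carrying the fitted spaces, the pairwise
Hellinger distance matrix and diagnostics, with layout, dendrogram and
positional statistics hanging off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import clustering, posstats, seqspace
from .descriptors import DescriptorTable, encode_peptides, load_descriptor_table
from .extraction import Peptide, dedupe_peptides, filter_organisms, frame_to_peptides
from .posstats import PositionQuery


class SequenceSpaceModel:
    """Per-entity Gaussian sequence-space model of C-terminal decamers.

    Parameters
    ----------
    peptides
        Extracted decamers with organism / OMP-class provenance.
    descriptor_table
        20 x 5 physicochemical scale; the packaged z-scales by default.
    min_unique
        Entities with fewer unique decamers are dropped (21 keeps organisms
        with more than 20 unique peptides, the headline filter).
    entity
        'organism' fits one Gaussian per organism; 'organism_class' splits
        organisms into (organism, OMP class) entities with at least
        ``min_unique`` unique peptides each.
    """

    def __init__(
        self,
        peptides: Sequence[Peptide],
        descriptor_table: DescriptorTable | None = None,
        min_unique: int = 21,
        entity: str = "organism",
    ) -> None:
        if entity not in ("organism", "organism_class"):
            raise ValueError("entity must be 'organism' or 'organism_class'")
        self.descriptor_table = descriptor_table or load_descriptor_table()
        self.min_unique = min_unique
        self.entity = entity
        self.peptides = list(peptides)
        if entity == "organism":
            self.entities: dict[str, list[Peptide]] = {
                org: dedupe_peptides(plist, scope="per_organism")
                for org, plist in filter_organisms(self.peptides, min_unique).items()
            }
        else:
            self.entities = {
                f"{org}/{cls}": dedupe_peptides(plist, scope="global")
                for (org, cls), plist in clustering.split_entities(
                    self.peptides, min_unique_per_class=min_unique
                ).items()
            }
        if len(self.entities) < 2:
            raise ValueError("need at least two entities passing the uniqueness filter")

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, descriptor_table: DescriptorTable | None = None, **kwargs
    ) -> "SequenceSpaceModel":
        """Build from a table with columns organism_id, protein_id, peptide[, omp_class]."""
        return cls(frame_to_peptides(frame), descriptor_table=descriptor_table, **kwargs)

    def fit(
        self,
        k: int | str = seqspace.DEFAULT_N_COMPONENTS,
        regularization: float = seqspace.DEFAULT_REGULARIZATION,
        shrinkage: float = 0.0,
        debias: bool = False,
    ) -> "SequenceSpaceResults":
        """Encode, reduce to ``k`` principal components, fit Gaussians, compare.

        PCA is fitted on the pooled unique peptides of all retained entities.

        Parameters
        ----------
        k
            Number of principal components, or ``"auto"`` to pick the
            smallest k whose cumulative explained variance reaches 69%
            (capped below the smallest entity size).
        shrinkage
            Covariance shrinkage intensity toward the pooled within-entity
            covariance (0 = plain per-entity sample covariances).
        debias
            Subtract the expected finite-sample inflation from the
            Mahalanobis term of each pairwise distance; recommended whenever
            entity sizes vary widely.
        """
        pooled = [p for plist in self.entities.values() for p in plist]
        encoded = encode_peptides(pooled, self.descriptor_table)
        if k == "auto":
            max_k = min(20, min(len(pl) for pl in self.entities.values()) - 1)
            k = seqspace.choose_n_components(encoded, max_k=max_k)
        pca = seqspace.fit_pca(encoded, k=k)
        reduced = pca.project(encoded.data)

        blocks: dict[str, np.ndarray] = {}
        offset = 0
        for eid, plist in self.entities.items():
            blocks[eid] = reduced[offset : offset + len(plist)]
            offset += len(plist)

        target = None
        if shrinkage > 0:
            # pooled within-entity covariance (entity means removed)
            scatter = sum(
                (b - b.mean(axis=0)).T @ (b - b.mean(axis=0)) for b in blocks.values()
            )
            dof = sum(len(b) for b in blocks.values()) - len(blocks)
            target = scatter / dof

        spaces = [
            seqspace.fit_gaussian(eid, block, regularization,
                                  shrinkage=shrinkage, shrinkage_target=target)
            for eid, block in blocks.items()
        ]
        distances = seqspace.pairwise_distances(spaces, debias=debias)
        return SequenceSpaceResults(model=self, pca=pca, spaces=tuple(spaces),
                                    distances=distances)


@dataclass(frozen=True)
class SequenceSpaceResults:
    """Fitted sequence spaces, their pairwise distances, and diagnostics."""

    model: SequenceSpaceModel
    pca: seqspace.PcaModel
    spaces: tuple[seqspace.SequenceSpace, ...]
    distances: seqspace.DistanceMatrix

    @property
    def entity_ids(self) -> tuple[str, ...]:
        return self.distances.entity_ids

    @property
    def weights(self) -> pd.DataFrame:
        """Overlap (Bhattacharyya) attraction weights, 1 - D_H^2."""
        return seqspace.distances_to_weights(self.distances)

    def layout(self, params: clustering.LayoutParams | None = None,
               contrast: bool = True) -> clustering.Layout:
        """CLANS-style force-directed 2-D map of the entities.

        ``contrast`` min-max rescales the overlap weights first; highly
        conserved signals give near-uniform overlaps under which the map
        collapses into a single blob.
        """
        w = seqspace.distances_to_weights(self.distances, contrast=contrast)
        return clustering.layout_clans(w, params)

    def cluster(self, n_clusters: int, seed: int = 0) -> pd.Series:
        """Partition entities by k-means on their Hellinger distance profiles."""
        return clustering.cluster_distance_profiles(self.distances, n_clusters, seed=seed)

    def dendrogram(self, n_boot: int = 0, seed: int = 0,
                   pseudocount: float = 0.5) -> clustering.Dendrogram:
        """PSSM-profile average-linkage dendrogram with bootstrap support."""
        profiles = clustering.pssm_profiles(
            {eid: [p.sequence for p in plist] for eid, plist in self.model.entities.items()},
            pseudocount=pseudocount,
        )
        return clustering.hcluster_profiles(profiles, n_boot=n_boot, seed=seed)

    def percent_at_position(self, position: int, residues: Iterable[str]) -> pd.DataFrame:
        """Per-entity percent of unique peptides with a query residue at +k."""
        return posstats.per_organism_position_profile(
            self.model.entities, PositionQuery.make(position, residues)
        )

    def summary(self) -> str:
        """Human-readable fit summary."""
        dm = self.distances.values
        n = len(self.entity_ids)
        off = dm[~np.eye(n, dtype=bool)]
        lines = [
            "Sequence-space model fit",
            "=" * 60,
            f"Entities:                  {n}",
            f"Peptides (unique, pooled): {sum(s.n_peptides for s in self.spaces)}",
            f"Descriptor dimensions:     {self.pca.components.shape[1]}",
            f"PCA components retained:   {self.pca.k}"
            f"  (explained variance {100 * self.pca.cumulative_explained:.2f}%)",
            f"Hellinger distance range:  [{off.min():.4f}, {off.max():.4f}]"
            f"  median {np.median(off):.4f}",
            "",
            f"{'entity':<28}{'n_unique':>9}{'mean D_H':>10}{'min D_H':>10}",
            "-" * 60,
        ]
        for i, s in enumerate(self.spaces):
            others = np.delete(dm[i], i)
            lines.append(
                f"{s.entity_id:<28}{s.n_peptides:>9}{others.mean():>10.4f}{others.min():>10.4f}"
            )
        return "\n".join(lines)

    def plot_map(self, params: clustering.LayoutParams | None = None, ax=None,
                 taxa: Mapping[str, str] | None = None):
        """Scatter the force-directed map (requires matplotlib)."""
        import matplotlib.pyplot as plt

        layout = self.layout(params)
        if ax is None:
            _, ax = plt.subplots()
        frame = layout.to_frame()
        if taxa:
            frame["taxon"] = [taxa.get(e, "") for e in frame["entity_id"]]
            for taxon, grp in frame.groupby("taxon"):
                ax.scatter(grp["x"], grp["y"], label=taxon, s=18)
            ax.legend(fontsize=7)
        else:
            ax.scatter(frame["x"], frame["y"], s=18)
        ax.set_xlabel("layout x")
        ax.set_ylabel("layout y")
        return ax
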