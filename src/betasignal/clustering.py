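"""Entity clustering: force-directed 2-D layout, PSSM dendrograms, controls.

Three independent views of the same question — do organisms group by the
composition of their C-terminal insertion signals?

* a simplified CLANS-style force-directed layout driven by pairwise overlap
  weights (attraction proportional to similarity, a small global repulsion
  that keeps highly similar nodes from collapsing into one point);
* hierarchical clustering of per-organism log2-odds position-specific
  scoring matrices (correlation distance, average linkage) with plain
  bootstrap support over resampled PSSM columns;
* the control transformations: within-peptide residue shuffling (destroys
  positional signal while preserving composition), OMP-class removal, and
  splitting organisms into (organism, OMP class) entities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .extraction import STANDARD_AA, OMP_CLASSES, Peptide, filter_organisms

logger = logging.getLogger(__name__)

#: OMP classes that are never removed in the class-removal control: their
#: strand number (and hence class membership) is unknown, so removing them
#: would not test the influence of a defined class.
PROTECTED_CLASSES = frozenset({"OMP.nn", "OMP.hypo"})


# ---------------------------------------------------------------------------
# Force-directed layout


@dataclass(frozen=True)
class LayoutParams:
    """Parameters of the force-directed layout.

    The defaults follow the regime that keeps near-identical sequence spaces
    from collapsing onto a single point: small attraction (up to 0.1) and
    high repulsion (up to 500).
    """

    attraction_scale: float = 0.1
    repulsion_scale: float = 500.0
    iterations: int = 400
    damping: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if self.attraction_scale <= 0 or self.repulsion_scale <= 0:
            raise ValueError("force scales must be positive")
        if not 0 < self.damping < 1:
            raise ValueError("damping must be in (0, 1)")
        if self.iterations <= 0:
            raise ValueError("iterations must be positive")


@dataclass(frozen=True)
class Layout:
    """2-D node coordinates produced by the force-directed layout."""

    entity_ids: tuple[str, ...]
    coordinates: np.ndarray
    params: LayoutParams
    converged: bool

    def __post_init__(self) -> None:
        if self.coordinates.shape != (len(self.entity_ids), 2):
            raise ValueError("coordinate shape does not match entity count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"entity_id": self.entity_ids,
             "x": self.coordinates[:, 0],
             "y": self.coordinates[:, 1]}
        )


def layout_clans(weights, params: LayoutParams | None = None) -> Layout:
    """Force-directed 2-D embedding of a symmetric similarity matrix.

    Nodes start at seeded random positions in the unit square.  Each
    iteration, node i feels an attraction ``attraction_scale * w_ij`` along
    the vector to node j, and a repulsion ``repulsion_scale / (n^2 *
    max(r, eps))`` away from every node j at distance r.  Displacements are
    damped and step-limited; the run is exactly reproducible given
    (weights, params).
    """
    params = params or LayoutParams()
    if isinstance(weights, pd.DataFrame):
        ids = tuple(map(str, weights.index))
        w = weights.to_numpy(dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
        ids = tuple(f"node{i}" for i in range(w.shape[0]))
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weights must be a square matrix")
    if np.isnan(w).any():
        raise ValueError("weights contain NaN")
    if not np.allclose(w, w.T, atol=1e-9):
        raise ValueError("weights must be symmetric")

    n = w.shape[0]
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    rng = np.random.default_rng(params.seed)
    pos = rng.random((n, 2))

    eps = 1e-9
    max_step = 0.5
    converged = False
    for _ in range(params.iterations):
        diff = pos[None, :, :] - pos[:, None, :]        # diff[i, j] = x_j - x_i
        r = np.sqrt((diff**2).sum(axis=2))
        np.fill_diagonal(r, np.inf)
        attract = params.attraction_scale * np.einsum("ij,ijk->ik", w, diff)
        rep_mag = params.repulsion_scale / (n**2 * np.maximum(r, eps))
        repel = -np.einsum("ij,ijk->ik", rep_mag / np.maximum(r, eps), diff)
        force = attract + repel
        step = params.damping * force
        norms = np.sqrt((step**2).sum(axis=1, keepdims=True))
        step = np.where(norms > max_step, step * (max_step / np.maximum(norms, eps)), step)
        pos = pos + step
        if float(np.abs(step).max()) < 1e-6:
            converged = True
            break

    return Layout(entity_ids=ids, coordinates=pos, params=params, converged=converged)


def cluster_distance_profiles(distances, n_clusters: int, seed: int = 0) -> pd.Series:
    """Partition entities by k-means on row-centered distance profiles.

    Each entity is represented by its vector of Hellinger distances to every
    entity.  Row-centering removes the entity-specific offset (small entities
    are uniformly farther from everyone because of sampling noise), leaving
    the profile shape, which is determined by which group the entity belongs
    to.  The noise of a profile entry is largely independent across the
    columns while the group signal is systematic, so profiles discriminate
    groups far better than individual pairwise distances do.
    """
    from sklearn.cluster import KMeans

    if hasattr(distances, "values") and hasattr(distances, "entity_ids"):
        ids = list(distances.entity_ids)
        V = distances.values
    elif isinstance(distances, pd.DataFrame):
        ids = list(map(str, distances.index))
        V = distances.to_numpy(dtype=float)
    else:
        V = np.asarray(distances, dtype=float)
        ids = [f"entity{i}" for i in range(V.shape[0])]
    profiles = V - V.mean(axis=1, keepdims=True)
    km = KMeans(n_clusters=n_clusters, n_init=50, random_state=seed)
    return pd.Series(km.fit_predict(profiles), index=ids, name="cluster")


# ---------------------------------------------------------------------------
# PSSM profiles and hierarchical clustering

AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}


def background_composition(peptides_by_entity: Mapping[str, Sequence[str]]) -> np.ndarray:
    """Pooled residue composition over all peptides of all entities.

    Shuffling residues within peptides leaves each residue's total count
    unchanged, so the shuffle-derived background equals the pooled
    composition in expectation; the pooled composition is used directly.
    """
    counts = np.zeros(20)
    for seqs in peptides_by_entity.values():
        for s in seqs:
            for aa in s:
                counts[AA_INDEX[aa]] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no peptides supplied")
    return counts / total


def pssm_profiles(
    peptides_by_entity: Mapping[str, Sequence[str]],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-entity 20x10 log2-odds PSSMs, flattened to 200-vectors.

    Positional relative frequencies (unique peptides as supplied by the
    caller) are divided by the pooled background composition and log2 is
    applied.  A small pseudocount ``pseudocount / n_peptides`` is added to
    every positional count before normalizing so that absent residues give
    a large negative score instead of -inf.  Row layout: positions (N to C)
    major, residues (alphabetical) minor.
    """
    if not peptides_by_entity:
        raise ValueError("no entities supplied")
    for eid, seqs in peptides_by_entity.items():
        if len(seqs) == 0:
            raise ValueError(f"entity {eid!r} has no peptides")
    background = background_composition(peptides_by_entity)
    if np.any(background == 0):
        # residues absent from the whole pool: tiny floor keeps log2 finite
        floor = (pseudocount if pseudocount > 0 else 0.5) * 1e-3
        background = np.where(background == 0, floor, background)
        background = background / background.sum()

    rows = {}
    for eid, seqs in peptides_by_entity.items():
        n = len(seqs)
        counts = np.zeros((10, 20))
        for s in seqs:
            for pos, aa in enumerate(s):
                counts[pos, AA_INDEX[aa]] += 1
        counts += pseudocount / n
        freqs = counts / counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore"):
            pssm = np.log2(freqs / background[None, :])
        rows[eid] = pssm.ravel()

    columns = [f"p{pos:02d}_{aa}" for pos in range(1, 11) for aa in STANDARD_AA]
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)


@dataclass(frozen=True)
class Dendrogram:
    """Average-linkage merge tree over entities with bootstrap support."""

    labels: tuple[str, ...]
    linkage: np.ndarray
    bootstrap_support: np.ndarray | None = None

    def clades(self) -> list[frozenset[str]]:
        """Leaf-label sets of the internal nodes, in merge order."""
        return _linkage_clades(self.linkage, self.labels)

    def to_newick(self) -> str:
        """Newick string with bootstrap support as internal node labels."""
        tree = hierarchy.to_tree(self.linkage)
        support = self.bootstrap_support

        def walk(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            label = ""
            if support is not None:
                label = f"{support[node.id - len(self.labels)]:.2f}"
            return f"({left},{right}){label}:{length:.6g}"

        return walk(tree, tree.dist) + ";"


def _correlation_condensed(profiles: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance; constant rows treated as maximally distant."""
    constant = profiles.std(axis=1) == 0
    if constant.any():
        logger.warning(
            "%d constant profile row(s): correlation undefined, treated as maximally distant",
            int(constant.sum()),
        )
    safe = profiles.copy()
    # give constant rows a dummy variation so pdist is defined, then overwrite
    safe[constant] += np.arange(profiles.shape[1])[None, :] * 1e-12
    dist = pdist(safe, metric="correlation")
    if constant.any():
        square = squareform(dist)
        square[constant, :] = 2.0
        square[:, constant] = 2.0
        np.fill_diagonal(square, 0.0)
        dist = squareform(square)
    return dist


def hcluster_profiles(
    profiles: pd.DataFrame | np.ndarray,
    n_boot: int = 0,
    seed: int = 0,
) -> Dendrogram:
    """Average-linkage clustering of PSSM profiles on correlation distance.

    Bootstrap support of an internal node is the fraction of ``n_boot``
    column-resampled replicates in which that node's exact leaf set reappears
    (plain bootstrap probability).  ``n_boot=0`` gives a deterministic tree
    with no support values.
    """
    if isinstance(profiles, pd.DataFrame):
        labels = tuple(map(str, profiles.index))
        X = profiles.to_numpy(dtype=float)
    else:
        X = np.asarray(profiles, dtype=float)
        labels = tuple(f"entity{i}" for i in range(X.shape[0]))
    if X.shape[0] < 2:
        raise ValueError("need at least two profiles")

    Z = hierarchy.linkage(_correlation_condensed(X), method="average")

    support = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        original = _linkage_clades(Z, labels)
        hits = np.zeros(len(original))
        m = X.shape[1]
        for _ in range(n_boot):
            cols = rng.integers(0, m, size=m)
            Zb = hierarchy.linkage(_correlation_condensed(X[:, cols]), method="average")
            boot_clades = set(_linkage_clades(Zb, labels))
            for i, clade in enumerate(original):
                if clade in boot_clades:
                    hits[i] += 1
        support = hits / n_boot

    return Dendrogram(labels=labels, linkage=Z, bootstrap_support=support)


def _linkage_clades(Z: np.ndarray, labels: Sequence[str]) -> list[frozenset[str]]:
    n = len(labels)
    members: dict[int, frozenset[str]] = {i: frozenset([labels[i]]) for i in range(n)}
    clades = []
    for i, (a, b, _, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + i] = merged
        clades.append(merged)
    return clades


# ---------------------------------------------------------------------------
# Controls


def shuffle_control(peptides: Iterable[Peptide], seed: int = 0) -> list[Peptide]:
    """Permute residue order uniformly within each peptide (seeded).

    Destroys all position-specific signal while preserving each peptide's
    residue multiset and all provenance labels — the negative control for
    positional clustering signal.
    """
    rng = np.random.default_rng(seed)
    out = []
    for p in peptides:
        letters = np.array(list(p.sequence))
        rng.shuffle(letters)
        out.append(
            Peptide(
                sequence="".join(letters),
                organism_id=p.organism_id,
                protein_id=p.protein_id,
                omp_class=p.omp_class,
                is_protein_cterminal=p.is_protein_cterminal,
            )
        )
    return out


def leave_out_class(
    peptides: Sequence[Peptide], omp_class: str, min_unique: int = 21
) -> list[Peptide]:
    """Remove one OMP class and re-apply the per-organism uniqueness filter.

    Classes of unknown strand number (OMP.nn, OMP.hypo) are never removed;
    requesting them returns the dataset unchanged with a warning.
    """
    if omp_class not in OMP_CLASSES:
        raise ValueError(f"unknown OMP class {omp_class!r}")
    if omp_class in PROTECTED_CLASSES:
        logger.warning("class %s is never removed; dataset unchanged", omp_class)
        return list(peptides)
    kept = [p for p in peptides if p.omp_class != omp_class]
    by_org = filter_organisms(kept, min_unique=min_unique)
    return [p for plist in by_org.values() for p in plist]


def split_entities(
    peptides: Iterable[Peptide], min_unique_per_class: int = 6
) -> dict[tuple[str, str], list[Peptide]]:
    """Split organisms into (organism, OMP class) entities.

    Only entities with at least ``min_unique_per_class`` unique decamers are
    retained; peptides without a class label are ignored.
    """
    groups: dict[tuple[str, str], list[Peptide]] = {}
    for p in peptides:
        if p.omp_class is None:
            continue
        groups.setdefault((p.organism_id, p.omp_class), []).append(p)
    return {
        key: plist
        for key, plist in groups.items()
        if len({p.sequence for p in plist}) >= min_unique_per_class
    }
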