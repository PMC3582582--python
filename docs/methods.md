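# Methods

## Overview

`betasignal` treats the C-terminal insertion signals of an organism's
outer-membrane β-barrel proteins (OMPs) as a *population* of points in a
physicochemical descriptor space, models that population as a multivariate
Gaussian (the organism's "peptide sequence space"), and quantifies
between-organism similarity as distributional overlap. The pipeline is:
decamer extraction → 50-dim encoding → PCA → per-entity Gaussian fit →
pairwise Hellinger distances → clustering and positional statistics.

## Decamer extraction

Inputs are protein sequences plus two per-residue strand tracks: a
barrel-topology prediction (which residues form transmembrane strands) and a
generic secondary-structure prediction. Per protein:

1. the last barrel-track strand segment is taken as the candidate motif;
2. at least 70% of its residues (`min_strand_fraction`) must also be strand
   in the secondary-structure track — disagreement between the two
   predictors marks likely false positives;
3. if the protein extends more than 4 residues (`max_cterm_extension`)
   beyond the motif, the motif is extended C-terminally by up to 4 residues
   to the first aromatic residue (F/Y/W) found; if the C-terminus is closer
   than that, the motif is simply extended to the protein end (the
   aromaticity requirement is *not* enforced in this branch — the final
   pattern match is the arbiter);
4. motifs shorter than 10 residues are extended N-terminally;
5. the motif is trimmed to its 10 C-terminal residues;
6. the decamer must match the alternating-hydrophobic pattern
   `[^C][YFWKLHVITMADGRE][^C][YFWKLHVITMADGRE][^C][YFWKLHVITMADGRE][^C].[^C][YFWHILM]`.

Decamers containing non-standard residues (X/B/Z/U) are rejected rather than
substituted, because the descriptor encoding is undefined for them. All
positions downstream use the +k convention: +1 is the C-terminal residue,
+k the k-th residue from the C-terminus (decamer index 11−k).

Deduplication is exposed at two scopes — within organism (the default for
fitting: the same decamer in two organisms is evidence for both) and global.
Organisms with more than 20 unique decamers are retained; below that a
12-dimensional Gaussian fit is not meaningful.

## Encoding

Each residue maps to the five principal-property scales z1–z5 (principal
components of a large panel of measured physicochemical variables —
lipophilicity, steric bulk/polarizability, polarity, electronic properties).
A decamer becomes the concatenation of its residues' 5-vectors in N→C order:
block k of 5 columns = residue k, 50 columns total. The packaged table
(`betasignal/data/zscales.tsv`) can be replaced by any 20×5 scale; all
downstream machinery is agnostic to the table's provenance.

## PCA

PCA centers but does not rescale columns (the five scales are already
variance-comparable principal properties). Components carry a deterministic
sign convention (largest-magnitude loading positive) so fits are exactly
reproducible. The default dimension is k=12. The number that *should* be
retained is data-dependent — the rule is "the smallest dimension that still
holds most of the variation while staying below the smallest entity size".
`choose_n_components` (and `fit(k="auto")`) operationalizes this as the
smallest k whose cumulative explained variance reaches 69%, capped at
min(20, smallest entity − 1). On the synthetic default data this selects
k=17: the synthetic background is deliberately close to uniform within each
position's residue class, so variance spreads over more components than in
real, strongly conserved β-signals.

## Gaussian fits and small-sample estimation

Per entity: μ = column means, Σ = unbiased (n−1) sample covariance, plus a
tiny ridge `1e-6 · (trace/d) · I` that keeps near-degenerate fits
positive-definite. Two optional estimators matter when entities hold only
21–171 peptides in d = 12–17 dimensions:

* **Covariance shrinkage** (`fit(shrinkage=λ)`): Σ_entity is replaced by
  (1−λ)·Σ_entity + λ·Σ_pooled, where Σ_pooled is the pooled within-entity
  covariance. At n ≈ 50, d ≈ 12 the sample covariance is noise-dominated
  (its log-determinant alone fluctuates by O(d²/n)); most of the
  covariance structure is shared across entities, so heavy shrinkage
  (default λ = 0.8 in the synthetic pipeline) trades a little
  entity-specific structure for a large variance reduction while keeping a
  per-entity component.
* **Distance debiasing** (`fit(debias=True)`): the squared Mahalanobis term
  of each pairwise distance is reduced by its expected value under equal
  distributions, d·(1/n₁+1/n₂)/2, floored at zero. Without this, entities
  with few peptides are systematically far from *everything* — the map
  shows sample size, not biology (small organisms drift to the periphery).

Both options default to off; the plain estimator reproduces the textbook
plug-in fit.

## Hellinger distance

For Gaussians, the Bhattacharyya coefficient (overlap) has the closed form

    BC = 2^{d/2} (det Σ₁ det Σ₂)^{1/4} / det(Σ₁+Σ₂)^{1/2}
         · exp(−¼ (μ₁−μ₂)ᵀ(Σ₁+Σ₂)^{−1}(μ₁−μ₂))

and D_H = √(1 − BC) ∈ [0, 1]. The implementation works in log-determinant
form via Cholesky factors and solves the quadratic form rather than forming
inverses; d = 12–17 poses no conditioning issues. Squared distances below
1e-12 are snapped to zero (the √ would otherwise amplify ~1e-16 roundoff
into spurious ~1e-8 distances between identical distributions). The
implementation is verified against brute-force numerical integration of
∫√(p·q) in one and two dimensions, and against the univariate closed form
(`hellinger_1d`), e.g. N(0,1) vs N(0,25) → 0.6163, N(0,1) vs N(5,1) →
0.9778.

## Clustering

**Force-directed map.** Entities start at seeded random positions in the
unit square; per iteration each node feels attraction
`attraction_scale · w_ij` along the vector to node j and repulsion
`repulsion_scale / (n² · r)` away from every node, with damped,
step-limited displacements. Defaults (attraction 0.1, repulsion 500) are
the small-attraction / high-repulsion regime needed to keep highly similar
nodes from collapsing onto one point. Attraction weights are the overlaps
w = 1 − D_H² = BC; because conserved signals give near-uniform overlaps, the
layout entry point min-max rescales the off-diagonal weights by default
(monotone, order-preserving — the role that significance transforms play in
graph-layout tools). The map is a visualization: k-means on its 2-D
coordinates recovers strongly contrasted groups (within-weight 0.9 vs
between 0.1 → ARI 1.0) but is lossy for weak contrasts.

**Distance-profile clustering** is the quantitative readout: each entity is
represented by its row of the Hellinger matrix, row-centered (removing the
entity-specific sampling-noise offset), and k-means is run on these
profiles. The noise in a profile entry is largely independent across
columns while group membership shapes the whole profile, so this aggregates
the n−1 distances per entity instead of judging single noisy pairs.

**PSSM dendrograms.** Per entity, a 20×10 positional frequency matrix is
converted to log2 odds against the pooled residue composition of all
peptides (shuffling residues preserves composition, so the shuffle-derived
background equals the pooled composition in expectation — the pooled form
is deterministic). A pseudocount of 0.5/n per positional count avoids
log2(0); residues absent from the entire pool get a floored background so
scores stay finite. Profiles are clustered by 1 − Pearson correlation with
average linkage; constant profiles (correlation undefined) are treated as
maximally distant (distance 2) with a logged warning. Bootstrap support of
an internal node is the fraction of column-resampled replicates in which
its exact leaf set reappears (plain bootstrap proportions; no multiscale
correction). Trees export to Newick with support as internal node labels.

**Controls.** (1) Within-peptide residue shuffling destroys positional
signal while preserving each peptide's composition — the negative control
for everything positional. (2) OMP-class removal drops one strand-number
class and re-applies the >20-unique filter; classes of unknown strand
number (OMP.nn, OMP.hypo) are never removed. (3) Entity splitting forms
(organism, OMP class) entities with ≥6 unique peptides, separating the
taxonomic from the OMP-class contribution to the signal.

## Positional statistics

Position-frequency matrices are built from unique decamers (deduplicated
within the plotted group, after pooling). `percent_at_position` computes
the percentage of peptides carrying a residue from a query set at a +k
position on the peptides exactly as supplied — the caller chooses unique vs
all. Logo rendering is delegated to external tools fed by the PFM export,
which records hydrophobic/polar color classes as metadata.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:
4 taxa × 10 organisms, 21–171 decamers per organism (uniformly drawn),
per-position categorical residue distributions built on the extraction
pattern's own position classes (so samples are pattern-plausible by
construction; rejection sampling enforces exact conformity). Background
positions are uniform within their allowed class except +2, which carries
the typical 30% Arg/Lys mass. The planted taxa:

* *Neisseria-like*: P(R∪K at +2) = 0.65 — the >60% positive-charge
  phenotype;
* *beta-like*: OMP.16 (general porins) at 60% of the class mix, with
  P(H at +3 | OMP.16) = 0.5 — the porin-borne His signal;
* *Helicobacter-like*: P(Y at +5) = 0.5;
* *background*: no planted signal beyond the 30% Arg/Lys level.

OMP classes are drawn per peptide from the taxon's mix; `wrap_as_proteins`
embeds decamers at the C-terminus of randomly padded proteins with matching
annotation tracks for end-to-end extraction tests (recovery ≥ 99%).

What the generator does **not** emulate: the strong residue conservation of
real β-signals (real positional distributions are far more peaked than
uniform-within-class, which is why the synthetic data needs k≈17 components
where real data needed 12), phylogenetic covariance between taxa,
within-organism homology structure, and duplicate peptides from paralogs.
Passing tests therefore demonstrate that the machinery detects positional
signals of realistic effect size against realistic sampling noise — not
that any particular real organism pair is separable.

With the estimator settings above (k="auto", shrinkage 0.8, debias), the
full pipeline separates the four planted taxa at ARI ≈ 0.87–1.0 over seeds
0–4 via the distance-profile readout, and the shuffle control collapses
this to |ARI| ≤ ~0.1. The 2-D force-map readout under the same conditions
reaches only ARI ≈ 0.3: a planar embedding of 40 weakly contrasted
entities cannot express the full distance structure, which is precisely why
the profile readout exists.

## Numerical choices and limitations

* Deterministic everywhere: seeded generators, PCA sign convention,
  first-occurrence tie-breaks in deduplication.
* Degenerate inputs: singular covariances raise unless the ridge or
  shrinkage applies; empty entities and empty peptide lists raise;
  length-mismatched annotation records are skipped with warnings rather
  than aborting a whole file.
* The Hellinger estimator is a plug-in (or shrunk plug-in) estimator; no
  significance testing of distances is attempted.
* Problem sizes in tests and the acceptance script are the generator's
  defaults (≈3,800 peptides, 40 organisms); all headline numbers recompute
  in seconds on one CPU.
* Descriptive statistics only: the positional percentages carry no
  enrichment tests, matching their exploratory role.
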