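# betasignal

Sequence-space analysis of the C-terminal insertion signal of Gram-negative
outer-membrane β-barrel proteins (OMPs).

## The problem

OMPs are folded into the outer membrane by the BAM complex, which recognizes
an unfolded substrate through its last transmembrane β-strand — the
C-terminal insertion signal, a short amphipathic strand typically ending in
an aromatic residue. Whether this signal is species-specific matters
practically: it decides whether an OMP from one organism can be functionally
overexpressed in another (e.g. for vaccine antigen production in *E. coli*).
Because the signals are short (10 residues) and highly conserved, ordinary
sequence clustering fails; the question has to be asked distributionally —
how strongly do the *populations* of signal peptides of two organisms
overlap?

`betasignal` is for computational microbiologists who want to quantify that
overlap. It:

1. extracts 10-residue C-terminal β-strands ("decamers") from annotated
   protein sequences, with strand-support filtering and an
   alternating-hydrophobic pattern check;
2. encodes each decamer as a 50-dimensional vector using five
   physicochemical principal-property scales (z1–z5) per residue;
3. reduces the encoding by PCA and fits, per organism, a multivariate
   Gaussian "peptide sequence space" N(μ, Σ);
4. compares organisms by the Hellinger distance between their Gaussians,

       D_H²(Org₁, Org₂) = 1 − BC(Org₁, Org₂),

       BC = 2^{d/2} (det Σ₁ det Σ₂)^{1/4} / det(Σ₁+Σ₂)^{1/2}
            · exp(−¼ (μ₁−μ₂)ᵀ(Σ₁+Σ₂)^{−1}(μ₁−μ₂)),

   with D_H ∈ [0, 1]: 0 for identical spaces, 1 for disjoint ones;
5. clusters organisms from the pairwise overlaps — a CLANS-style
   force-directed 2-D map, k-means on Hellinger distance profiles, and a
   PSSM-profile dendrogram (correlation distance, average linkage, bootstrap
   support);
6. computes the positional statistics behind the biology: percent Arg/Lys at
   the +2 position, His at +3, Tyr at +5 (+k counted from the C-terminus,
   +1 = terminal residue);
7. generates seeded synthetic datasets with planted taxon-specific
   positional signals, so the whole pipeline is testable end to end without
   any downloads.

## Worked example

```python
import betasignal as bs

# a seeded synthetic dataset: 4 taxa x 10 organisms, 21-171 decamers each,
# with planted signals (Arg/Lys at +2, His at +3 in porins, Tyr at +5)
dataset = bs.generate(bs.default_spec(seed=0))

model = bs.SequenceSpaceModel(list(dataset.peptides))
results = model.fit(k=12)
print(results.summary())
```

```
Sequence-space model fit
============================================================
Entities:                  40
Peptides (unique, pooled): 3816
Descriptor dimensions:     50
PCA components retained:   12  (explained variance 56.26%)
Hellinger distance range:  [0.3054, 0.8829]  median 0.5487
...
```

Forty organisms pass the >20-unique-peptides filter; 12 principal components
carry ~56% of the descriptor variance, and every pairwise distance sits well
inside (0, 1): the sequence spaces overlap broadly, with no two organisms
either identical or disjoint.

```python
# percent of unique peptides with Arg/Lys at the penultimate (+2) position
table = results.percent_at_position(2, "RK")
print(table.groupby(table.organism_id.str.rsplit("_org").str[0])["percent"].mean())
```

```
background           30.8
beta_like            27.9
helicobacter_like    30.0
neisseria_like       65.2
```

The Neisseria-like taxon sits above 60% positive charge at +2 while all
other taxa show the ~30% background level — the planted phenotype.

Small-sample estimation options matter when entities hold only dozens of
peptides in 12+ dimensions: `model.fit(k="auto", shrinkage=0.8, debias=True)`
selects the PCA dimension by a variance target, shrinks per-organism
covariances toward the pooled covariance, and removes the expected
finite-sample inflation from each distance. With those settings the
end-to-end pipeline recovers the four planted taxa (adjusted Rand index
≈ 0.9 across seeds), and collapses to ARI ≈ 0 after the within-peptide
residue shuffle control — positional signal, not composition, drives the
clustering.

A command-line interface mirrors the library:

```sh
betasignal simulate --seed 3 -o sim --fasta
betasignal extract --fasta sim/proteins.fasta --annot sim/tracks.txt -o peptides.tsv
betasignal space --peptides peptides.tsv -o spaces/
betasignal dist --distances spaces/hellinger.tsv -o weights.tsv
betasignal cluster --weights weights.tsv --seed 0 -o layout.tsv
betasignal pssm-clust --peptides peptides.tsv --nboot 100 -o tree.nwk
betasignal stats --peptides peptides.tsv --position +2 --residues RK -o plus2.tsv
```

## Documentation

`docs/methods.md` describes the model, the estimators and their defaults,
what the synthetic generator does and does not emulate, and the package's
numerical choices and limitations.
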