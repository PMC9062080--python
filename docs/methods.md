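# Methods

## The problem

A/B compartments — the classic bipartition of chromatin into active (A) and
inactive (B) groups from the sign of the leading eigenvector (EV1) of an
intra-chromosomal Hi-C O/E matrix — leave a substantial part of the genome
ambiguous: short regions whose EV1 value is near zero. This package calls
four compartmental states per chromosome. The two "major" states A1
(euchromatin) and B1 (constitutive heterochromatin) correspond to the
canonical compartments; the two "micro" states A2 (weakly active euchromatin)
and B2 (H3K27me3-marked facultative heterochromatin) are short regions
embedded in the major state of opposite activity, resolved by the second
informative eigenvector (EV2).

## The model

The O/E matrix A of one chromosome (observed contacts divided by the mean
contact at the same separation) is treated as the weighted adjacency matrix
of a contact graph. Its modularity matrix is

    B_ij = (A_ij − r · k_i k_j / 2m) / 2m

with k_i the full row sum of A (diagonal included), m = Σ_ij A_ij / 2 and
resolution r = 1. The modularity of a partition is

    Q = Σ_{i,j in the same community} B_ij

with the i = j diagonal terms included. With these conventions Q reproduces
Newman's Σ_c (e_cc − a_c²) identity exactly; the two-dyad worked example
(edges 1–2, 3–4, split by component) gives Q = 1/2, and an exhaustive
enumeration oracle confirms equality to 1e-12 on random small graphs.

The calling pipeline:

1. **Centromere-effect correction.** Each of the top `n_top` (default 10)
   eigenvectors by |eigenvalue| gets an arm-bias index
   I = (|mean sign over p-arm| + |mean sign over q-arm|) / 2.
   I ≤ 0.4 leaves the component untouched; 0.4 < I < 0.5 subtracts the
   vector's per-arm means; I ≥ 0.5 zeroes its eigenvalue. The matrix is
   rebuilt from the modified system. Note the formula assigns I = 1 to any
   one-signed vector, so the near-constant Perron ("coverage") component of a
   non-negative O/E matrix is also removed; this is harmless — its
   sign-bipartition has Q_EV ≈ 0 and would never be selected — and in effect
   centres the matrix. Acrocentric chromosomes (no assessable p-arm) skip the
   correction. Tiny negative entries produced by the rebuild are clipped at 0
   to keep the O/E non-negativity contract.
2. **Eigenvector selection by modularity.** The corrected matrix is
   re-decomposed; each top eigenvector defines a sign-bipartition (zeros
   grouped with the positive side) whose modularity Q_EV ranks it. The two
   best-ranked vectors become EV1 and EV2. This replaces the manual
   principal-component curation that PCA-based compartment callers need.
3. **K-means.** Bins are clustered (k = 4, k-means++, `n_init` = 10, fixed
   seed) in the 2-D space (|λ₁|·EV1, |λ₂|·EV2). Weighting by |eigenvalue| is
   the natural SVD scaling; λ² weighting was considered and rejected as
   unsupported.
4. **Constrained Louvain refinement.** Nodes are swept in genomic order; each
   node moves to whichever of the k seeded communities maximizes ΔQ, until a
   sweep makes no move. No new communities are created and there is no
   agglomeration phase, so refinement cannot destroy the four-state scheme
   (a community may still empty). Q is non-decreasing by construction, and an
   incremental-gain bookkeeping (per-community affinity sums updated per
   move) matches a full Q re-evaluation reference on random instances.
5. **State naming.** Highest mean EV1 → A1, lowest → B1. Of the remaining
   two clusters, the one with the higher H3K27me3-like signal → B2, the other
   → A2. Without an H3K27me3 track the lower-mean-EV1 cluster falls back to
   B2 and the call is flagged `micro_oriented = false`; without an activity
   track the A/B orientation of EV1 itself is arbitrary (flagged
   `oriented = false`). This fallback is our design choice, not something the
   A2/B2 definition pins down without a track.

Supporting scores: compartmentalization strength of an eigenvector,
Cs = (mean A over p90×p90 + mean over p10×p10) / (2 · mean over p90×p10),
where p90/p10 are bins above the 90th/below the 10th percentile of the
vector; silhouette (cosine distance, scikit-learn) and Calinski–Harabasz for
comparing partitions in the same eigen-feature space; and state-pair mean
interaction matrices (self-pairs excluded) on O/E or correlation matrices.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| resolution (bin size) | 100 kb | binning of the contact map (50 kb supported) |
| r | 1 | modularity resolution |
| I thresholds | 0.4 / 0.5 | arm-bias branches (balance / zero) |
| n_top | 10 | eigenvectors screened and ranked |
| k | 4 | clusters (the four-state scheme) |
| n_init | 10 | k-means restarts |
| seed | 7 | master seed (k-means; random-order sweeps if chosen) |
| Louvain order | genomic | deterministic sweep order |

Masking: bins with zero contact marginal, non-finite rows, or (when tracks
are supplied) missing track data are excluded from decomposition and
clustering and reported as state `NA`. Track binning marks a bin missing when
more than half its length is uncovered (`min_coverage`, configurable).

## Downstream analytics

Segmentation is run-length encoding of per-bin states (NA splits runs).
Border classification compares the four-state and A/B junction positions at
exact bin-edge equality (tolerance 0 — no tolerance is defined for the
method). Neighbourhood enrichment tests the six adjacent state-pair types
against a minimal length-preserving null: region labels are shuffled, region
lengths and positions stay fixed, and same-label junctions after shuffling
are dropped. Conservation of a region across cell lines is
(n_A − n_B)/N, each line voting by the majority A/B label over the region's
bins (a line with an exact tie or an all-NA call over the region does not
vote). Signal enrichment is state median over genome-wide median; annotation
(ChromHMM-style) enrichment is the mean covered-bp proportion in the state
over the genome-wide mean. Switch/expression concordance ranks states by
activity B1 < B2 < A2 < A1 (B < A for the baseline, which follows the sign
of EV1, not collapsed state names); a differential gene is concordant when
its rank-change direction matches the sign of its expression change. The
built-in DEG filter keeps genes with >50% change relative to the smaller
FPKM and p < 0.05, with a 0.01 pseudocount guarding zero FPKM.

## The synthetic generator

`generate_truth` plants alternating long A1/B1 blocks (geometric lengths,
mean 30 bins) with short micro runs (geometric, mean 3 bins) started at rate
1/6 per eligible bin — B2 only inside A1, A2 only inside B1, always separated
from block edges so each micro run is genuinely embedded. These defaults put
the major states near 70% of the chromosome and the micro states near 30%,
the regime the method targets, and were fixed by simulation before any
end-to-end evaluation. A centromere gap (2% of bins, invalid) exercises the
masking and arm-annotation paths.

`generate_matrix` draws entry (i, j) from a state-pair affinity table
(within-state 1.6/1.4 > same-activity cross 1.1 > opposite-activity cross
0.8 > A2–B2 0.7 > A1–B1 0.4) times symmetric multiplicative log-normal noise
(σ = 0.2, preserving non-negativity). Distance decay is off by default — an
O/E transform removes decay, so a planted O/E-like matrix should be
decay-free — but a power-law factor can be enabled to exercise the O/E
normaliser. `generate_tracks` emits matched active-mark (A1 > A2 > B2 ≈ B1),
H3K27me3-like (high only on B2) and expression (A1 > A2 > B2 ≥ B1) tracks
with Gaussian noise clipped at 0.

**What the generator does not emulate:** distance-dependent contact decay
beyond a global power law, TADs and loops, sequencing-depth heterogeneity,
copy-number artefacts, translocation effects, and inter-chromosomal context.
Passing recovery tests therefore demonstrate the correctness of the
modularity/SVD machinery on plaid-structured input, not calling accuracy on
real Hi-C libraries.

## Numerical choices and edge cases

- Eigenvector sign convention: positive-count majority, ties broken by making
  the first nonzero entry positive. sign(0) contributes 0 to the arm-bias
  index; zero entries join the positive side in sign-bipartitions.
- Dense eigendecomposition (`numpy.linalg.eigh`) restricted to valid bins;
  eigenvalues ordered by descending absolute value with a stable sort.
- Louvain move tolerance 1e-12 on ΔQ; k-means ties resolved by scikit-learn's
  deterministic seeded restarts.
- Calinski–Harabasz returns `inf` when the within-cluster dispersion is
  exactly zero; silhouette of a singleton cluster point is 0.
- A cell line with a tied A/B vote over a region abstains from the
  conservation score.
- Matrices are scored on the corrected O/E matrix for modularity comparisons
  (whether the original comparison used O/E or correlation graphs is
  unspecified; we fix O/E and report it).

## Problem sizes

Recovery and structural-mirror experiments run on 2000-bin chromosomes
(200 Mb at 100 kb), 20 seeds for recovery; oracle checks enumerate all
bipartitions of graphs with ≤ 12 nodes and 50 random metric instances. A
known scale limitation: on chromosomes shorter than roughly 500 bins at the
default contrast, the micro states' total edge weight falls below the
modularity resolution limit and Louvain refinement may merge a micro state
into its host (reported as a 3-cluster call with generic naming rather than
silently mislabelled).

## Known limitations

- Per-chromosome calling only; no genome-wide joint clustering or
  trans-contact subcompartments.
- No matrix balancing: whatever normalisation the input carries is accepted.
- A2/B2 identity is undefined without an H3K27me3-like track (flagged, not
  guessed).
- The `.cool`/`.mcool` reader needs the optional `cooler` dependency; dense
  text matrices are always supported.
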