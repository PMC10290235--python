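# Methods

This note documents the statistical models, defaults and numerical
conventions implemented in `screenlink`, and what the synthetic-data
generator does and does not emulate.

## Data model

Both screen types share one carrier: an entities × cell-lines real matrix
(`DependencyMatrix`). Gene-effect scores are dimensionless fitness effects
of CRISPR knockout (more negative = stronger dependency; −1 is the
conventional per-line essentiality cutoff). Drug-response values are
log-fold changes in viability (negative = inhibition). Missing entries are
kept as missing and handled per-operation; they are never imputed, because
pooled drug screens are sparse by design and imputation would change every
downstream statistic. Gene labels may carry a numeric-ID suffix
(`"SYMBOL (1234)"`); matching against annotations is by bare symbol after
optional stripping. After harmonization the common cell lines are sorted
lexicographically so outputs do not depend on input column order.

## Correlation engine

Correlations are pairwise-complete Pearson: for each pair of profiles,
positions missing in either are dropped and ρ is computed over the
remaining n observations. Significance uses the exact transform
t = ρ√((n−2)/(1−ρ²)) against Student-t with n−2 degrees of freedom,
two-sided by default (sidedness of the original analyses is not stated;
two-sided is the conservative choice). |ρ| = 1 reports p = 0.

* `min_pairs` (default 30): pairs with fewer complete observations are
  skipped and logged. The source analyses correlate over hundreds of lines
  and state no floor; 30 keeps the t approximation stable. Configurable.
* Zero-variance profiles are skipped, not reported as ρ = NaN.
* The all-pairs path uses indicator-masked cross-products (single matrix
  products for n, Σx, Σx², Σxy). Its contract is numerical equality with
  the scalar path to 1e−10, which the test suite enforces on random pairs;
  catastrophic cancellation is guarded by treating tiny negative variances
  as zero variance.
* Rankings: `signed_desc` is the default (a drug mimicking a knockout
  correlates positively with it); `absolute_desc` is available for
  exploratory use. Ties break lexicographically on the partner ID so
  results are deterministic.
* Lineage-scoped queries recompute correlations over that lineage's cell
  lines only; they never reuse pan-cancer tables.

## Network construction

Edges are kept when signed ρ ≥ per-class cutoff (gene–gene, drug–drug,
gene–drug); degree-0 nodes are dropped. Signed thresholding builds a
similar-effect network, which is what clusters same-pathway inhibitors
together; an absolute mode keeps strong anti-correlations too (the original
choice is unstated; signed is the default here because the downstream
interpretation — drug as knockout surrogate — is directional). Negative
cutoffs are rejected in signed mode rather than silently reinterpreted.

Cutoff selection implements "largest average node degree at a visualizable
size" literally: exhaustive grid search over per-class cutoff candidates,
maximizing 2|E|/|V| subject to |V| ≤ `max_nodes` (default 600, on the order
of the published 519-node network), ties broken by fewer nodes and then by
the larger gene–drug cutoff. The grids used here are small (≤ ~10 values
per class), so exhaustive evaluation is cheap and no refinement heuristic
is applied.

Hub-query networks select the top-k drug partners of the hub and each
drug's top-k gene partners from the *full* correlation tables (not the
thresholded network), then add any edge among included nodes that passes
the global cutoffs when those are supplied.

## Drug-target validation

For threshold t on gene–drug correlations, with margins fixed:
O = #{annotated pairs with ρ ≥ t},
E = |annotated| · |passing| / |all pairs| (independence of annotation and
passing status), and significance is the right-tailed Fisher exact test on
the 2×2 table, i.e. the hypergeometric upper tail P(X ≥ O). The tail is
evaluated in log space via `scipy.stats.hypergeom.sf`, exact for tables
with millions of pairs; the test suite cross-checks it against explicit
integer-factorial enumeration for every table with total ≤ 60. Passing uses
signed ρ by default, for the same directional reason as above. Coverage and
hit fractions are reported to one decimal percent. Phase stratification
restricts the annotated set only; the passing universe is unchanged, so a
phase's O/E is comparable to the unstratified one.

## Signature queries

A perturbagen's score for a query gene list is the mean of its signature
z-scores over the listed genes (duplicates collapsed; genes absent from the
matrix dropped with a warning). The null is size-matched: `n_perm` random
gene sets of the same size, drawn without replacement from the *measured*
genes (conditioning on assay coverage rather than the whole genome), scored
identically; p = (1 + #{null ≤ observed})/(n_perm + 1) for direction
`down`, mirrored for `up`, doubled smaller tail for `two_sided`. The
add-one correction bounds p below by 1/(n_perm+1) and avoids p = 0.
q-values are Benjamini–Hochberg across perturbagens. Default
n_perm = 10,000; permutation row sums are the runtime driver and scale
linearly in n_perm. The mean-z statistic with a size-matched null is the
simplest defensible connectivity score for this query; enrichment-style
weighted statistics are deliberately out of scope.

## Fingerprints

Three schemes: `maccs` (the public 166-key MACCS definition, via rdkit;
rdkit's unused bit 0 is dropped so indices are 0–165), `pubchem` (an 881-bit
substructure-key fingerprint), and `combined` (1047 bits; MACCS first, the
881-bit section at offset 166 — concatenation order does not affect
Tanimoto). The 881-bit layer is an in-house catalogue built from four
deterministic sections — element-count thresholds (115 bits), ring features
by size 3–10 from SSSR perception (104), bonded element pairs (66), and a
systematically generated SMARTS pattern list (596) — matching the published
881-bit substructure-key *layout* in length and spirit but not bit-for-bit
compatible with externally computed fingerprints; it is intended for
within-library similarity ranking, where only internal consistency matters.
Precomputed fingerprint tables (TSV of set-bit indices) are accepted at
query time so the chemistry backend is not required for search.

Tanimoto similarity is |A∩B|/|A∪B|; two empty fingerprints score 0 by
convention (affects only degenerate molecules). Ranked output reports the
shared/size counts alongside the similarity, to 4 decimals (2-decimal
display is formatting only).

## Synthetic data

`generate_screens` plants gene–drug links in a Gaussian latent-factor
model: each planted link carries its own latent factor f ~ N(0,1) per cell
line; the gene row is f + ε and the drug row a·f + ε′ with independent
ε ~ N(0, σ²), a ∈ (0,1]. The planted Pearson correlation has the closed
form a/√((1+σ²)(a²+σ²)), used as an oracle in the tests. Factors are
independent across links so rank-1 recovery of the matched partner is
well-posed. Unlinked rows are independent noise with the same marginal
variance as planted rows. Default study conditions: a = 0.6, σ = 0.6
(planted ρ ≈ 0.61, comfortably above the 0.27 network cutoff but far from
degenerate), panels of ~30–60 genes/drugs over 200–456 cell lines,
drug-matrix missingness 10% completely at random. Lineages are assigned
round-robin from a fixed 10-label list.

`generate_signatures` draws background z ~ N(0,1) and shifts a planted
perturbagen's gene set by −δ (knock-down-like), default δ = 3 with 20-gene
sets. `generate_chemistry` is a fixed 10-molecule panel with two analogue
pairs differing by a single substituent (an arylpropionic acid and its
methyl ester; two xanthines) plus six structurally unrelated fillers.

What the generator does *not* emulate: copy-number and guide-efficacy
artifacts of CRISPR screens, dose–response structure, batch effects,
informative missingness, correlated gene modules, and realistic chemical
library diversity. Passing tests therefore demonstrate that the statistics
recover planted structure under a clean additive-noise model — not that
they are robust to every failure mode of real screening data.

## Problem sizes and determinism

The test suite and the acceptance script run replicated simulations at
moderate sizes (50–60 genes × 30–40 drugs × 200 cell lines, 20–50
replicates; 1,000 permutations for signature queries), chosen so the whole
suite completes in well under a minute while leaving the planted-recovery
and calibration margins wide. Null calibration of signature p-values pools
runs of 200 perturbagens across several seeds before the
Kolmogorov–Smirnov comparison, since a single 200-value sample has KS
fluctuation of the same order as the tolerance. Every stochastic component
takes an explicit integer seed (numpy `default_rng`); the CLI threads one
`--seed` through all generators, and reruns are byte-identical apart from
manifest timestamps.

## Known limitations

* The 881-bit fingerprint is not interoperable with externally computed
  substructure fingerprints; use the MACCS scheme when comparing against
  other tools.
* Pearson-only: rank correlations and covariate adjustment are out of
  scope, so heavy-tailed screens are analyzed as-is.
* The O/E expected count assumes pairs are exchangeable under the null;
  structured annotation (many drugs sharing one target) is reflected in the
  Fisher test margins but not modelled beyond that.
* Lineage-scoped correlations can rest on few cell lines; the `min_pairs`
  floor guards significance but small-lineage estimates remain noisy.
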