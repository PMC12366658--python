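# Methods

## The decomposition model

Each measurement of a gene (or any positive cellular trait) in one
species–environment combination is modeled as the product of a cell-intrinsic
factor, set by the cell's own genotype, and a cell-extrinsic factor, set by
the surrounding tissue: `HM = I_M·E_M`, `HR = I_R·E_R`, `DM = I_M·E_R`,
`DR = I_R·E_M`. On a log2 scale the quartet is a saturated 2×2 two-factor
table, and the framework's estimates are exactly the closed-form
least-squares effects of that table under ±½ effect coding:

- `I = (I1+I2)/2` with `I1 = log2(HR/DM)`, `I2 = log2(DR/HM)` — the species
  main effect (rat − mouse);
- `E = (E1+E2)/2` with `E1 = log2(DM/HM)`, `E2 = log2(HR/DR)` — the
  environment main effect (rat-like − mouse-like);
- `N = (I1−I2)/2 = (E2−E1)/2` — the species×environment interaction, i.e.
  the matched-vs-mismatched contrast `½·log2(HM·HR/(DM·DR))`.

The identity `E2−E1 = I1−I2 = 2N` holds by construction and is asserted
row-wise in the tests, as is exact agreement with an independent
`numpy.linalg.lstsq` fit of the 2×2 table.

**Sign conventions.** Positive `I`/`E` mean higher in rat cells / the
rat-like environment. Positive `N` means higher in species-*matched*
environments. Two invariances follow from the algebra and are tested:
relabeling the species (swap HM↔HR, DM↔DR) negates `I` and `E` but leaves
`N` fixed; relabeling the environments (swap HM↔DM, HR↔DR) negates `E` and
`N` but leaves `I` fixed. Because user-facing statements about imprinting
are naturally phrased as "higher in mismatched environments", the
signed-mode imprinted enrichment ranks genes by the mismatch-oriented
`−signed_Np`, so a positive enrichment score means the set is up in
mismatched environments.

**Proportions.** `Ip = |I|/(|I|+|E|+|N|)` etc.; they sum to 1 whenever at
least one component is nonzero, and are NaN (with the gene failing the
divergence filter) when all three are zero. The divergence-evidence filter
requires |log2FC| strictly greater than 0.5 in at least one of I1, I2, E1,
E2; genes failing it are kept in the output with a flag rather than dropped,
so joins across cell types stay stable.

**Known bias.** Measurement noise enters `I` once per estimate but `N` (a
difference of estimates) twice, so noise inflates the interaction and, to a
lesser degree, the extrinsic component. No correction is applied; the
synthetic-recovery tests quantify the effect (interaction recovery is the
weakest of the three at realistic depths).

## Ingest

Species are called per barcode from dual-genome aligned-read totals: mouse if
≥ 70 % of aligned reads hit the mouse genome, rat if ≥ 70 % hit rat,
otherwise the barcode is discarded as a doublet (boundary inclusive). All
aligned reads are used for the fraction, not only ortholog-mapped reads (the
choice is documented rather than prescribed anywhere). After assignment only
the assigned genome's per-gene counts are kept. QC removes cells with
mitochondrial fraction > 15 % or > 7500 detected genes. Genes must be
expressed (count > 0) in ≥ 20 % of cells in at least one combination;
pseudobulk columns are per-cell-type sums, genes with < 10 summed counts in
all four combinations are removed, and a cell type with < 10 cells in any
combination is dropped with a logged warning. An optional gene whitelist
implements ortholog/sex-chromosome restriction from a user TSV. Cell-type
labels are an input column; clustering is out of scope.

## Equal-depth resampled normalization

Plain (count+1)/total×10⁴ normalization biases fold-changes when column
totals differ, because the pseudocount is worth 1/total: with totals
(10⁶, 10⁶, 10⁶, 10⁵) and counts (99, 99, 0, 0) for (DM, HM, HR, DR) the
normalized quartet is (1, 1, 0.01, 0.1), so the two estimates of the same
fold-change disagree 10-fold (DM/HR = 100 vs DM/DR = 10), inflating the
extrinsic/interaction components of low-count genes. The fix: downsample
each column *without replacement* (multivariate hypergeometric — the only
sampling scheme that fixes totals exactly) to the minimum column total,
average 100 independent draws, then pseudocount and scale to counts per 10⁴.
The pseudocount is applied after averaging and before division; this order
reproduces the worked example above, and the alternatives do not. Every
per-rep resampled column sums exactly to the target, and the per-combination
Spearman correlation between resampled-mean and direct normalization exceeds
0.999 on pseudobulk tables with 2–10× depth imbalance (the correlation is
computed within combinations: across columns the two schemes carry
incomparable pseudocount offsets, 1/total vs 1/target, which the method
never compares).

## Enrichment engine

The preranked statistic is the standard weighted Kolmogorov–Smirnov running
sum: hits advance by |score|^w (w = 1 by default) normalized to the set's
total weight, misses retreat by 1/(n−k); the ES is the extremum. The null is
gene-permutation (random same-size sets); NES divides ES by the same-sign
null mean; p is the smoothed same-sign tail fraction; FDR pools normalized
null scores across sets in the usual positive/negative way. Null ES values
are computed in O(k) per permutation by evaluating the piecewise-linear
running sum only at hit positions. Defaults: 1000 permutations, seed 6, set
size window 10–300 after intersection (a 30000 variant is available for
very large sets). Ties in any ranking metric break lexicographically by gene
id. ES values agree exactly with brute-force enumeration and with an
independent external implementation on random instances; peak position under
a float-level tie between a positive and a negative extremum of equal
magnitude is implementation-defined, so oracle tests compare magnitudes.

**Symmetric rank transform.** A running sum expects a signed metric; ranking
raw absolute values concentrates all weight at one end and produces spurious
enrichment. The transform maps n genes, sorted descending, to
⌈n/2⌉, ⌈n/2⌉−1, …, mirroring the bottom half to equally large negative
values (lowest = −⌈n/2⌉, zero skipped for even n; for odd n the mirrored
half is one value shorter). For 5000 genes the top gene gets 2500 and the
lowest −2500.

**Tail fold-enrichment.** log2((hits in top c ranks + 1)/(hits in bottom c
ranks + 1)), with c the running-sum extremum rank (the leading-edge
cutoff); tails swap for negative enrichments, and the value is undefined
(NaN) when the cutoff exceeds half the list.

## Trait analyses

- **Ratio quartets** (e.g. post-mitotic neurons ÷ progenitors per
  combination) feed the same decomposition; per-combination totals cancel in
  the ratio, so counts and proportions are equivalent.
- **Tau** specificity: Σ(1 − xᵢ/x_max)/(n−1) over cell types; 1 = fully
  specific, 0 = uniform; scale-invariant.
- **Predictor correlations**: Spearman of each gene-level covariate against
  Ip − Ep over filter-passing genes; complete-case or per-covariate missing
  handling; constant covariates report NaN.
- **Developmental dynamics**: Pearson correlation of expression with stage
  index per species (with three points a rank correlation is degenerate);
  similar if the product of the two correlations > 0.7, opposite if
  < −0.25, temporal shift = similar plus |cross-species log2FC| < 0.25 at
  both later stages. A temporally shifted but shared trajectory mimics
  extrinsic divergence in stage-matched chimeras, which is why the class
  matters as a confound.
- **Bulk imprinting workflow**: per-condition median TPM, floor of 5 in all
  conditions, z-score per gene, hierarchical clustering of samples
  (Euclidean distance, average linkage — the linkage is a documented default
  since "default parameters" of plotting tools is ambiguous; samples are
  sorted before clustering so the result is input-order invariant), and
  flagging of genes with |log2 mismatched/matched median| > 1.
- **Marker gate**: a cell passes if any marker strictly exceeds 1 TPM;
  companion fold-changes add one pseudo-TPM and drop genes below 1 TPM in
  all categories.

## Immunofluorescence quantification

The DAPI and TdTomato channels are Gaussian-blurred and thresholded; the
measured target channel is never blurred. Donor pixels are DAPI⁺∧TdT⁺, host
pixels DAPI⁺∧TdT⁻; means are taken over pixels with non-zero raw target
intensity. The within-chimera log2FC uses unsubtracted means; means minus
the mean of a no-nuclei background rectangle are stored for between-chimera
comparisons (both variants are reported since the within-chimera convention
is ambiguous). The two reciprocal chimera images assemble the protein
quartet (hosts → HM/HR, donors → DM/DR) for the decomposition. The
robustness sweep recomputes all four log fold-changes over 3 DAPI × 3 TdT
cutoffs per chimera (81 combinations), reporting per-quantity standard
errors; masks are monotone in cutoffs, and combinations that empty a mask
are excluded and counted. Rectangles are half-open pixel intervals with
origin top-left.

## Synthetic data generator

The generator is the model run forward. Expected log2 expression of gene g
in combination (species s, environment e) is
`baseline_g + I_g·[s=rat] + E_g·[e=rat-like] + N_g·[s≠e]`; note the planted
`N_g` is mismatch-positive while the framework's estimate is
matched-positive, so the truth table stores both signs
(`interaction_framework = −interaction`). Decomposing the expected quartets
recovers the planted effects exactly; pipeline estimates additionally carry
a small gene-shared compositional offset from per-combination normalization,
which cancels in correlations.

Defaults are chosen once to emulate the study regime: effect spreads
σ_I = 1.0 > σ_E = 0.5 > σ_N = 0.25 (intrinsic-dominant, matching the
observed ordering of mean proportions); baselines Normal(0, 1.5) on log2;
negative binomial counts (gamma–Poisson, size 10) with log-normal per-cell
library sizes (σ = 0.35); unequal default cell numbers (200/200/80/40 for
HM/HR/DM/DR) and depths (5000/5000/3000/1500 reads per cell) reflecting
donor-cell scarcity; 1 % of a singlet's reads leak to the other genome; 5 %
mixed-species doublets per combination whose genome mixing fraction is
uniform in (0.3, 0.7) with a rejection loop guaranteeing the realized
fraction fails the 70 % rule; 2 % of cells get a high mitochondrial fraction
so QC is exercised. An optional imprinted-like block plants mismatch effects
of magnitude uniform in (1, 2) with random sign. All randomness flows from a
single seed; identical seeds give byte-identical datasets.

The generator collapses the model's replicate-specific latents into one
latent value per gene and combination plus the planted interaction; real
chimera-to-chimera latent variability would be an additional variance
component and is deliberately not emulated. Other features of real data the
generator does not reproduce: ambient RNA, cell-type mixtures with shared
manifolds, UMI saturation, batch effects, and realistic transcriptome
references. Passing recovery tests therefore demonstrate correctness of the
estimator under its own model, not robustness to those artifacts.

The timecourse generator emits noise-free geometric trajectories per class
(similar / opposite / temporal shift / unclassified tent) so the classifier
round-trips labels exactly. The IF image generator draws circular nuclei
with a TdTomato plateau twice the DAPI plateau and a minimum clearance
between nuclei larger than the blur support, so noiseless masks select pure
compartments at any cutoff in the sweep range — geometry choices that make
the exactness fixtures exact, not properties of real tissue.

## Problem sizes and numerics

Test and acceptance workloads are sized for a laptop-class single core:
recovery at 500 genes × 200 cells per combination; imprinted-detection at
2050 genes across 20 replicate simulations; identity checks on 10,000
random quartets; normalization agreement at ~2300 genes with 100 resampling
reps. Tolerances: exact worked examples at float precision; algebraic
identities at 1e-9; stochastic recovery thresholds at the values stated in
the tests. Degenerate inputs (zero totals, empty masks, all-zero metrics,
constant covariates) raise informative errors or NaN as documented per
function rather than propagating silently.
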