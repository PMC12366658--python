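# chimeradecomp

Decompose evolutionary divergence in cellular traits into **cell-intrinsic**,
**cell-extrinsic**, and **intrinsic–extrinsic interaction** components from
reciprocal interspecies chimera data.

## The problem

When a gene is expressed differently in mouse and rat, is that because the
regulatory program *inside* each cell diverged (cell-intrinsic), or because
the extracellular environment the cells live in diverged (cell-extrinsic)?
Reciprocal chimeras answer this: inject rat embryonic stem cells into a mouse
blastocyst and vice versa, so that each species' cells can be measured both in
their own environment (host cells) and in the other species' environment
(donor cells). For every gene and cell type this yields a *quartet* of
normalized expression values:

|      | mouse-like environment | rat-like environment |
|------|------------------------|----------------------|
| mouse cells | HM (host mouse) | DM (donor mouse) |
| rat cells   | DR (donor rat)  | HR (host rat)    |

Modeling each measurement as the product of an intrinsic and an extrinsic
factor gives two independent estimates of each divergence component
(log2 units throughout):

```
I1 = log2(HR/DM)    I2 = log2(DR/HM)      intrinsic (rat − mouse)
E1 = log2(DM/HM)    E2 = log2(HR/DR)      extrinsic (rat-like − mouse-like env.)
I  = (I1+I2)/2      E = (E1+E2)/2
N  = (I1−I2)/2  =  (E2−E1)/2  =  ½·log2(HM·HR / (DM·DR))
```

The interaction `N` is the disagreement between the paired estimates: it is
nonzero when cells respond to the foreign environment differently than their
own species does — the signature of, e.g., imprinted genes collapsing in
species-mismatched environments. Proportions `Ip, Ep, Np` divide each
magnitude by the sum of the three magnitudes (they sum to 1); signed
proportions carry the component's sign (rat-higher positive).

## What the package provides

- `simulate` — synthetic reciprocal-chimera scRNA-seq with planted per-gene
  effects, negative-binomial noise, unequal depths/cell numbers, mixed-species
  doublets; plus timecourse tables and immunofluorescence images, all with
  ground truth.
- `ingest` — barnyard species assignment (≥70 % aligned-read rule), QC
  (mito ≤ 15 %, ≤ 7500 genes detected), gene filters, and pseudobulking into
  the four combinations per cell type.
- `normalize` — equal-depth resampled normalization: downsample every
  combination to the smallest column total (multivariate hypergeometric),
  average 100 draws, pseudocount, counts per 10k. Removes the depth-driven
  fold-change bias that plain CP10K suffers from.
- `decompose` — the quartet decomposition itself, with the divergence-evidence
  filter (|log2FC| > 0.5 in at least one of I1/I2/E1/E2); also exposed as the
  sklearn-style transformers `QuartetDecomposer` and `EqualDepthNormalizer`.
- `enrichment` — a self-contained preranked gene-set enrichment engine
  (weighted running-sum ES, gene-permutation null, NES/p/FDR), the symmetric
  rank transform for unsigned metrics, tail log2 fold-enrichment, TF-target
  propagation correlations, and the imprinted-gene interaction tests.
- `traits` — the framework applied to non-expression traits
  (neuron/progenitor ratios), the Tau specificity index, covariate
  correlations with Ip − Ep, developmental-dynamics classification
  (similar / opposite / temporal shift), and bulk imprinted-gene workflows.
- `imaging` — blur–mask–measure quantification of donor vs host protein
  signal from (DAPI, TdTomato, target) images, with background subtraction
  and the 81-combination masking-robustness sweep.
- `pipeline` / `chimera-decomp` CLI — one-config orchestration
  (simulate/load → ingest → normalize → decompose → summarize) with a
  manifest and structured logs.

## Worked example

```python
import chimeradecomp as cd
from scipy import stats

ds = cd.generate_chimera_counts(1000, seed=1)        # synthetic chimera data
res = cd.ingest_dataset(ds.adata)                    # species calls, QC, pseudobulk
norm = cd.normalize_resampled(res.tables["synthetic"], n_reps=100, seed=1)
dec = cd.decompose_table(norm)                       # I/E/N per gene
passed = dec[dec.passed_divergence_filter]
print("mean proportions  Ip=%.2f  Ep=%.2f  Np=%.2f"
      % tuple(passed[["Ip", "Ep", "Np"]].mean()))
truth = ds.truth.loc[dec.index]
for comp, col in (("I", "intrinsic"), ("E", "extrinsic"), ("N", "interaction_framework")):
    print(f"recovery of planted {comp}: r = %.3f"
          % stats.pearsonr(dec[comp], truth[col])[0])
```

prints

```
mean proportions  Ip=0.54  Ep=0.28  Np=0.18
recovery of planted I: r = 0.975
recovery of planted E: r = 0.904
recovery of planted N: r = 0.748
```

i.e. on data simulated under an intrinsic-dominant regime most divergence is
recovered as intrinsic, about a quarter as extrinsic, and the planted
per-gene effects correlate strongly with their estimates (the interaction
term is the noisiest, as it is a difference of estimates; deeper donor
sampling raises its recovery above 0.9). The same chain runs from the shell:

```sh
chimera-decomp run --seed 1 --out runout/
```

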