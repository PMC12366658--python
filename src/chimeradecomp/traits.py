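"""The framework beyond expression: trait quartets, specificity, covariates,
developmental dynamics, and imprinted-gene bulk workflows.

Any cellular trait measured in all four species-environment combinations can
be decomposed exactly like expression -- e.g. the ratio of post-mitotic
neurons to progenitors, whose divergence reflects the species difference in
the tempo of neurogenesis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .decompose import DecompositionResult, decompose
from .ingest import COMBOS

__all__ = [
    "RatioQuartet",
    "ratio_decompose",
    "tau",
    "predictor_correlations",
    "classify_dynamics",
    "imprinted_bulk_workflow",
    "BulkWorkflowResult",
    "marker_gate",
    "pseudo_tpm_log2fc",
]


@dataclass(frozen=True)
class RatioQuartet:
    """A derived-trait quartet, e.g. neurons / progenitors per combination."""

    trait_name: str
    HM: float
    HR: float
    DM: float
    DR: float


def ratio_decompose(
    cell_counts: Mapping[str, tuple[int, int]],
    trait_name: str = "neuron_progenitor_ratio",
    min_abs_lfc: float = 0.5,
) -> DecompositionResult:
    """Decompose the divergence of a count ratio (e.g. neurons / progenitors).

    ``cell_counts`` maps each combination to ``(numerator, denominator)``
    cell counts.  Whether proportions or raw counts are used is immaterial:
    the per-combination totals cancel in the ratio.
    """
    missing = [c for c in COMBOS if c not in cell_counts]
    if missing:
        raise ValueError(f"missing combinations: {missing}")
    vals = {}
    for combo in COMBOS:
        num, den = cell_counts[combo]
        if den <= 0:
            raise ValueError(f"combination {combo!r} has zero denominator (progenitors)")
        if num <= 0:
            raise ValueError(f"combination {combo!r} has zero numerator (neurons)")
        vals[combo] = num / den
    q = RatioQuartet(trait_name=trait_name, **vals)
    res = decompose(q, min_abs_lfc=min_abs_lfc)
    return DecompositionResult(**{**res.__dict__, "gene_id": trait_name})


def tau(expression: Sequence[float]) -> float:
    """Cell-type specificity index in [0, 1].

    tau = sum_i (1 - x_i / x_max) / (n - 1).  Equals 1 for expression
    confined to a single cell type and 0 for perfectly uniform expression.
    Requires non-negative values, length >= 2, and a positive maximum.
    """
    x = np.asarray(expression, dtype=float)
    if x.size < 2:
        raise ValueError("tau needs expression in at least 2 cell types")
    if np.any(x < 0):
        raise ValueError("tau expects non-negative expression values")
    xmax = x.max()
    if xmax <= 0:
        raise ValueError("tau is undefined for an all-zero expression vector")
    return float(np.sum(1.0 - x / xmax) / (x.size - 1))


def predictor_correlations(
    decomp: pd.DataFrame,
    covariates: pd.DataFrame,
    join: str = "complete",
    min_genes: int = 10,
) -> pd.DataFrame:
    """Spearman correlation of each covariate with (Ip - Ep).

    The target is the intrinsic-minus-extrinsic proportion of
    filter-passing genes.  ``join="complete"`` keeps only genes with every
    covariate present (one shared gene universe); ``join="pairwise"`` drops
    missing values per covariate.  Constant covariates yield NaN.

    Returns a DataFrame indexed by covariate with columns rho, p, n.
    """
    if join not in ("complete", "pairwise"):
        raise ValueError("join must be 'complete' or 'pairwise'")
    d = decomp
    if "passed_divergence_filter" in d.columns:
        d = d.loc[d["passed_divergence_filter"].astype(bool)]
    target = (d["Ip"] - d["Ep"]).dropna()
    merged = covariates.join(target.rename("_target"), how="inner").dropna(
        subset=["_target"]
    )
    if len(merged) == 0:
        raise ValueError("no overlap between decomposition table and covariates")
    if join == "complete":
        merged = merged.dropna()
    rows = {}
    for cov in covariates.columns:
        sub = merged[[cov, "_target"]].dropna()
        n = len(sub)
        if n < min_genes or sub[cov].nunique() < 2:
            rows[cov] = {"rho": np.nan, "p": np.nan, "n": n}
            continue
        rho, p = stats.spearmanr(sub[cov], sub["_target"])
        rows[cov] = {"rho": float(rho), "p": float(p), "n": n}
    return pd.DataFrame.from_dict(rows, orient="index")


def classify_dynamics(
    timecourse: pd.DataFrame,
    crossspecies_lfc: pd.DataFrame | None = None,
    similar_min: float = 0.7,
    opposite_max: float = -0.25,
    shift_lfc_max: float = 0.25,
    species_lfc_min: float = 0.5,
    timepoints: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Classify developmental expression dynamics across two species.

    ``timecourse`` has one row per gene and columns ``mouse_<tp>`` /
    ``rat_<tp>`` for >= 3 shared timepoints.  Per species, the Pearson
    correlation of expression with stage index is computed (with 3 points a
    rank correlation would be degenerate).  Classes:

    - ``similar``: product of the two correlations > ``similar_min``;
    - ``opposite``: product < ``opposite_max``;
    - ``temporal_shift``: similar AND |cross-species log2FC| <
      ``shift_lfc_max`` at both of the two later timepoints (a shared
      trajectory offset in developmental time looks extrinsic in
      stage-matched chimeras);
    - ``unclassified`` otherwise.

    ``crossspecies_lfc`` (genes x 2, log2 mouse/rat at the two later
    timepoints) defaults to being computed from the timecourse.  Also emits
    ``direction`` (increasing / decreasing for similar genes) and
    higher-in-mouse / higher-in-rat flags at |mean log2FC| > ``species_lfc_min``.
    """
    if timepoints is None:
        timepoints = [c[len("mouse_") :] for c in timecourse.columns if c.startswith("mouse_")]
    if len(timepoints) < 3:
        raise ValueError("classification needs at least 3 timepoints")
    mouse = timecourse[[f"mouse_{tp}" for tp in timepoints]].to_numpy(dtype=float)
    rat = timecourse[[f"rat_{tp}" for tp in timepoints]].to_numpy(dtype=float)
    stage = np.arange(len(timepoints), dtype=float)

    def _corr(mat: np.ndarray) -> np.ndarray:
        centered = mat - mat.mean(axis=1, keepdims=True)
        sd = centered.std(axis=1)
        s = stage - stage.mean()
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (centered @ s) / (sd * np.sqrt((s**2).sum())) / np.sqrt(mat.shape[1])
        # constant trajectories have undefined correlation
        r[sd == 0] = np.nan
        return r

    r_mouse = _corr(mouse)
    r_rat = _corr(rat)
    prod = r_mouse * r_rat

    if crossspecies_lfc is None:
        with np.errstate(divide="ignore", invalid="ignore"):
            lfc_late = np.log2(mouse[:, -2:] / rat[:, -2:])
    else:
        lfc_late = crossspecies_lfc.reindex(timecourse.index).to_numpy(dtype=float)

    similar = prod > similar_min
    opposite = prod < opposite_max
    shift = similar & (np.abs(lfc_late) < shift_lfc_max).all(axis=1)
    cls = np.where(shift, "temporal_shift", np.where(similar, "similar", np.where(opposite, "opposite", "unclassified")))

    direction = np.where(
        similar & (r_mouse > 0) & (r_rat > 0), "increasing",
        np.where(similar & (r_mouse < 0) & (r_rat < 0), "decreasing", "none"),
    )
    mean_lfc = np.nanmean(lfc_late, axis=1)
    return pd.DataFrame(
        {
            "dynamics_class": cls,
            "is_similar": similar,
            "r_mouse": r_mouse,
            "r_rat": r_rat,
            "direction": direction,
            "higher_in_mouse": mean_lfc > species_lfc_min,
            "higher_in_rat": mean_lfc < -species_lfc_min,
        },
        index=timecourse.index,
    )


@dataclass
class BulkWorkflowResult:
    """Output of :func:`imprinted_bulk_workflow`."""

    medians: pd.DataFrame
    zscores: pd.DataFrame
    sample_order: list[str]
    linkage: np.ndarray
    flagged_genes: list[str]


def imprinted_bulk_workflow(
    tpm: pd.DataFrame,
    conditions: Mapping[str, str],
    imprinted: Iterable[str],
    min_median_tpm: float = 5.0,
    lfc_flag_min: float = 1.0,
    linkage_method: str = "average",
    standardize: bool = True,
) -> BulkWorkflowResult:
    """Median-TPM workflow for imprinted genes in bulk replicates.

    ``tpm`` is samples x genes (gene-level TPM; collapse transcripts by
    summation beforehand if needed); ``conditions`` maps each sample to
    ``mismatched`` / ``matched`` / ``wildtype``.  Per-condition medians are
    taken, genes below ``min_median_tpm`` in *all* conditions are removed,
    the table is restricted to the imprinted set, genes are z-scored across
    samples, and samples are hierarchically clustered (Euclidean distance,
    ``linkage_method`` linkage).  Genes with |log2(mismatched median /
    matched median)| > ``lfc_flag_min`` are flagged.
    """
    cond = pd.Series(conditions)
    missing = [s for s in tpm.index if s not in cond.index]
    if missing:
        raise ValueError(f"samples without a condition label: {missing[:5]}")
    counts = cond.reindex(tpm.index).value_counts()
    for c in ("mismatched", "matched"):
        if counts.get(c, 0) == 0:
            raise ValueError(f"condition {c!r} has zero samples")

    medians = tpm.groupby(cond.reindex(tpm.index)).median().T  # genes x conditions
    keep = (medians >= min_median_tpm).any(axis=1)
    imprinted = pd.Index(pd.unique(pd.Index(list(imprinted)).astype(str)))
    genes = medians.index[keep].intersection(imprinted)
    if len(genes) == 0:
        raise ValueError("no imprinted genes pass the median-TPM floor")

    sub = tpm[genes]  # samples x imprinted genes
    z = sub.copy()
    if standardize:
        std = sub.std(axis=0, ddof=0).replace(0, 1.0)
        z = (sub - sub.mean(axis=0)) / std
    # cluster samples; sort the sample axis first so the result is
    # invariant to input sample order
    z = z.sort_index()
    link = hierarchy.linkage(pdist(z.to_numpy(), metric="euclidean"), method=linkage_method)
    order = [z.index[i] for i in hierarchy.leaves_list(link)]

    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(medians.loc[genes, "mismatched"] / medians.loc[genes, "matched"])
    flagged = sorted(genes[np.abs(lfc.to_numpy()) > lfc_flag_min])
    return BulkWorkflowResult(
        medians=medians.loc[genes],
        zscores=z,
        sample_order=order,
        linkage=link,
        flagged_genes=list(flagged),
    )


def marker_gate(
    tpm_cell: Mapping[str, float] | pd.Series,
    markers: Sequence[str],
    min_tpm: float = 1.0,
) -> bool:
    """True iff any marker gene strictly exceeds ``min_tpm`` in this cell.

    Used to gate putative cell identities (e.g. epiblast via NANOG / SOX2 /
    POU5F1) when annotations are unavailable.  Exactly ``min_tpm`` does not
    pass.
    """
    if len(markers) == 0:
        raise ValueError("marker list is empty")
    s = pd.Series(tpm_cell, dtype=float)
    missing = [m for m in markers if m not in s.index]
    if missing:
        raise ValueError(f"markers absent from expression table: {missing}")
    return bool((s[list(markers)] > min_tpm).any())


def pseudo_tpm_log2fc(
    tpm_by_category: pd.DataFrame,
    numerator: str,
    denominator: str,
    pseudo: float = 1.0,
    min_tpm: float = 1.0,
) -> pd.Series:
    """log2 fold-change between two categories with one pseudo-TPM added.

    Genes expressed below ``min_tpm`` in *all* categories are dropped before
    the ratio; the pseudo-TPM keeps the ratio finite for the rest.
    """
    keep = (tpm_by_category >= min_tpm).any(axis=1)
    sub = tpm_by_category.loc[keep]
    return np.log2((sub[numerator] + pseudo) / (sub[denominator] + pseudo))
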