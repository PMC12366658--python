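"""Self-contained preranked gene-set enrichment.

Implements the weighted Kolmogorov-Smirnov running-sum statistic with a
gene-permutation null, plus two companions used throughout the chimera
analyses:

- a *symmetric rank transform* that turns an unsigned metric (e.g. the
  absolute interaction divergence |N|) into mirrored positive/negative
  ranks, so the running-sum statistic -- designed for signed metrics --
  behaves sensibly on absolute values;
- a *log2 fold-enrichment* comparing gene-set membership in the top vs
  bottom tails at the rank cutoff set by the running-sum extremum.

Defaults (1000 permutations, seed 6, set sizes 10-300) match common
preranked-GSEA practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "EnrichmentResult",
    "rank_list",
    "preranked_enrichment",
    "symmetric_rank_transform",
    "SymmetricRankTransform",
    "log2_fold_enrichment",
    "tf_propagation_correlation",
    "imprinted_interaction_test",
    "read_gmt",
    "write_gmt",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment of one gene set in one ranked list."""

    set_name: str
    es: float
    nes: float
    p: float
    fdr: float
    size: int
    leading_edge_cutoff_rank: int
    log2_fold_enrichment: float


def rank_list(values: Mapping[str, float] | pd.Series) -> pd.Series:
    """Build a ranked list: genes sorted by score, descending, ties broken by gene id.

    Returns a Series (index = gene id, values = score).  Duplicate gene ids
    are an error.
    """
    s = pd.Series(values, dtype=float)
    if s.index.has_duplicates:
        dupes = s.index[s.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in ranking metric: {dupes[:5]}")
    if s.isna().any():
        raise ValueError("ranking metric contains NaN")
    order = pd.DataFrame({"score": -s.to_numpy(), "gene": s.index.astype(str)})
    idx = np.lexsort((order["gene"].to_numpy(), order["score"].to_numpy()))
    return s.iloc[idx]


def _running_sum_es(
    scores: np.ndarray, in_set: np.ndarray, weight: float
) -> tuple[float, int]:
    """Enrichment score and 0-based extremum position of the running sum."""
    n = scores.size
    k = int(in_set.sum())
    if k == 0 or k == n:
        raise ValueError("gene set must be a proper non-empty subset of the ranked list")
    w = np.where(in_set, np.abs(scores) ** weight, 0.0)
    nr = w.sum()
    if nr == 0:
        return 0.0, 0
    steps = np.where(in_set, w / nr, -1.0 / (n - k))
    cum = np.cumsum(steps)
    pos = int(np.argmax(np.abs(cum)))
    return float(cum[pos]), pos


def _null_es(
    abs_w: np.ndarray,
    k: int,
    n_perm: int,
    rng: np.random.Generator,
    chunk: int = 200,
) -> np.ndarray:
    """Null enrichment scores for random size-``k`` gene sets.

    Exploits the piecewise-linear running sum: its extrema occur at hit
    positions (just after a hit) or immediately before a hit, so each
    permutation costs O(k) after sampling.
    """
    n = abs_w.size
    m = 1.0 / (n - k)
    out = np.empty(n_perm)
    j = np.arange(k)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        # uniform random k-subsets of positions, one per permutation
        pos = np.sort(rng.random((b, n)).argpartition(k, axis=1)[:, :k], axis=1)
        wmat = abs_w[pos]
        nr = wmat.sum(axis=1, keepdims=True)
        nr[nr == 0] = np.inf  # degenerate perm: all-zero weights -> ES 0
        cw = np.cumsum(wmat, axis=1) / nr
        misses = pos - j  # misses strictly before each hit
        top = cw - m * misses
        bot = np.concatenate([np.zeros((b, 1)), cw[:, :-1]], axis=1) - m * misses
        es_pos = top.max(axis=1)
        es_neg = np.minimum(bot.min(axis=1), 0.0)
        out[done : done + b] = np.where(es_pos >= -es_neg, es_pos, es_neg)
        done += b
    return out


def preranked_enrichment(
    ranked: pd.Series,
    sets: Mapping[str, Iterable[str]],
    n_perm: int = 1000,
    min_size: int = 10,
    max_size: int = 300,
    seed: int = 6,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Weighted running-sum enrichment of each gene set in a ranked list.

    Parameters
    ----------
    ranked
        Ranked list from :func:`rank_list` (or any descending-sorted Series
        of scores indexed by gene id).
    sets
        Mapping set name -> iterable of gene ids.  Sets whose intersection
        with the ranked list falls outside ``[min_size, max_size]`` are
        skipped.
    n_perm
        Gene-permutation null size per set (>= 1).
    weight
        Exponent on |score| for hit increments; 0 gives the classic
        unweighted KS statistic.

    Returns a DataFrame with one row per tested set: ``es``, ``nes``
    (ES normalized by the same-sign null mean), permutation ``p``, pooled
    ``fdr``, matched set ``size``, the 1-based ``leading_edge_cutoff_rank``
    of the running-sum extremum, and the tail ``log2_fold_enrichment`` at
    that cutoff (NaN when the cutoff exceeds half the list).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(ranked) == 0:
        raise ValueError("ranked list is empty")
    ranked = ranked.astype(float)
    scores = ranked.to_numpy()
    genes = ranked.index.astype(str)
    gene_pos = pd.Series(np.arange(len(genes)), index=genes)
    abs_w = np.abs(scores) ** weight
    rng = np.random.default_rng(seed)

    rows = []
    null_by_size: dict[int, np.ndarray] = {}
    for name, members in sets.items():
        members = pd.Index(pd.unique(pd.Index(list(members)).astype(str)))
        hit_pos = gene_pos.reindex(members).dropna().astype(int).to_numpy()
        k = hit_pos.size
        if k < min_size or k > max_size or k == len(genes):
            continue
        in_set = np.zeros(len(genes), dtype=bool)
        in_set[hit_pos] = True
        es, peak = _running_sum_es(scores, in_set, weight)
        if k not in null_by_size:
            null_by_size[k] = _null_es(abs_w, k, n_perm, rng)
        null = null_by_size[k]

        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        p = (1.0 + np.sum(np.abs(same_sign) >= abs(es))) / (1.0 + same_sign.size)
        mean_same = np.abs(same_sign).mean() if same_sign.size else np.nan
        nes = es / mean_same if mean_same and np.isfinite(mean_same) else np.nan

        cutoff = peak + 1  # 1-based rank of the extremum
        if cutoff <= len(genes) // 2:
            direction = "positive" if es >= 0 else "negative"
            lfe = log2_fold_enrichment(ranked, members, cutoff, direction=direction)
        else:
            lfe = np.nan
        rows.append(
            {
                "set_name": name,
                "es": es,
                "nes": nes,
                "p": p,
                "size": k,
                "leading_edge_cutoff_rank": cutoff,
                "log2_fold_enrichment": lfe,
                "_null_mean_same": mean_same,
            }
        )

    res = pd.DataFrame(
        rows,
        columns=[
            "set_name", "es", "nes", "p", "size",
            "leading_edge_cutoff_rank", "log2_fold_enrichment", "_null_mean_same",
        ],
    )
    if len(res) == 0:
        res["fdr"] = pd.Series(dtype=float)
        return res.drop(columns=["_null_mean_same"]).set_index("set_name")

    # Pooled-null FDR: normalize every null ES by its set's same-sign null mean.
    pooled = []
    for row in res.itertuples():
        null = null_by_size[row.size]
        pos_mean = np.abs(null[null >= 0]).mean() if (null >= 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        nn = np.where(null >= 0, null / pos_mean, null / np.abs(neg_mean))
        pooled.append(nn[np.isfinite(nn)])
    pooled = np.concatenate(pooled)
    obs = res["nes"].to_numpy()
    fdr = np.empty(len(res))
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            fdr[i] = np.nan
            continue
        if nes >= 0:
            null_frac = np.mean(pooled[pooled >= 0] >= nes) if (pooled >= 0).any() else 0.0
            obs_frac = np.mean(obs[obs >= 0] >= nes)
        else:
            null_frac = np.mean(pooled[pooled < 0] <= nes) if (pooled < 0).any() else 0.0
            obs_frac = np.mean(obs[obs < 0] <= nes)
        fdr[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else np.nan
    res["fdr"] = fdr
    return res.drop(columns=["_null_mean_same"]).set_index("set_name")


def symmetric_rank_transform(values: Mapping[str, float] | pd.Series) -> pd.Series:
    """Mirror an unsigned metric into symmetric positive/negative ranks.

    For ``n`` genes sorted by the metric descending (ties broken by gene
    id), the top gene gets ``ceil(n/2)``, the next ``ceil(n/2) - 1``, and so
    on; the bottom half mirrors to equally large negative values, the lowest
    gene getting ``-ceil(n/2)``.  Zero is skipped, so for even ``n`` the
    values run ``n/2 ... 1, -1 ... -n/2``.  Negative inputs are an error
    (the transform is for absolute metrics).

    Returns a ranked Series (descending) suitable for
    :func:`preranked_enrichment`.
    """
    s = pd.Series(values, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least 2 genes")
    if (s < 0).any():
        raise ValueError("symmetric rank transform expects non-negative (absolute) values")
    ranked = rank_list(s)
    n = len(ranked)
    half = (n + 1) // 2  # ceil(n/2)
    top = np.arange(half, 0, -1, dtype=float)
    # position n+1-i mirrors position i for the lower floor(n/2) positions
    bottom = -top[: n - half][::-1]
    return pd.Series(np.concatenate([top, bottom]), index=ranked.index)


class SymmetricRankTransform(BaseEstimator, TransformerMixin):
    """Sklearn-style wrapper around :func:`symmetric_rank_transform`.

    ``transform`` maps an ``(n, 1)`` column of non-negative scores to the
    mirrored rank values *in the input row order* (the functional API
    returns them sorted).
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 1:
            raise ValueError("expected a single column of scores")
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "n_features_in_")
        X = np.asarray(X, dtype=float)
        s = pd.Series(X[:, 0], index=[f"r{i:09d}" for i in range(X.shape[0])])
        ranks = symmetric_rank_transform(s).reindex(s.index)
        return ranks.to_numpy()[:, None]


def log2_fold_enrichment(
    ranked: pd.Series,
    gene_set: Iterable[str],
    cutoff_rank: int,
    direction: str = "positive",
) -> float:
    """Tail-imbalance statistic: log2((hits in top cutoff + 1) / (hits in bottom cutoff + 1)).

    ``cutoff_rank`` counts genes from the relevant end of the ranked list
    and must not exceed half the list (the tails may not overlap).  For
    ``direction="negative"`` the tails swap, so a set piling up at the
    bottom of the list still gets a positive value.
    """
    n = len(ranked)
    if cutoff_rank < 1:
        raise ValueError("cutoff_rank must be >= 1")
    if cutoff_rank > n // 2:
        raise ValueError(f"cutoff_rank {cutoff_rank} exceeds half the list ({n} genes)")
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    members = set(map(str, gene_set))
    genes = ranked.index.astype(str)
    top = sum(g in members for g in genes[:cutoff_rank])
    bottom = sum(g in members for g in genes[n - cutoff_rank :])
    if direction == "negative":
        top, bottom = bottom, top
    return float(np.log2((top + 1) / (bottom + 1)))


def tf_propagation_correlation(
    tf_signed_component: Mapping[str, float],
    target_set_enrichment: Mapping[str, float],
) -> tuple[float, float, int]:
    """Spearman correlation, across cell types, of a TF's signed divergence
    with the enrichment of its target set for the same signed divergence.

    Returns ``(rho, two-sided p, n shared cell types)``; requires at least 3
    shared cell types.
    """
    a = pd.Series(tf_signed_component, dtype=float)
    b = pd.Series(target_set_enrichment, dtype=float)
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared cell types, got {len(shared)}")
    rho, p = stats.spearmanr(a[shared], b[shared])
    return float(rho), float(p), int(len(shared))


def imprinted_interaction_test(
    decomp: pd.DataFrame,
    imprinted: Iterable[str],
    mode: str = "absolute",
    n_perm: int = 1000,
    seed: int = 6,
    min_size: int = 10,
    max_size: int = 300,
    weight: float = 1.0,
) -> EnrichmentResult:
    """Test whether a gene set (e.g. imprinted genes) concentrates interaction divergence.

    ``mode="absolute"`` asks whether the set has unusually *large* |N|:
    genes are ranked by the symmetric rank transform of |N|.  ``mode="signed"``
    ranks by the *mismatch-oriented* signed interaction proportion
    (``-signed_Np``, since the decomposition's N is positive when matched
    environments are higher), so a positive enrichment score means the set
    is expressed higher in species-mismatched environments and a negative
    one higher in matched environments.
    """
    imprinted = pd.Index(pd.unique(pd.Index(list(imprinted)).astype(str)))
    genes = decomp.index.astype(str)
    inter = imprinted.intersection(genes)
    if len(inter) == 0:
        raise ValueError("imprinted gene set does not intersect the decomposition table")
    if mode == "absolute":
        ranked = symmetric_rank_transform(
            pd.Series(np.abs(decomp["N"].to_numpy()), index=genes)
        )
    elif mode == "signed":
        ranked = rank_list(pd.Series(-decomp["signed_Np"].to_numpy(), index=genes).dropna())
    else:
        raise ValueError("mode must be 'absolute' or 'signed'")
    res = preranked_enrichment(
        ranked,
        {"imprinted": inter},
        n_perm=n_perm,
        min_size=min(min_size, len(inter)),
        max_size=max(max_size, len(inter)),
        seed=seed,
        weight=weight,
    )
    row = res.loc["imprinted"]
    return EnrichmentResult(
        set_name="imprinted",
        es=float(row["es"]),
        nes=float(row["nes"]),
        p=float(row["p"]),
        fdr=float(row["fdr"]),
        size=int(row["size"]),
        leading_edge_cutoff_rank=int(row["leading_edge_cutoff_rank"]),
        log2_fold_enrichment=float(row["log2_fold_enrichment"]),
    )


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file (name <tab> description <tab> genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, ""] + [str(g) for g in genes]) + "\n")
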