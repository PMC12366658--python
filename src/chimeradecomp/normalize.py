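"""Equal-depth resampled normalization of pseudobulk count tables.

Naive counts-per-10k normalization biases log fold-changes when the four
species-environment combinations were sequenced to very different depths,
because the pseudocount is worth more in a shallow column.  The fix used
here: downsample every combination column (without replacement, i.e.
multivariate hypergeometric) to the smallest column total, average the
resampled counts over ``n_reps`` draws, then add the pseudocount and convert
to counts per ``scale``.

Worked example: with column totals (1e6, 1e6, 1e6, 1e5) for (DM, HM, HR, DR)
and raw counts (99, 99, 0, 0), direct normalization gives (1, 1, 0.01, 0.1),
so DM/HR = 100 while DM/DR = 10 -- a 10-fold discrepancy created purely by
depth.  Equal-depth resampling removes it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_random_state

from .ingest import COMBOS, ComboCountTable

__all__ = [
    "NormalizedQuartet",
    "EqualDepthNormalizer",
    "normalize_direct",
    "normalize_resampled",
    "log1p_cp10k",
]


@dataclass(frozen=True)
class NormalizedQuartet:
    """Normalized (pseudocounted, per-``scale``) values of one gene in the four combinations."""

    gene_id: str
    HM: float
    HR: float
    DM: float
    DR: float


class EqualDepthNormalizer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer for pseudobulk count normalization.

    Input ``X`` is a genes x combinations matrix of raw non-negative integer
    counts (any number of columns; the chimera framework uses the four
    combination columns).  The transformer is stateless: the downsampling
    target (the minimum column total) is a property of the table being
    transformed, so ``fit`` only validates.

    Parameters
    ----------
    n_reps : int, default 100
        Number of independent equal-depth resampling draws averaged before
        normalization.
    scale : float, default 10000
        Normalized counts are per this many total counts.
    pseudocount : float, default 1
        Added to the (mean resampled) count of every gene before dividing by
        the column total, guaranteeing strictly positive output.
    resample : bool, default True
        If False, skip resampling and normalize each column by its own raw
        total (direct normalization).
    random_state : int, Generator or None
        Seed for the resampling draws.
    """

    def __init__(
        self,
        n_reps: int = 100,
        scale: float = 10_000.0,
        pseudocount: float = 1.0,
        resample: bool = True,
        random_state=None,
    ):
        self.n_reps = n_reps
        self.scale = scale
        self.pseudocount = pseudocount
        self.resample = resample
        self.random_state = random_state

    def _validate(self, X) -> np.ndarray:
        X = check_array(X, dtype=None, ensure_2d=True)
        X = np.asarray(X)
        if np.any(X < 0):
            raise ValueError("counts must be non-negative")
        totals = X.sum(axis=0)
        if np.any(totals <= 0):
            bad = int(np.flatnonzero(totals <= 0)[0])
            raise ValueError(f"column {bad} has zero total counts")
        return X

    def fit(self, X, y=None):
        X = self._validate(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "n_features_in_")
        X = self._validate(X)
        if not self.resample:
            totals = X.sum(axis=0, dtype=float)
            return (X + self.pseudocount) / totals * self.scale

        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        counts = np.rint(X).astype(np.int64)
        if not np.allclose(counts, X):
            raise ValueError("resampling requires integer counts")
        rng = np.random.default_rng(
            self.random_state
            if isinstance(self.random_state, (int, np.integer, np.random.Generator))
            or self.random_state is None
            else check_random_state(self.random_state).randint(2**31)
        )
        totals = counts.sum(axis=0)
        target = int(totals.min())
        mean = np.empty(counts.shape, dtype=float)
        for j in range(counts.shape[1]):
            if totals[j] == target:
                # downsampling a column to its own total is the identity
                mean[:, j] = counts[:, j]
                continue
            draws = rng.multivariate_hypergeometric(
                counts[:, j], target, size=self.n_reps, method="marginals"
            )
            mean[:, j] = draws.mean(axis=0)
        return (mean + self.pseudocount) / float(target) * self.scale


def _as_count_frame(table) -> pd.DataFrame:
    if isinstance(table, ComboCountTable):
        return table.counts
    df = pd.DataFrame(table)
    missing = [c for c in COMBOS if c not in df.columns]
    if missing:
        raise ValueError(f"count table missing combination columns: {missing}")
    return df[list(COMBOS)]


def normalize_direct(
    table,
    scale: float = 10_000.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Pseudocounted counts-per-``scale`` normalization, column by column.

    value = (count + pseudocount) / column_total * scale, where the column
    total is the raw (un-pseudocounted) sum.
    """
    df = _as_count_frame(table)
    norm = EqualDepthNormalizer(
        scale=scale, pseudocount=pseudocount, resample=False
    ).fit_transform(df.to_numpy())
    return pd.DataFrame(norm, index=df.index, columns=df.columns)


def normalize_resampled(
    table,
    n_reps: int = 100,
    scale: float = 10_000.0,
    pseudocount: float = 1.0,
    seed=None,
) -> pd.DataFrame:
    """Equal-depth resampled normalization (see module docstring).

    Each column is downsampled without replacement to the minimum column
    total ``n_reps`` times; per-gene resampled counts are averaged, then
    pseudocounted and converted to counts per ``scale``.  Deterministic
    given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    df = _as_count_frame(table)
    norm = EqualDepthNormalizer(
        n_reps=n_reps,
        scale=scale,
        pseudocount=pseudocount,
        resample=True,
        random_state=seed,
    ).fit_transform(df.to_numpy())
    return pd.DataFrame(norm, index=df.index, columns=df.columns)


def log1p_cp10k(counts, scale: float = 10_000.0) -> np.ndarray:
    """Per-cell log-normalization (ln(1 + counts-per-10k)) for visualization."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.log1p(counts / totals * scale)
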