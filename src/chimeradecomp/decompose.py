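"""Decomposition of reciprocal-chimera quartets into divergence components.

A *quartet* holds the four normalized measurements of one gene (or any other
cellular trait) in one cell type:

====  =========================================================
HM    host mouse   -- mouse cells in a mouse-like environment
HR    host rat     -- rat cells in a rat-like environment
DM    donor mouse  -- mouse cells in a rat-like environment
DR    donor rat    -- rat cells in a mouse-like environment
====  =========================================================

Modeling each measurement as the product of a cell-intrinsic and a
cell-extrinsic factor, the quartet yields two independent estimates of the
intrinsic (between-species) divergence and two of the extrinsic
(between-environment) divergence, all in log2 units::

    I1 = log2(HR / DM)      I2 = log2(DR / HM)
    E1 = log2(DM / HM)      E2 = log2(HR / DR)

In the absence of intrinsic-extrinsic interaction the paired estimates agree;
their discrepancy estimates the interaction::

    I = (I1 + I2) / 2
    E = (E1 + E2) / 2
    N = (I1 - I2) / 2  ==  (E2 - E1) / 2

Positive I and E mean higher expression in rat cells / the rat-like
environment; positive N means higher expression in species-matched
environments.  The proportions Ip, Ep, Np divide each magnitude by the sum of
the three magnitudes, and signed proportions carry the component's sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "QUARTET_COLS",
    "DecompositionResult",
    "QuartetDecomposer",
    "decompose",
    "decompose_table",
    "divergence_filter",
]

#: Canonical column order for quartet tables.
QUARTET_COLS = ("HM", "HR", "DM", "DR")

#: Numeric output columns, in order, of :class:`QuartetDecomposer.transform`.
COMPONENT_COLS = (
    "I1",
    "I2",
    "E1",
    "E2",
    "I",
    "E",
    "N",
    "Ip",
    "Ep",
    "Np",
    "signed_Ip",
    "signed_Ep",
    "signed_Np",
    "passed_divergence_filter",
)


@dataclass(frozen=True)
class DecompositionResult:
    """Divergence components for a single gene or trait."""

    gene_id: str
    I1: float
    I2: float
    E1: float
    E2: float
    I: float
    E: float
    N: float
    Ip: float
    Ep: float
    Np: float
    signed_Ip: float
    signed_Ep: float
    signed_Np: float
    passed_divergence_filter: bool


def _decompose_arrays(
    hm: np.ndarray,
    hr: np.ndarray,
    dm: np.ndarray,
    dr: np.ndarray,
    min_abs_lfc: float = 0.5,
) -> dict[str, np.ndarray]:
    """Vectorized decomposition; inputs must be strictly positive."""
    hm, hr, dm, dr = (np.asarray(x, dtype=float) for x in (hm, hr, dm, dr))
    for name, arr in zip(QUARTET_COLS, (hm, hr, dm, dr)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite value in quartet column {name!r}")
        if np.any(arr <= 0):
            raise ValueError(
                f"quartet column {name!r} contains non-positive values; "
                "normalized quartets must be strictly positive (use a pseudocount)"
            )

    i1 = np.log2(hr / dm)
    i2 = np.log2(dr / hm)
    e1 = np.log2(dm / hm)
    e2 = np.log2(hr / dr)
    i = (i1 + i2) / 2.0
    e = (e1 + e2) / 2.0
    n = (i1 - i2) / 2.0

    mags = np.abs(i) + np.abs(e) + np.abs(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        ip = np.where(mags > 0, np.abs(i) / mags, np.nan)
        ep = np.where(mags > 0, np.abs(e) / mags, np.nan)
        np_ = np.where(mags > 0, np.abs(n) / mags, np.nan)
    passed = (
        np.maximum.reduce([np.abs(i1), np.abs(i2), np.abs(e1), np.abs(e2)])
        > min_abs_lfc
    )
    return {
        "I1": i1,
        "I2": i2,
        "E1": e1,
        "E2": e2,
        "I": i,
        "E": e,
        "N": n,
        "Ip": ip,
        "Ep": ep,
        "Np": np_,
        "signed_Ip": np.sign(i) * ip,
        "signed_Ep": np.sign(e) * ep,
        "signed_Np": np.sign(n) * np_,
        "passed_divergence_filter": passed,
    }


def _quartet_values(q) -> tuple[str, float, float, float, float]:
    """Extract (gene_id, HM, HR, DM, DR) from a quartet-like object."""
    if hasattr(q, "HM"):
        gene_id = getattr(q, "gene_id", "")
        return gene_id, q.HM, q.HR, q.DM, q.DR
    if isinstance(q, Mapping):
        gene_id = str(q.get("gene_id", ""))
        return gene_id, q["HM"], q["HR"], q["DM"], q["DR"]
    vals = tuple(q)
    if len(vals) != 4:
        raise ValueError("quartet sequence must have exactly four values (HM, HR, DM, DR)")
    return "", *vals


def decompose(q, min_abs_lfc: float = 0.5) -> DecompositionResult:
    """Decompose one quartet into intrinsic, extrinsic, and interaction divergence.

    Parameters
    ----------
    q
        A quartet: any object with attributes or keys ``HM, HR, DM, DR``
        (optionally ``gene_id``), or a sequence in that order.  All four
        values must be strictly positive.
    min_abs_lfc
        Divergence-evidence threshold: the result's
        ``passed_divergence_filter`` is true iff at least one of
        ``|I1|, |I2|, |E1|, |E2|`` strictly exceeds this value.
    """
    gene_id, hm, hr, dm, dr = _quartet_values(q)
    out = _decompose_arrays(
        np.array([hm]), np.array([hr]), np.array([dm]), np.array([dr]), min_abs_lfc
    )
    scalars = {k: v[0] for k, v in out.items()}
    scalars["passed_divergence_filter"] = bool(scalars["passed_divergence_filter"])
    return DecompositionResult(gene_id=gene_id, **scalars)


def divergence_filter(q, min_abs_lfc: float = 0.5) -> bool:
    """True iff the quartet shows evidence of divergence.

    A gene is considered measurably diverged when at least one of the four
    log2 fold-change estimates (I1, I2, E1, E2) has magnitude strictly
    greater than ``min_abs_lfc``.
    """
    return decompose(q, min_abs_lfc=min_abs_lfc).passed_divergence_filter


def decompose_table(
    quartets,
    min_abs_lfc: float = 0.5,
    cell_type: str | None = None,
) -> pd.DataFrame:
    """Vectorized decomposition of many quartets into a tidy table.

    Parameters
    ----------
    quartets
        Either a DataFrame with columns ``HM, HR, DM, DR`` (gene ids taken
        from a ``gene_id`` column or the index), or an iterable of
        quartet-like objects accepted by :func:`decompose`.
    min_abs_lfc
        Threshold for the divergence-evidence filter.
    cell_type
        Optional label recorded in a ``cell_type`` column.

    Returns
    -------
    DataFrame indexed by gene id with one column per component, the (signed)
    proportions, and the filter flag.  Genes failing the filter keep their
    component estimates; proportions are NaN only when all three component
    magnitudes are zero.
    """
    if isinstance(quartets, pd.DataFrame):
        df = quartets
        if "gene_id" in df.columns:
            gene_ids = df["gene_id"].astype(str).to_numpy()
        else:
            gene_ids = df.index.astype(str).to_numpy()
        cols = {c: df[c].to_numpy(dtype=float) for c in QUARTET_COLS}
    else:
        rows = [(lambda t: t)(_quartet_values(q)) for q in quartets]
        gene_ids = np.array([r[0] for r in rows], dtype=object)
        arr = np.array([r[1:] for r in rows], dtype=float).reshape(-1, 4)
        cols = dict(zip(QUARTET_COLS, arr.T))

    if len(gene_ids) != len(set(gene_ids)):
        dupes = pd.Index(gene_ids)
        raise ValueError(
            f"duplicate gene ids in quartet table: {sorted(dupes[dupes.duplicated()])[:5]}"
        )
    if len(gene_ids) == 0:
        out = pd.DataFrame(columns=list(COMPONENT_COLS))
        out.index.name = "gene_id"
        if cell_type is not None:
            out.insert(0, "cell_type", pd.Series(dtype=object))
        return out

    comp = _decompose_arrays(
        cols["HM"], cols["HR"], cols["DM"], cols["DR"], min_abs_lfc
    )
    out = pd.DataFrame(comp, index=pd.Index(gene_ids, name="gene_id"))
    if cell_type is not None:
        out.insert(0, "cell_type", cell_type)
    return out


class QuartetDecomposer(BaseEstimator, TransformerMixin):
    """Stateless sklearn-style transformer wrapping the quartet decomposition.

    Input ``X`` is an ``(n_genes, 4)`` array of strictly positive normalized
    values in ``(HM, HR, DM, DR)`` order; :meth:`transform` returns an
    ``(n_genes, 14)`` array whose columns are ``COMPONENT_COLS`` (the filter
    flag encoded as 0/1).  The transformer learns nothing from the data; fit
    only validates shape, so it composes with sklearn pipelines.

    Parameters
    ----------
    min_abs_lfc : float, default 0.5
        Divergence-evidence threshold applied to |I1|, |I2|, |E1|, |E2|.
    """

    def __init__(self, min_abs_lfc: float = 0.5):
        self.min_abs_lfc = min_abs_lfc

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_features=4)
        if X.shape[1] != 4:
            raise ValueError(
                f"expected 4 quartet columns (HM, HR, DM, DR), got {X.shape[1]}"
            )
        self.n_features_in_ = 4
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "n_features_in_")
        X = check_array(X)
        if X.shape[1] != 4:
            raise ValueError(
                f"expected 4 quartet columns (HM, HR, DM, DR), got {X.shape[1]}"
            )
        comp = _decompose_arrays(
            X[:, 0], X[:, 1], X[:, 2], X[:, 3], self.min_abs_lfc
        )
        return np.column_stack([
            comp[c].astype(float) for c in COMPONENT_COLS
        ])

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(COMPONENT_COLS, dtype=object)
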