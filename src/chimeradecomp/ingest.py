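"""Cell ingest: species assignment, QC, gene filtering, and pseudobulking.

Cells from a dual-genome (barnyard) alignment are assigned a species from the
fraction of reads aligning to each genome, quality-filtered, and then summed
within each cell type into the four species-environment combinations::

    HM  host mouse    (mouse cells, mouse-like environment)
    HR  host rat      (rat cells, rat-like environment)
    DM  donor mouse   (mouse cells, rat-like environment)
    DR  donor rat     (rat cells, mouse-like environment)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "COMBOS",
    "combo_label",
    "ComboCountTable",
    "assign_species",
    "qc_filter",
    "filter_genes_cellfrac",
    "pseudobulk",
    "ingest_dataset",
    "IngestResult",
]

COMBOS = ("HM", "HR", "DM", "DR")

_COMBO_OF = {
    ("mouse", "mouse_like"): "HM",
    ("rat", "rat_like"): "HR",
    ("mouse", "rat_like"): "DM",
    ("rat", "mouse_like"): "DR",
}


def combo_label(species: str, environment: str) -> str:
    """Map a (species, environment) pair to its combination label."""
    try:
        return _COMBO_OF[(species, environment)]
    except KeyError:
        raise ValueError(
            f"unknown species/environment combination: ({species!r}, {environment!r})"
        ) from None


@dataclass
class ComboCountTable:
    """Pseudobulked gene x combination raw count matrix for one cell type.

    ``counts`` is a genes x 4 DataFrame with columns ``HM, HR, DM, DR``;
    ``n_cells`` records how many cells were summed into each column.
    """

    cell_type: str
    counts: pd.DataFrame
    n_cells: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in COMBOS if c not in self.counts.columns]
        if missing:
            raise ValueError(f"ComboCountTable missing combination columns: {missing}")
        self.counts = self.counts[list(COMBOS)]

    @property
    def total_counts(self) -> pd.Series:
        """Raw count total per combination column."""
        return self.counts.sum(axis=0)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index


def assign_species(
    reads_mouse,
    reads_rat,
    threshold: float = 0.70,
) -> np.ndarray:
    """Assign each cell to mouse, rat, or doublet from aligned-read totals.

    A cell is called mouse if at least ``threshold`` (default 70%) of its
    aligned reads map to the mouse genome, rat if at least ``threshold`` map
    to the rat genome, and doublet otherwise.  The boundary is inclusive:
    a cell at exactly 70% mouse is called mouse.
    """
    rm = np.atleast_1d(np.asarray(reads_mouse, dtype=float))
    rr = np.atleast_1d(np.asarray(reads_rat, dtype=float))
    total = rm + rr
    if np.any(total <= 0):
        bad = int(np.flatnonzero(total <= 0)[0])
        raise ValueError(
            f"cell {bad} has zero aligned reads; species fraction is undefined"
        )
    frac_mouse = rm / total
    out = np.where(
        frac_mouse >= threshold,
        "mouse",
        np.where(1.0 - frac_mouse >= threshold, "rat", "doublet"),
    )
    return out


def qc_filter(
    meta: pd.DataFrame,
    mito_max: float = 0.15,
    genes_detected_max: int = 7500,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove low-quality cells.

    A cell is retained iff its mitochondrial read fraction is at most
    ``mito_max`` and its number of detected genes is at most
    ``genes_detected_max`` (cells *strictly above* either threshold are
    rejected).  Returns ``(retained, rejection_log)`` where the log has one
    row per rejected cell with a ``reason`` column.
    """
    for col in ("mito_fraction", "genes_detected"):
        if col not in meta.columns:
            raise ValueError(f"cell metadata is missing required column {col!r}")
    mito_bad = meta["mito_fraction"] > mito_max
    genes_bad = meta["genes_detected"] > genes_detected_max
    reasons = np.where(
        mito_bad & genes_bad, "mito;genes_detected",
        np.where(mito_bad, "mito", np.where(genes_bad, "genes_detected", "")),
    )
    rejected = meta.loc[mito_bad | genes_bad].copy()
    rejected["reason"] = reasons[(mito_bad | genes_bad).to_numpy()]
    retained = meta.loc[~(mito_bad | genes_bad)]
    return retained, rejected


def filter_genes_cellfrac(
    combo_counts: Mapping[str, np.ndarray],
    min_frac: float = 0.20,
) -> np.ndarray:
    """Keep genes expressed in at least ``min_frac`` of cells in >=1 combination.

    ``combo_counts`` maps each of the four combination labels to a
    cells x genes count matrix.  A gene is *expressed* in a cell when its
    count is > 0; the boundary is inclusive (exactly 20% qualifies).
    Returns a boolean gene mask.
    """
    missing = [c for c in COMBOS if c not in combo_counts]
    if missing:
        raise ValueError(f"missing species-environment combinations: {missing}")
    keep = None
    for combo in COMBOS:
        mat = np.asarray(combo_counts[combo])
        if mat.shape[0] == 0:
            raise ValueError(f"combination {combo!r} has zero cells")
        frac = (mat > 0).mean(axis=0)
        keep = frac >= min_frac if keep is None else keep | (frac >= min_frac)
    return keep


def pseudobulk(
    counts: np.ndarray,
    combos: Sequence[str],
    gene_ids: Sequence[str],
    cell_type: str,
    min_cells: int = 10,
    min_counts: int = 10,
) -> ComboCountTable | None:
    """Sum per-cell counts into the four combinations for one cell type.

    Genes with fewer than ``min_counts`` summed counts in *all four*
    combinations are removed (a single combination reaching the floor keeps
    the gene).  If any combination has fewer than ``min_cells`` cells the
    whole cell type is dropped: a warning is logged and ``None`` returned.

    Raises on combination labels outside ``HM/HR/DM/DR``.
    """
    counts = np.asarray(counts)
    combos = np.asarray(combos)
    unknown = set(np.unique(combos)) - set(COMBOS)
    if unknown:
        raise ValueError(f"unknown combination labels: {sorted(unknown)}")

    n_cells = {c: int((combos == c).sum()) for c in COMBOS}
    thin = [c for c in COMBOS if n_cells[c] < min_cells]
    if thin:
        logger.warning(
            "dropping cell type %r: fewer than %d cells in combination(s) %s "
            "(n_cells=%s)", cell_type, min_cells, thin, n_cells,
        )
        return None

    summed = {c: np.asarray(counts[combos == c].sum(axis=0)).ravel() for c in COMBOS}
    table = pd.DataFrame(summed, index=pd.Index(gene_ids, name="gene_id"))
    keep = (table >= min_counts).any(axis=1)
    return ComboCountTable(cell_type=cell_type, counts=table.loc[keep], n_cells=n_cells)


@dataclass
class IngestResult:
    """Output of :func:`ingest_dataset`: per-cell-type pseudobulk tables plus audit info."""

    tables: dict[str, ComboCountTable]
    cell_meta: pd.DataFrame
    rejection_log: pd.DataFrame
    stage_counts: dict[str, int]


def ingest_dataset(
    adata,
    species_threshold: float = 0.70,
    mito_max: float = 0.15,
    genes_detected_max: int = 7500,
    min_cell_frac: float = 0.20,
    min_cells: int = 10,
    min_counts: int = 10,
    gene_whitelist: Sequence[str] | None = None,
) -> IngestResult:
    """Run the full ingest on a dual-genome AnnData.

    ``adata`` must carry per-genome count layers ``"mouse"`` and ``"rat"``
    (cells x genes, shared one-to-one ortholog gene space) and obs columns
    ``environment`` (mouse_like / rat_like), ``cell_type``, ``mito_fraction``
    and ``genes_detected``.  Species are called from the per-genome read
    totals; only the assigned genome's per-gene counts are kept afterwards.
    ``gene_whitelist`` optionally restricts to e.g. autosomal one-to-one
    orthologs before pseudobulking.
    """
    for layer in ("mouse", "rat"):
        if layer not in adata.layers:
            raise ValueError(f"adata is missing per-genome count layer {layer!r}")
    mouse = np.asarray(adata.layers["mouse"])
    rat = np.asarray(adata.layers["rat"])

    reads_mouse = mouse.sum(axis=1)
    reads_rat = rat.sum(axis=1)
    species = assign_species(reads_mouse, reads_rat, threshold=species_threshold)

    meta = adata.obs.copy()
    meta["species"] = species
    meta["reads_mouse"] = reads_mouse
    meta["reads_rat"] = reads_rat
    n_input = len(meta)

    doublets = meta.loc[meta["species"] == "doublet"].copy()
    doublets["reason"] = "doublet"
    meta = meta.loc[meta["species"] != "doublet"]

    retained, qc_rejected = qc_filter(
        meta, mito_max=mito_max, genes_detected_max=genes_detected_max
    )
    rejection_log = pd.concat([doublets, qc_rejected]) if len(doublets) or len(qc_rejected) \
        else qc_rejected

    # Only same-genome per-gene counts are kept after assignment.
    idx = adata.obs_names.get_indexer(retained.index)
    own = np.where(
        (retained["species"] == "mouse").to_numpy()[:, None],
        mouse[idx],
        rat[idx],
    )
    gene_ids = np.asarray(adata.var_names)
    if gene_whitelist is not None:
        keep = np.isin(gene_ids, np.asarray(list(gene_whitelist)))
        own = own[:, keep]
        gene_ids = gene_ids[keep]

    combos = np.array([
        combo_label(s, e)
        for s, e in zip(retained["species"], retained["environment"])
    ])
    retained = retained.assign(combo=combos)

    tables: dict[str, ComboCountTable] = {}
    for ct, sub in retained.groupby("cell_type", observed=True, sort=True):
        rows = retained.index.get_indexer(sub.index)
        sub_counts = own[rows]
        sub_combos = combos[rows]
        if any((sub_combos == c).sum() == 0 for c in COMBOS):
            logger.warning("dropping cell type %r: empty combination", ct)
            continue
        if any((sub_combos == c).sum() < min_cells for c in COMBOS):
            # pseudobulk logs the detailed warning
            pseudobulk(sub_counts, sub_combos, gene_ids, str(ct), min_cells, min_counts)
            continue
        gene_mask = filter_genes_cellfrac(
            {c: sub_counts[sub_combos == c] for c in COMBOS}, min_frac=min_cell_frac
        )
        table = pseudobulk(
            sub_counts[:, gene_mask],
            sub_combos,
            gene_ids[gene_mask],
            str(ct),
            min_cells=min_cells,
            min_counts=min_counts,
        )
        if table is not None:
            tables[str(ct)] = table

    stage_counts = {
        "cells_input": n_input,
        "cells_doublet": int(len(doublets)),
        "cells_qc_rejected": int(len(qc_rejected)),
        "cells_retained": int(len(retained)),
        "cell_types_retained": len(tables),
    }
    return IngestResult(
        tables=tables,
        cell_meta=retained,
        rejection_log=rejection_log,
        stage_counts=stage_counts,
    )
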