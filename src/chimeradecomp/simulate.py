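"""Synthetic reciprocal-chimera data with known ground truth.

The generator mirrors the multiplicative latent model behind the
decomposition: the expected log2 expression of gene *g* in a cell of species
*s* living in environment *e* is::

    baseline_g + I_g * [s == rat] + E_g * [e == rat_like] + N_g * [s != e]

with ``I_g`` the intrinsic (rat minus mouse) effect, ``E_g`` the extrinsic
(rat-like minus mouse-like environment) effect, and ``N_g`` a symmetric
mismatch penalty applied to both species-mismatched combinations (donor
mouse and donor rat), the pattern shown by imprinted genes.  Note the sign
convention: a *positive* ``N_g`` here means higher expression in mismatched
environments, whereas the decomposition's interaction estimate
``N = (I1 - I2)/2`` is positive when matched environments are higher; the
truth table stores both (``interaction`` and ``interaction_framework = -interaction``).

Counts are negative binomial (gamma-Poisson) around per-cell expectations,
with log-normal per-cell library-size variation and distinct sequencing
depths and cell numbers per combination.  A configurable fraction of
barcodes are mixed-species doublets whose reads split between the two
genomes so that neither genome reaches the 70% species-assignment rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import anndata as ad
import numpy as np
import pandas as pd

from .ingest import COMBOS

__all__ = [
    "EffectSpec",
    "SyntheticDataset",
    "generate_chimera_counts",
    "generate_timecourse_table",
    "generate_if_image",
    "IFImage",
]

_SPECIES_OF = {"HM": "mouse", "HR": "rat", "DM": "mouse", "DR": "rat"}
_ENV_OF = {"HM": "mouse_like", "HR": "rat_like", "DM": "rat_like", "DR": "mouse_like"}
_MISMATCH = {"HM": 0.0, "HR": 0.0, "DM": 1.0, "DR": 1.0}
_IS_RAT = {"HM": 0.0, "HR": 1.0, "DM": 0.0, "DR": 1.0}
_IS_RAT_ENV = {"HM": 0.0, "HR": 1.0, "DM": 1.0, "DR": 0.0}


@dataclass(frozen=True)
class EffectSpec:
    """Distributions of the planted per-gene log2 effects.

    Defaults follow the intrinsic-dominant regime seen in real chimera data:
    intrinsic effects have the largest spread, extrinsic effects roughly
    half, interaction the smallest.  ``n_imprinted`` genes (the last genes in
    the table) additionally receive a mismatch-environment effect with
    magnitude uniform in ``(imprinted_min_abs, imprinted_max_abs)`` and
    random sign.
    """

    sigma_intrinsic: float = 1.0
    sigma_extrinsic: float = 0.5
    sigma_interaction: float = 0.25
    baseline_mean: float = 0.0
    baseline_sd: float = 1.5
    n_imprinted: int = 0
    imprinted_min_abs: float = 1.0
    imprinted_max_abs: float = 2.0


@dataclass
class SyntheticDataset:
    """A simulated reciprocal-chimera scRNA-seq experiment.

    ``adata`` holds cells x genes counts with per-genome layers ``"mouse"``
    and ``"rat"`` (X is their sum) and obs columns ``true_species``,
    ``environment``, ``cell_type``, ``is_doublet``, ``mito_fraction``,
    ``genes_detected``.  ``truth`` has one row per gene: the planted
    ``baseline_log2``, ``intrinsic``, ``extrinsic``, ``interaction`` (and its
    framework-sign twin), ``is_imprinted``, plus the expected quartet of
    model-scale means in columns ``HM, HR, DM, DR``.
    """

    adata: ad.AnnData
    truth: pd.DataFrame
    seed: int

    @property
    def cell_meta(self) -> pd.DataFrame:
        return self.adata.obs


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with mean ``mean`` and NB size ``dispersion``."""
    lam = rng.gamma(shape=dispersion, scale=np.maximum(mean, 1e-300) / dispersion)
    return rng.poisson(lam)


def generate_chimera_counts(
    n_genes: int,
    cells_per_combo: dict[str, int] | None = None,
    effect_spec: EffectSpec | None = None,
    depth_per_combo: dict[str, float] | None = None,
    doublet_fraction: float = 0.05,
    dispersion: float = 10.0,
    library_size_sd: float = 0.35,
    cross_genome_rate: float = 0.01,
    qc_outlier_fraction: float = 0.02,
    cell_type: str = "synthetic",
    planted: dict[str, np.ndarray] | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Simulate a reciprocal-chimera scRNA-seq dataset with planted effects.

    Parameters
    ----------
    n_genes
        Number of one-to-one ortholog genes.
    cells_per_combo
        Cells per combination, e.g. ``{"HM": 200, "HR": 200, "DM": 80,
        "DR": 40}``; unequal numbers emulate the scarcity of donor cells.
        Default 200/200/80/40.
    effect_spec
        Distributions of the planted effects (see :class:`EffectSpec`).
    depth_per_combo
        Mean aligned reads per cell per combination; unequal depths exercise
        the equal-depth normalization.  Default
        ``{"HM": 5000, "HR": 5000, "DM": 3000, "DR": 1500}``.
    doublet_fraction
        Extra mixed-species barcodes emitted per combination, as a fraction
        of that combination's cells.
    dispersion
        Negative binomial size parameter (larger = closer to Poisson).
    cross_genome_rate
        Fraction of a singlet's reads mis-assigned to the other genome.
    qc_outlier_fraction
        Fraction of cells given a high mitochondrial fraction so the QC
        filter has work to do.
    planted
        Optional explicit per-gene effect arrays (length ``n_genes``) for
        any of ``baseline_log2``, ``intrinsic``, ``extrinsic``,
        ``interaction``, overriding the random draws -- useful for planting
        exact effects.
    seed
        Single top-level seed; identical seeds give identical datasets.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    cells_per_combo = dict(cells_per_combo or {"HM": 200, "HR": 200, "DM": 80, "DR": 40})
    depth_per_combo = dict(depth_per_combo or {"HM": 5000.0, "HR": 5000.0, "DM": 3000.0, "DR": 1500.0})
    effect_spec = effect_spec or EffectSpec()
    for combo in COMBOS:
        if cells_per_combo.get(combo, 0) <= 0:
            raise ValueError(
                f"combination {combo!r} has zero cells; the framework needs all four"
            )
        if depth_per_combo.get(combo, 0) <= 0:
            raise ValueError(f"combination {combo!r} has non-positive depth")

    rng = np.random.default_rng(seed)
    gene_ids = np.array([f"g{i:05d}" for i in range(n_genes)])

    baseline = rng.normal(effect_spec.baseline_mean, effect_spec.baseline_sd, n_genes)
    intrinsic = rng.normal(0.0, effect_spec.sigma_intrinsic, n_genes) \
        if effect_spec.sigma_intrinsic > 0 else np.zeros(n_genes)
    extrinsic = rng.normal(0.0, effect_spec.sigma_extrinsic, n_genes) \
        if effect_spec.sigma_extrinsic > 0 else np.zeros(n_genes)
    interaction = rng.normal(0.0, effect_spec.sigma_interaction, n_genes) \
        if effect_spec.sigma_interaction > 0 else np.zeros(n_genes)
    if planted:
        unknown = set(planted) - {"baseline_log2", "intrinsic", "extrinsic", "interaction"}
        if unknown:
            raise ValueError(f"unknown planted effect names: {sorted(unknown)}")
        arrays = {"baseline_log2": baseline, "intrinsic": intrinsic,
                  "extrinsic": extrinsic, "interaction": interaction}
        for name, values in planted.items():
            values = np.asarray(values, dtype=float)
            if values.shape != (n_genes,):
                raise ValueError(f"planted {name!r} must have shape ({n_genes},)")
            arrays[name][:] = values
    is_imprinted = np.zeros(n_genes, dtype=bool)
    k = int(effect_spec.n_imprinted)
    if k > 0:
        if k > n_genes:
            raise ValueError("n_imprinted exceeds n_genes")
        mag = rng.uniform(effect_spec.imprinted_min_abs, effect_spec.imprinted_max_abs, k)
        sign = rng.choice([-1.0, 1.0], size=k)
        interaction[-k:] = interaction[-k:] + mag * sign
        is_imprinted[-k:] = True

    # Expected log2 mean per gene per combination, on the latent model scale.
    log2_mean = {
        c: baseline
        + intrinsic * _IS_RAT[c]
        + extrinsic * _IS_RAT_ENV[c]
        + interaction * _MISMATCH[c]
        for c in COMBOS
    }
    rel = {c: 2.0 ** log2_mean[c] for c in COMBOS}
    prop = {c: rel[c] / rel[c].sum() for c in COMBOS}

    blocks_mouse, blocks_rat, obs_rows = [], [], []
    barcode_counter = 0

    def _emit(counts_own, counts_other, species, combo, is_doublet):
        nonlocal barcode_counter
        n = counts_own.shape[0]
        if species == "mouse":
            blocks_mouse.append(counts_own)
            blocks_rat.append(counts_other)
        else:
            blocks_rat.append(counts_own)
            blocks_mouse.append(counts_other)
        for i in range(n):
            obs_rows.append(
                {
                    "barcode": f"bc{barcode_counter:06d}",
                    "true_species": "doublet" if is_doublet else species,
                    "environment": _ENV_OF[combo],
                    "cell_type": cell_type,
                    "is_doublet": is_doublet,
                }
            )
            barcode_counter += 1

    for combo in COMBOS:
        n = cells_per_combo[combo]
        depth = depth_per_combo[combo]
        species = _SPECIES_OF[combo]
        p = prop[combo]
        libs = depth * rng.lognormal(-0.5 * library_size_sd**2, library_size_sd, n)
        mean = libs[:, None] * p[None, :]
        own = _nb_counts(rng, mean, dispersion)
        # a small fraction of reads lands on the other genome
        other = rng.binomial(own, cross_genome_rate)
        own = own - other
        _emit(own, other, species, combo, is_doublet=False)

        # doublets: a cell of each species sharing one barcode in this environment
        n_dbl = int(round(doublet_fraction * n))
        if n_dbl > 0:
            env = _ENV_OF[combo]
            combo_m = "HM" if env == "mouse_like" else "DM"
            combo_r = "DR" if env == "mouse_like" else "HR"
            dbl_m = np.empty((n_dbl, n_genes), dtype=np.int64)
            dbl_r = np.empty((n_dbl, n_genes), dtype=np.int64)
            for i in range(n_dbl):
                while True:
                    f = rng.uniform(0.3, 0.7)
                    lib = depth * rng.lognormal(-0.5 * library_size_sd**2, library_size_sd)
                    cm = _nb_counts(rng, f * lib * prop[combo_m], dispersion)
                    cr = _nb_counts(rng, (1 - f) * lib * prop[combo_r], dispersion)
                    tot = cm.sum() + cr.sum()
                    if tot > 0:
                        frac = cm.sum() / tot
                        # enforce the planted property that doublets fail the 70% rule
                        if 0.3 < frac < 0.7:
                            break
                dbl_m[i] = cm
                dbl_r[i] = cr
            _emit(dbl_m, dbl_r, "mouse", combo, is_doublet=True)

    counts_mouse = np.vstack(blocks_mouse)
    counts_rat = np.vstack(blocks_rat)
    obs = pd.DataFrame(obs_rows).set_index("barcode")

    n_cells_total = len(obs)
    mito = rng.beta(2.0, 38.0, n_cells_total)
    outliers = rng.random(n_cells_total) < qc_outlier_fraction
    mito[outliers] = rng.beta(8.0, 24.0, outliers.sum())
    obs["mito_fraction"] = mito
    obs["genes_detected"] = ((counts_mouse + counts_rat) > 0).sum(axis=1)

    adata = ad.AnnData(
        X=counts_mouse + counts_rat,
        obs=obs,
        var=pd.DataFrame(index=pd.Index(gene_ids, name="gene_id")),
        layers={"mouse": counts_mouse, "rat": counts_rat},
        uns={
            "seed": seed,
            "cells_per_combo": cells_per_combo,
            "depth_per_combo": {k: float(v) for k, v in depth_per_combo.items()},
            "effect_spec": asdict(effect_spec),
        },
    )

    truth = pd.DataFrame(
        {
            "baseline_log2": baseline,
            "intrinsic": intrinsic,
            "extrinsic": extrinsic,
            "interaction": interaction,
            "interaction_framework": -interaction,
            "is_imprinted": is_imprinted,
            **{c: rel[c] for c in COMBOS},
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return SyntheticDataset(adata=adata, truth=truth, seed=seed)


def generate_timecourse_table(
    n_genes: int,
    classes: dict[str, float] | None = None,
    seed: int = 0,
    timepoints: tuple[str, ...] = ("E11.5", "E13.5", "E15.25"),
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a 3-timepoint, 2-species bulk expression table with class labels.

    ``classes`` gives the proportions of ``similar``, ``opposite`` and
    ``temporal_shift`` genes (the remainder is unclassified); they must sum
    to at most 1.  Trajectories are noise-free by construction, so
    :func:`chimeradecomp.traits.classify_dynamics` recovers the labels
    exactly:

    - *similar*: geometric trajectories with the same direction in both
      species, offset by >= 0.5 log2 units (so they are not temporal shifts);
    - *temporal_shift*: shared trajectory, rat lagging at the first
      timepoint, |species log2FC| < 0.25 at the two later timepoints;
    - *opposite*: the rat trajectory is the mouse one reversed;
    - *unclassified*: rat expression is a tent (up-down), giving a species
      correlation product between the two thresholds.
    """
    if len(timepoints) < 3:
        raise ValueError("at least 3 timepoints are required")
    classes = dict(classes or {"similar": 0.4, "opposite": 0.2, "temporal_shift": 0.2})
    extra = set(classes) - {"similar", "opposite", "temporal_shift"}
    if extra:
        raise ValueError(f"unknown dynamics classes: {sorted(extra)}")
    if sum(classes.values()) > 1 + 1e-12:
        raise ValueError("class proportions must sum to <= 1")

    rng = np.random.default_rng(seed)
    n_sim = int(round(classes.get("similar", 0.0) * n_genes))
    n_opp = int(round(classes.get("opposite", 0.0) * n_genes))
    n_shift = int(round(classes.get("temporal_shift", 0.0) * n_genes))
    n_unc = n_genes - n_sim - n_opp - n_shift
    if n_unc < 0:
        n_unc = 0

    t = np.arange(len(timepoints), dtype=float)
    rows, labels = [], []
    gene_idx = 0

    def _traj(slope, base):
        return base * 2.0 ** (slope * t)

    for _ in range(n_sim):
        slope = rng.choice([-1.0, 1.0]) * rng.uniform(0.7, 1.3)
        base = 2.0 ** rng.uniform(0, 3)
        offset = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.5)
        mouse = _traj(slope, base)
        rat = mouse * 2.0**offset
        rows.append(np.concatenate([mouse, rat]))
        labels.append("similar")
        gene_idx += 1
    for _ in range(n_opp):
        slope = rng.choice([-1.0, 1.0]) * rng.uniform(0.7, 1.3)
        base = 2.0 ** rng.uniform(0, 3)
        mouse = _traj(slope, base)
        rows.append(np.concatenate([mouse, mouse[::-1]]))
        labels.append("opposite")
        gene_idx += 1
    for _ in range(n_shift):
        slope = rng.choice([-1.0, 1.0]) * rng.uniform(0.7, 1.3)
        base = 2.0 ** rng.uniform(0, 3)
        mouse = _traj(slope, base)
        eps = rng.uniform(-0.2, 0.2, 2)
        rat = mouse.copy()
        rat[0] = mouse[0] * 2.0 ** (-0.5 * np.sign(slope))  # rat lags at the first stage
        rat[1] = mouse[1] * 2.0 ** eps[0]
        rat[2] = mouse[2] * 2.0 ** eps[1]
        rows.append(np.concatenate([mouse, rat]))
        labels.append("temporal_shift")
        gene_idx += 1
    for _ in range(n_unc):
        base = 2.0 ** rng.uniform(0, 3)
        mouse = _traj(rng.choice([-1.0, 1.0]) * rng.uniform(0.7, 1.3), base)
        rat = np.array([base, base * 2.0, base])  # tent: zero stage correlation
        rows.append(np.concatenate([mouse, rat]))
        labels.append("unclassified")
        gene_idx += 1

    columns = [f"mouse_{tp}" for tp in timepoints] + [f"rat_{tp}" for tp in timepoints]
    index = pd.Index([f"g{i:05d}" for i in range(len(rows))], name="gene_id")
    table = pd.DataFrame(rows, index=index, columns=columns)
    return table, pd.Series(labels, index=index, name="dynamics_class")


@dataclass
class IFImage:
    """A synthetic multi-channel immunofluorescence image with ground truth.

    ``channels`` is a (3, H, W) float array ordered (DAPI, TdTomato, target).
    The truth masks mark donor vs host nuclei pixels; truth intensities are
    the noiseless target values inside each compartment (background excluded).
    """

    channels: np.ndarray
    donor_mask: np.ndarray
    host_mask: np.ndarray
    donor_truth_intensity: float
    host_truth_intensity: float
    background: float


def _disk_mask(shape, center, radius) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def generate_if_image(
    shape: tuple[int, int],
    donor_blobs: list[tuple[tuple[float, float], float, float]],
    host_intensity: float,
    background: float = 0.0,
    host_blobs: list[tuple[tuple[float, float], float]] | None = None,
    n_host_blobs: int = 12,
    host_blob_radius: float = 8.0,
    host_clearance: float = 12.0,
    clear_roi: tuple[int, int, int, int] | None = None,
    dapi_level: float = 100.0,
    tdt_level: float = 200.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> IFImage:
    """Simulate a (DAPI, TdTomato, target) image with circular nuclei.

    ``donor_blobs`` is a list of ``((row, col), radius, target_intensity)``
    tuples; donor nuclei carry TdTomato signal, host nuclei do not.  Host
    nuclei either come from ``host_blobs`` (``((row, col), radius)``) or are
    placed uniformly at random, keeping at least ``host_clearance`` pixels
    away from donor blobs (so a blurred DAPI halo from a host nucleus never
    bleeds into a donor mask) and out of ``clear_roi`` (reserve it for
    background measurement).  The target channel is
    ``intensity + background`` inside nuclei, ``background`` outside, plus
    optional Gaussian noise (clipped at zero).

    Raises if any blob leaves the image bounds or donor and host regions
    overlap.
    """
    h, w = shape
    rng = np.random.default_rng(seed)
    donor_mask = np.zeros(shape, dtype=bool)
    for (cy, cx), r, _ in donor_blobs:
        if cy - r < 0 or cy + r >= h or cx - r < 0 or cx + r >= w:
            raise ValueError(f"donor blob at ({cy}, {cx}) r={r} leaves image bounds")
        donor_mask |= _disk_mask(shape, (cy, cx), r)

    host_mask = np.zeros(shape, dtype=bool)
    if host_blobs is not None:
        for (cy, cx), r in host_blobs:
            if cy - r < 0 or cy + r >= h or cx - r < 0 or cx + r >= w:
                raise ValueError(f"host blob at ({cy}, {cx}) r={r} leaves image bounds")
            m = _disk_mask(shape, (cy, cx), r)
            if (m & donor_mask).any():
                raise ValueError(f"host blob at ({cy}, {cx}) overlaps a donor blob")
            host_mask |= m
    else:
        placed = 0
        attempts = 0
        r = host_blob_radius
        donor_centers = [(cy, cx, br) for (cy, cx), br, _ in donor_blobs]
        host_centers: list[tuple[float, float]] = []
        while placed < n_host_blobs:
            attempts += 1
            if attempts > 1000 * n_host_blobs:
                raise ValueError("could not place host blobs without overlap")
            cy = rng.uniform(r + 1, h - r - 2)
            cx = rng.uniform(r + 1, w - r - 2)
            too_close = any(
                np.hypot(cy - dy, cx - dx) < r + br + host_clearance
                for dy, dx, br in donor_centers
            ) or any(
                # separated host nuclei: overlapping DAPI halos would bridge
                # between nuclei and admit background pixels into the mask
                np.hypot(cy - hy, cx - hx) < 2 * r + host_clearance
                for hy, hx in host_centers
            )
            if too_close:
                continue
            if clear_roi is not None:
                r0, r1, c0, c1 = clear_roi
                pad = host_clearance
                if (cy + r >= r0 - pad and cy - r < r1 + pad
                        and cx + r >= c0 - pad and cx - r < c1 + pad):
                    continue
            host_mask |= _disk_mask(shape, (cy, cx), r)
            host_centers.append((cy, cx))
            placed += 1

    nuclei = donor_mask | host_mask
    dapi = np.where(nuclei, dapi_level, 0.0)
    tdt = np.where(donor_mask, tdt_level, 0.0)

    target = np.full(shape, float(background))
    for (cy, cx), r, intensity in donor_blobs:
        target[_disk_mask(shape, (cy, cx), r)] = intensity + background
    target[host_mask] = host_intensity + background
    if noise_sd > 0:
        target = np.clip(target + rng.normal(0.0, noise_sd, shape), 0.0, None)

    donor_truth = float(np.mean([i for _, _, i in donor_blobs])) if donor_blobs else np.nan
    return IFImage(
        channels=np.stack([dapi, tdt, target]),
        donor_mask=donor_mask,
        host_mask=host_mask,
        donor_truth_intensity=donor_truth,
        host_truth_intensity=float(host_intensity),
        background=float(background),
    )
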