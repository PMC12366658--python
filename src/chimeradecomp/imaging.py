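"""Immunofluorescence quantification: blur, mask, measure.

Donor cells carry a TdTomato label, so after Gaussian-blurring the DAPI and
TdTomato channels and thresholding them, DAPI+ TdTomato+ pixels are donor
(species-mismatched environment) and DAPI+ TdTomato- pixels are host.  The
mean target-protein intensity over each compartment (restricted to pixels
with non-zero raw target signal) gives a donor/host log2 fold-change within
one chimera; background-subtracted means support comparisons between the
two reciprocal chimeras, which assemble a protein quartet for the
decomposition.  The blur is never applied to the measured target channel.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
from skimage.filters import gaussian

from .decompose import DecompositionResult, decompose

__all__ = [
    "MaskParams",
    "IntensityMeasurement",
    "quantify_if",
    "if_decompose",
    "mask_robustness_sweep",
]


@dataclass(frozen=True)
class MaskParams:
    """Blur-and-threshold parameters for the DAPI / TdTomato masks.

    ``roi`` is an optional half-open rectangle ``(row0, row1, col0, col1)``
    in pixel coordinates, origin top-left.
    """

    gaussian_sigma_dapi: float = 2.0
    gaussian_sigma_tdt: float = 2.0
    dapi_cutoff: float = 10.0
    tdt_cutoff: float = 10.0
    roi: tuple[int, int, int, int] | None = None

    def __post_init__(self):
        if self.gaussian_sigma_dapi <= 0 or self.gaussian_sigma_tdt <= 0:
            raise ValueError("Gaussian sigmas must be positive")


@dataclass(frozen=True)
class IntensityMeasurement:
    """Mean target intensities for one chimera image."""

    donor_mean: float
    host_mean: float
    background_mean: float
    n_donor_pixels: int
    n_host_pixels: int
    log2fc_within: float

    @property
    def donor_mean_subtracted(self) -> float:
        return self.donor_mean - self.background_mean

    @property
    def host_mean_subtracted(self) -> float:
        return self.host_mean - self.background_mean


def _rect_slice(rect: tuple[int, int, int, int]) -> tuple[slice, slice]:
    r0, r1, c0, c1 = rect
    if r0 >= r1 or c0 >= c1:
        raise ValueError(f"degenerate rectangle {rect}")
    return slice(r0, r1), slice(c0, c1)


def quantify_if(
    image: np.ndarray,
    params: MaskParams,
    background_roi: tuple[int, int, int, int],
) -> IntensityMeasurement:
    """Measure donor and host target intensity in one (DAPI, TdTomato, target) image.

    ``image`` is (3, H, W).  The DAPI and TdTomato channels are blurred with
    their Gaussian sigmas and thresholded at their cutoffs; donor pixels are
    DAPI+ & TdT+, host pixels DAPI+ & TdT-.  Means are taken over pixels
    with non-zero *raw* target intensity.  ``background_roi`` is a
    rectangle with no nuclei whose mean raw target signal is stored for
    between-chimera comparisons; the within-chimera log2 fold-change uses
    unsubtracted means.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[0] != 3:
        raise ValueError("image must be (3, H, W): DAPI, TdTomato, target")
    dapi, tdt, target = image

    if params.roi is not None:
        rs, cs = _rect_slice(params.roi)
        if params.roi[1] > dapi.shape[0] or params.roi[3] > dapi.shape[1]:
            raise ValueError("roi exceeds image bounds")
        dapi, tdt, target = dapi[rs, cs], tdt[rs, cs], target[rs, cs]

    dapi_mask = gaussian(dapi, sigma=params.gaussian_sigma_dapi, preserve_range=True) > params.dapi_cutoff
    tdt_mask = gaussian(tdt, sigma=params.gaussian_sigma_tdt, preserve_range=True) > params.tdt_cutoff

    # background is checked and measured on full-image coordinates
    rs, cs = _rect_slice(background_roi)
    full = np.asarray(image, dtype=float)
    bg_dapi = gaussian(full[0], sigma=params.gaussian_sigma_dapi, preserve_range=True) > params.dapi_cutoff
    if bg_dapi[rs, cs].any():
        raise ValueError("background_roi overlaps DAPI+ pixels")
    background_mean = float(full[2][rs, cs].mean())

    donor = dapi_mask & tdt_mask
    host = dapi_mask & ~tdt_mask
    nonzero = target > 0
    donor_px = donor & nonzero
    host_px = host & nonzero
    if donor_px.sum() == 0:
        raise ValueError("donor mask (DAPI+ TdTomato+) is empty")
    if host_px.sum() == 0:
        raise ValueError("host mask (DAPI+ TdTomato-) is empty")

    donor_mean = float(target[donor_px].mean())
    host_mean = float(target[host_px].mean())
    return IntensityMeasurement(
        donor_mean=donor_mean,
        host_mean=host_mean,
        background_mean=background_mean,
        n_donor_pixels=int(donor_px.sum()),
        n_host_pixels=int(host_px.sum()),
        log2fc_within=float(np.log2(donor_mean / host_mean)),
    )


def if_decompose(
    rat_like: IntensityMeasurement,
    mouse_like: IntensityMeasurement,
    trait_name: str = "protein",
    min_abs_lfc: float = 0.5,
    background_subtract: bool = True,
) -> DecompositionResult:
    """Assemble the protein quartet from the two reciprocal chimeras and decompose.

    In the rat-like chimera the host cells are rat (HR) and the donor cells
    mouse (DM); in the mouse-like chimera the host cells are mouse (HM) and
    the donor cells rat (DR).  Background-subtracted means are used by
    default, as required for comparisons across images.
    """
    def _vals(m: IntensityMeasurement) -> tuple[float, float]:
        if background_subtract:
            d, h = m.donor_mean_subtracted, m.host_mean_subtracted
        else:
            d, h = m.donor_mean, m.host_mean
        if d <= 0 or h <= 0:
            raise ValueError("non-positive background-subtracted mean intensity")
        return d, h

    dm, hr = _vals(rat_like)
    dr, hm = _vals(mouse_like)
    res = decompose({"HM": hm, "HR": hr, "DM": dm, "DR": dr}, min_abs_lfc=min_abs_lfc)
    return DecompositionResult(**{**res.__dict__, "gene_id": trait_name})


def mask_robustness_sweep(
    rat_like_image: np.ndarray,
    mouse_like_image: np.ndarray,
    rat_like_params: MaskParams,
    mouse_like_params: MaskParams,
    rat_like_background_roi: tuple[int, int, int, int],
    mouse_like_background_roi: tuple[int, int, int, int],
    dapi_cutoffs_rat_like: tuple[float, float, float] | None = None,
    tdt_cutoffs_rat_like: tuple[float, float, float] | None = None,
    dapi_cutoffs_mouse_like: tuple[float, float, float] | None = None,
    tdt_cutoffs_mouse_like: tuple[float, float, float] | None = None,
    cutoff_scale: tuple[float, float, float] = (0.8, 1.0, 1.2),
) -> dict:
    """Sensitivity of the four log2 fold-changes to the masking cutoffs.

    Recomputes the quartet log fold-changes (I1, I2, E1, E2) for every
    combination of three DAPI and three TdTomato cutoffs per chimera --
    3**4 = 81 combinations -- and reports the per-quantity standard error
    (standard deviation across combinations).  Cutoff grids default to the
    chosen cutoff scaled by ``cutoff_scale``.  Combinations that empty a
    mask are excluded and counted.
    """
    grids = {
        "dapi_rat": dapi_cutoffs_rat_like or tuple(s * rat_like_params.dapi_cutoff for s in cutoff_scale),
        "tdt_rat": tdt_cutoffs_rat_like or tuple(s * rat_like_params.tdt_cutoff for s in cutoff_scale),
        "dapi_mouse": dapi_cutoffs_mouse_like or tuple(s * mouse_like_params.dapi_cutoff for s in cutoff_scale),
        "tdt_mouse": tdt_cutoffs_mouse_like or tuple(s * mouse_like_params.tdt_cutoff for s in cutoff_scale),
    }
    for name, grid in grids.items():
        if len(grid) != 3:
            raise ValueError(f"cutoff grid {name!r} must have exactly 3 values")

    records = {"I1": [], "I2": [], "E1": [], "E2": []}
    n_failed = 0
    combos = list(itertools.product(grids["dapi_rat"], grids["tdt_rat"], grids["dapi_mouse"], grids["tdt_mouse"]))
    assert len(combos) == 81
    for d_r, t_r, d_m, t_m in combos:
        try:
            m_rat = quantify_if(
                rat_like_image,
                replace(rat_like_params, dapi_cutoff=d_r, tdt_cutoff=t_r),
                rat_like_background_roi,
            )
            m_mouse = quantify_if(
                mouse_like_image,
                replace(mouse_like_params, dapi_cutoff=d_m, tdt_cutoff=t_m),
                mouse_like_background_roi,
            )
        except ValueError:
            n_failed += 1
            continue
        hr, dm = m_rat.host_mean_subtracted, m_rat.donor_mean_subtracted
        hm, dr = m_mouse.host_mean_subtracted, m_mouse.donor_mean_subtracted
        if min(hr, dm, hm, dr) <= 0:
            n_failed += 1
            continue
        records["I1"].append(np.log2(hr / dm))
        records["I2"].append(np.log2(dr / hm))
        records["E1"].append(np.log2(dm / hm))
        records["E2"].append(np.log2(hr / dr))

    out = {
        "n_combinations": 81,
        "n_failed": n_failed,
        "n_used": 81 - n_failed,
    }
    for key, vals in records.items():
        arr = np.asarray(vals)
        out[f"se_{key}"] = float(arr.std(ddof=0)) if arr.size else np.nan
        out[f"mean_{key}"] = float(arr.mean()) if arr.size else np.nan
    out["max_se"] = float(np.nanmax([out[f"se_{k}"] for k in records]))
    return out
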