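"""Apparent-diffusion-coefficient analysis of multi-b diffusion MRI.

The diffusion-weighted signal of a voxel under a mono-exponential model is
``S(b) = S0 exp(-b * ADC)`` with ``b`` the diffusion weighting (s/mm^2) and
ADC the apparent diffusion coefficient (mm^2/s).  The pipeline:

1. fit the ADC per voxel by log-linear least squares over all b-values;
2. segment organoid tissue by automatic thresholding of the highest-b
   image (tissue retains signal at strong weighting, free medium does not);
3. reduce masked ADC values to a 100-bin normalized histogram;
4. denoise the histogram by truncating its Fourier spectrum;
5. locate the distribution's maximal-likelihood position as the midpoint
   of the two interpolated crossings of 2/3 of the denoised peak height —
   a location estimate robust to the asymmetry of tissue ADC profiles;
6. compare groups scan-by-scan through relative deviations from a
   reference group, cancelling longitudinal drift, with a matched t test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from skimage import filters as _skfilters
from skimage import morphology as _skmorph

from .errors import (
    DesignError,
    InvalidInputError,
    InvalidParameterError,
    SegmentationError,
)
from .stats import TestResult, paired_t_test

__all__ = [
    "DWIStack",
    "ADCMap",
    "ADCDistribution",
    "fit_adc_map",
    "segment_organoids",
    "adc_distribution",
    "denoise_distribution",
    "maximal_likelihood_position",
    "scan_ml_position",
    "group_comparison",
]

N_BINS = 100
DEFAULT_KEEP_MODES = 10


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class DWIStack:
    """Aligned diffusion-weighted images, one per b-value.

    ``images`` has shape ``(n_b, *spatial)``; ``b_values`` are strictly
    increasing with ``b_values[0] == 0``.
    """

    images: np.ndarray
    b_values: np.ndarray
    voxel_size: tuple[float, ...] = (0.1, 0.1)
    scan_id: str = ""
    group: str = ""

    def __post_init__(self):
        imgs = np.asarray(self.images, dtype=float)
        b = np.asarray(self.b_values, dtype=float)
        object.__setattr__(self, "images", imgs)
        object.__setattr__(self, "b_values", b)
        if b.ndim != 1 or b.size < 2:
            raise InvalidInputError("need >= 2 b-values")
        if imgs.shape[0] != b.size:
            raise InvalidInputError("one image per b-value required")
        if np.any(np.diff(b) <= 0):
            raise InvalidInputError("b_values must be strictly increasing")
        if b[0] != 0:
            raise InvalidInputError("b_values must include b = 0 first")


@dataclass(frozen=True)
class ADCMap:
    """Per-voxel ADC (mm^2/s), fitted S0, per-voxel R^2 and tissue mask."""

    adc: np.ndarray
    s0: np.ndarray
    fit_r2: np.ndarray
    mask: np.ndarray
    n_excluded: int = 0
    scan_id: str = ""
    group: str = ""

    @property
    def masked_values(self) -> np.ndarray:
        return self.adc[self.mask]


@dataclass(frozen=True)
class ADCDistribution:
    """100-bin normalized ADC histogram with its denoised profile."""

    bin_centers: np.ndarray
    density: np.ndarray
    denoised: np.ndarray | None = None
    ml_position: float | None = None
    i_max: float | None = None
    scan_id: str = ""
    group: str = ""

    def __post_init__(self):
        c = np.asarray(self.bin_centers, dtype=float)
        d = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "bin_centers", c)
        object.__setattr__(self, "density", d)
        if c.shape != d.shape:
            raise InvalidInputError("bin_centers and density must match")
        if not np.isclose(d.sum(), 1.0, atol=1e-8):
            raise InvalidInputError("density must sum to 1")


# ---------------------------------------------------------------------------
# operations


def fit_adc_map(stack: DWIStack, mask: np.ndarray | None = None) -> ADCMap:
    """Per-voxel mono-exponential fit ``ln S(b) = ln S0 - b ADC``.

    Ordinary least squares on the log signal over all b-values.  Voxels
    with any non-positive intensity, or with a negative fitted ADC, are
    excluded from the mask and counted in ``n_excluded``.
    """
    imgs = stack.images
    b = stack.b_values
    spatial = imgs.shape[1:]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != spatial:
            raise InvalidInputError("mask shape mismatch")

    flat = imgs.reshape(imgs.shape[0], -1)
    positive = np.all(flat > 0, axis=0)
    logs = np.where(flat > 0, np.log(np.where(flat > 0, flat, 1.0)), 0.0)

    # closed-form simple linear regression of log-signal on b, vectorized
    bm = b.mean()
    bc = b - bm
    sxx = float(bc @ bc)
    ym = logs.mean(axis=0)
    slope = (bc @ logs) / sxx
    intercept = ym - slope * bm
    adc = -slope
    s0 = np.exp(intercept)

    pred = intercept[None, :] + b[:, None] * slope[None, :]
    ss_res = ((logs - pred) ** 2).sum(axis=0)
    ss_tot = ((logs - ym) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)

    valid = positive & (adc >= 0)
    final_mask = mask & valid.reshape(spatial)
    n_excluded = int((mask & ~valid.reshape(spatial)).sum())
    return ADCMap(adc=adc.reshape(spatial), s0=s0.reshape(spatial),
                  fit_r2=r2.reshape(spatial), mask=final_mask,
                  n_excluded=n_excluded, scan_id=stack.scan_id, group=stack.group)


def segment_organoids(stack: DWIStack, threshold: float | None = None,
                      min_size: int = 9) -> np.ndarray:
    """Tissue mask from the highest-b image.

    Automatic bimodal (Otsu) threshold unless a manual ``threshold`` is
    given; connected components smaller than ``min_size`` voxels are
    dropped.
    """
    high_b = stack.images[-1]
    if threshold is None:
        if np.ptp(high_b) == 0:
            raise SegmentationError("uniform highest-b image: nothing to segment")
        threshold = float(_skfilters.threshold_otsu(high_b))
    mask = high_b > threshold
    if min_size > 1:
        mask = _skmorph.remove_small_objects(mask, max_size=min_size - 1)
    if not mask.any():
        raise SegmentationError("segmentation produced an empty mask")
    return mask


def adc_distribution(adc_map: ADCMap, n_bins: int = N_BINS,
                     value_range: tuple[float, float] | None = None,
                     ) -> ADCDistribution:
    """Normalized ``n_bins``-bin histogram of the masked ADC values."""
    values = adc_map.masked_values
    if values.size == 0:
        raise InvalidInputError("empty mask: no ADC values to histogram")
    if value_range is None:
        lo, hi = float(values.min()), float(values.max())
    else:
        lo, hi = value_range
    if hi <= lo:
        hi = lo + max(abs(lo), 1e-12) * 1e-9  # all-equal values: one-bin histogram
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    density = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return ADCDistribution(bin_centers=centers, density=density,
                           scan_id=adc_map.scan_id, group=adc_map.group)


def denoise_distribution(dist: ADCDistribution,
                         keep_modes: int = DEFAULT_KEEP_MODES) -> ADCDistribution:
    """Low-pass the histogram by zeroing Fourier components above
    ``keep_modes``; negative ripple is clipped at zero."""
    n = dist.density.size
    if not (1 <= keep_modes <= n // 2):
        raise InvalidParameterError(
            f"keep_modes must be in [1, {n // 2}], got {keep_modes}")
    spectrum = np.fft.rfft(dist.density)
    spectrum[keep_modes + 1:] = 0.0
    smooth = np.fft.irfft(spectrum, n=n)
    smooth = np.clip(smooth, 0.0, None)
    return replace(dist, denoised=smooth)


def maximal_likelihood_position(dist: ADCDistribution) -> float:
    """Maximal-likelihood position by the 2/3-of-peak rule.

    Finds the peak height ``I_max`` of the denoised profile, interpolates
    the nearest left and right crossings of ``(2/3) I_max`` flanking the
    peak, and returns the midpoint of the two crossing positions.
    """
    if dist.denoised is None:
        raise InvalidInputError("denoise the distribution before locating its peak")
    y = dist.denoised
    x = dist.bin_centers
    i_peak = int(np.argmax(y))
    i_max = float(y[i_peak])
    if i_max <= 0:
        raise InvalidInputError("denoised profile has no positive peak")
    level = (2.0 / 3.0) * i_max

    def crossing(direction: int) -> float:
        i = i_peak
        while 0 <= i + direction < y.size:
            j = i + direction
            if y[j] < level <= y[i]:
                # linear interpolation between bins i and j
                frac = (y[i] - level) / (y[i] - y[j])
                return float(x[i] + frac * (x[j] - x[i]))
            i = j
        raise InvalidInputError(
            "distribution truncated: no 2/3 peak crossing on "
            + ("the right" if direction > 0 else "the left"))

    left = crossing(-1)
    right = crossing(+1)
    return 0.5 * (left + right)


def scan_ml_position(adc_map: ADCMap, keep_modes: int = DEFAULT_KEEP_MODES,
                     n_bins: int = N_BINS) -> float:
    """Histogram -> denoise -> 2/3-peak location, for one scan/group."""
    dist = adc_distribution(adc_map, n_bins=n_bins)
    dist = denoise_distribution(dist, keep_modes=keep_modes)
    return maximal_likelihood_position(dist)


def group_comparison(positions: Mapping[str, Mapping[str, float]],
                     reference_group: str,
                     ) -> dict[str, dict]:
    """Per-scan relative deviations of each group from a reference group.

    ``positions[group][scan_id]`` holds the maximal-likelihood ADC position
    of a group in a scan.  For every non-reference group the deviation in
    scan s is ``(pos_g[s] - pos_ref[s]) / pos_ref[s]``; taking the ratio
    within each scan cancels longitudinal drift common to the groups.
    Reported per contrast: mean and SD of the deviations in percent, and
    the matched (paired) t test of the deviations against zero.
    """
    if reference_group not in positions:
        raise DesignError(f"reference group {reference_group!r} missing")
    ref = positions[reference_group]
    scans = sorted(ref)
    out: dict[str, dict] = {}
    for group, vals in positions.items():
        if group == reference_group:
            continue
        if sorted(vals) != scans:
            raise DesignError(
                f"group {group!r} scans do not match the reference (matched design)")
        devs = np.array([(vals[s] - ref[s]) / ref[s] for s in scans])
        test: TestResult = paired_t_test(devs)
        out[group] = {
            "deviations_pct": (devs * 100.0).tolist(),
            "mean_pct": float(devs.mean() * 100.0),
            "sd_pct": float(devs.std(ddof=1) * 100.0) if devs.size > 1 else 0.0,
            "t": test.statistic,
            "p": test.p_value,
            "n_scans": len(scans),
        }
    return out
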