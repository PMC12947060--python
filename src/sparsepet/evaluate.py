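"""Quantification suite: SSIM, masked MAE, ROI statistics (background
variability, contrast recovery), pixel-correlation samples, Fisher-Z
comparison of correlations, Mann-Whitney U.

SSIM and MAE share the implementation used by the training loss; at
evaluation time the SSIM dynamic range is the reference image's value range
per slice (the loss uses L=1 on normalised inputs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .binning import BinMask, SinogramStack
from .nn.loss import masked_mae as _masked_mae
from .nn.loss import ssim as _ssim
from .simulate import LABEL_BACKGROUND, LABEL_HOT

__all__ = [
    "RoiStats",
    "EvalReport",
    "ssim_metric",
    "mae_metric",
    "pixel_correlation_sample",
    "fisher_z_compare",
    "mann_whitney",
    "background_variability",
    "roi_metrics",
    "evaluate_stack_pair",
]


@dataclass
class RoiStats:
    """Mean, standard deviation and background variability of one ROI."""

    mean: float
    std: float

    @property
    def bv(self) -> float:
        """Background variability sigma/mu * 100 (%); undefined for mu == 0."""
        if self.mean == 0:
            raise ZeroDivisionError("BV undefined for zero-mean ROI")
        return self.std / self.mean * 100.0


@dataclass
class EvalReport:
    """Per-slice and aggregate metric records for one method vs. reference."""

    method: str
    ssim_per_slice: np.ndarray
    mae_masked_per_slice: np.ndarray
    mae_all_per_slice: np.ndarray
    correlation: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "method": self.method,
            "ssim_median": float(np.median(self.ssim_per_slice)),
            "mae_masked_median": float(np.median(self.mae_masked_per_slice)),
            "mae_all_median": float(np.median(self.mae_all_per_slice)),
            **{f"corr_{k}": v for k, v in self.correlation.items()},
        }


def ssim_metric(
    a: np.ndarray, b: np.ndarray, data_range: float | None = None,
    win_size: int = 11, sigma: float = 1.5,
) -> float | np.ndarray:
    """SSIM of a against the reference b; dynamic range defaults to the
    reference's max - min (per the whole input)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if data_range is None:
        data_range = float(b.max() - b.min())
        if data_range == 0:
            data_range = 1.0
    return _ssim(a, b, data_range=data_range, win_size=win_size, sigma=sigma)


def mae_metric(a: np.ndarray, b: np.ndarray, m: np.ndarray) -> float | np.ndarray:
    """Mean absolute error over the masked region m."""
    return _masked_mae(a, b, m)


def pixel_correlation_sample(
    reference: np.ndarray,
    method: np.ndarray,
    n_sample: int = 100_000,
    rng: np.random.Generator | None = None,
):
    """Pearson r and least-squares line on a uniform random pixel sample
    (without replacement).  Returns (r, slope, intercept, (ref_s, met_s))."""
    reference = np.asarray(reference, dtype=np.float64).ravel()
    method = np.asarray(method, dtype=np.float64).ravel()
    if reference.shape != method.shape:
        raise ValueError("shapes must match")
    rng = rng or np.random.default_rng()
    n = min(n_sample, reference.size)
    idx = rng.choice(reference.size, size=n, replace=False)
    x, y = reference[idx], method[idx]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate (constant) sample: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    slope, intercept = np.polyfit(x, y, 1)
    return r, float(slope), float(intercept), (x, y)


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher Z comparison of two independent Pearson correlations:
    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided p."""
    for r in (r1, r2):
        if not -1 < r < 1:
            raise ValueError("correlations must satisfy |r| < 1")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("sample sizes must exceed 3")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def mann_whitney(
    sample_a, sample_b, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U (exact for combined n <= 20 without ties, tie-corrected
    normal approximation otherwise)."""
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be nonempty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def background_variability(image: np.ndarray, roi: np.ndarray) -> RoiStats:
    vals = np.asarray(image, dtype=np.float64)[np.asarray(roi, dtype=bool)]
    if vals.size == 0:
        raise ValueError("empty ROI")
    return RoiStats(mean=float(vals.mean()), std=float(vals.std()))


def _random_background_roi(
    labels: np.ndarray, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Randomly placed compact background ROI of ~``size`` voxels: a ball
    grown around a random background voxel."""
    bg = np.argwhere(labels == LABEL_BACKGROUND)
    if len(bg) == 0:
        raise ValueError("no background voxels")
    centre = bg[rng.integers(len(bg))]
    d2 = ((bg - centre) ** 2).sum(axis=1)
    keep = bg[np.argsort(d2)[:size]]
    roi = np.zeros(labels.shape, dtype=bool)
    roi[tuple(keep.T)] = True
    return roi


def roi_metrics(
    original: np.ndarray,
    restored: np.ndarray,
    labels: np.ndarray,
    rng: np.random.Generator | None = None,
    background_roi_size: int | None = None,
) -> dict:
    """rBV and CR between a restored and an original image volume.

    rBV = BV(restored) / BV(original) in the hot ("bladder-like") ROI and in
    a randomly placed background ROI of similar size;
    CR = (mu_hot,res - mu_bg,res) / (mu_hot,orig - mu_bg,orig) * 100 (%).
    """
    original = np.asarray(original, dtype=np.float64)
    restored = np.asarray(restored, dtype=np.float64)
    labels = np.asarray(labels)
    if original.shape != restored.shape or original.shape != labels.shape:
        raise ValueError("images and labels must be aligned")
    rng = rng or np.random.default_rng()
    hot = labels == LABEL_HOT
    if not hot.any():
        raise ValueError("no hot ROI in labels")
    n_hot = int(hot.sum())
    bg_roi = _random_background_roi(labels, background_roi_size or n_hot, rng)

    bv_hot_orig = background_variability(original, hot)
    bv_hot_res = background_variability(restored, hot)
    bv_bg_orig = background_variability(original, bg_roi)
    bv_bg_res = background_variability(restored, bg_roi)

    contrast_orig = bv_hot_orig.mean - bv_bg_orig.mean
    contrast_res = bv_hot_res.mean - bv_bg_res.mean
    if contrast_orig == 0:
        raise ZeroDivisionError("zero original contrast: CR undefined")
    return {
        "rbv_hot": bv_hot_res.bv / bv_hot_orig.bv,
        "rbv_background": bv_bg_res.bv / bv_bg_orig.bv,
        "cr_percent": contrast_res / contrast_orig * 100.0,
    }


def evaluate_stack_pair(
    reference: SinogramStack,
    method_stack: SinogramStack,
    mask: BinMask,
    rng: np.random.Generator | None = None,
    n_sample: int = 100_000,
) -> EvalReport:
    """Per-slice SSIM and MAE (masked and all-pixel) plus a pixel-correlation
    sample for one method against the reference stack."""
    if reference.data.shape != method_stack.data.shape:
        raise ValueError("stack shapes differ")
    ref, met = reference.data, method_stack.data
    n_planes = ref.shape[0]
    ssim_s = np.empty(n_planes)
    mae_m = np.empty(n_planes)
    mae_a = np.empty(n_planes)
    aff = mask.affected
    all_m = np.ones(ref.shape[1:], dtype=bool)
    for p in range(n_planes):
        dr = float(ref[p].max() - ref[p].min()) or 1.0
        ssim_s[p] = ssim_metric(met[p], ref[p], data_range=dr)
        mae_m[p] = mae_metric(met[p], ref[p], aff[p]) if aff[p].any() else 0.0
        mae_a[p] = mae_metric(met[p], ref[p], all_m)
    rng = rng or np.random.default_rng()
    r, slope, intercept, _ = pixel_correlation_sample(ref, met, n_sample, rng)
    return EvalReport(
        method=method_stack.provenance,
        ssim_per_slice=ssim_s,
        mae_masked_per_slice=mae_m,
        mae_all_per_slice=mae_a,
        correlation={"r": r, "slope": slope, "intercept": intercept, "n": min(n_sample, ref.size)},
    )
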