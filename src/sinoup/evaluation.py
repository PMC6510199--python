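"""Quality metrics, filtered back projection, and the benchmark harness.

PSNR is ``10·log₁₀(peak²/MSE)`` with a configurable peak (defaulting to the
ground truth's data range).  SSIM uses Gaussian-weighted 11×11 windows with
the standard constants K₁=0.01, K₂=0.03.  Reconstruction uses plain
parallel-beam filtered back projection (Ram-Lak filter, linear-interpolation
backprojection) with the region outside the inscribed circle set to a NaN
sentinel; masked metrics exclude sentinel pixels.

The benchmark harness reproduces the structure of a sparse-view upscaling
study: held-out sinograms are angularly downsampled, re-upscaled by each
method, and scored on the predicted intermediate rows against noiseless
ground truth (sinogram space) and on their FBP reconstructions against the
fully sampled reconstruction (reconstruction space).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity
from skimage.transform import iradon

from . import sampling
from .io import SinogramStack


@dataclass
class QualityReport:
    """PSNR/SSIM of one comparison, with enough context to tabulate it."""

    method: str
    space: str  # "sinogram" | "reconstruction"
    psnr_db: float
    ssim: float | None
    n_projections: int | None = None
    crop: tuple | None = None

    def __post_init__(self) -> None:
        if self.ssim is not None and not -1.0 <= self.ssim <= 1.0 + 1e-9:
            raise ValueError(f"SSIM {self.ssim} outside [-1, 1]")


def psnr(a: np.ndarray, b: np.ndarray, peak: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` for identical images.

    NaN sentinel pixels (in either image) are excluded from the mean.
    ``peak`` defaults to the data range of ``b`` (the ground truth).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    mask = np.isfinite(a) & np.isfinite(b)
    if not mask.any():
        raise ValueError("no finite pixels to compare")
    if peak is None:
        bv = b[mask]
        peak = float(bv.max() - bv.min()) or 1.0
    mse = float(np.mean((a[mask] - b[mask]) ** 2))
    if mse == 0.0:
        return np.inf
    return float(10.0 * np.log10(peak ** 2 / mse))


def ssim(a: np.ndarray, b: np.ndarray, peak: float | None = None,
         K1: float = 0.01, K2: float = 0.03, win_size: int = 11,
         sigma: float = 1.5) -> float:
    """Mean structural similarity with Gaussian-weighted windows.

    Follows the reference formulation: 11×11 Gaussian windows (σ=1.5),
    population (not sample) covariances, C₁=(K₁·peak)², C₂=(K₂·peak)².
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if min(a.shape) < win_size:
        raise ValueError(f"image smaller than the {win_size}×{win_size} window")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("ssim requires sentinel-free images; crop the mask first")
    if peak is None:
        peak = float(b.max() - b.min()) or 1.0
    return float(structural_similarity(
        a, b, data_range=peak, gaussian_weights=True, sigma=sigma,
        win_size=win_size, use_sample_covariance=False, K1=K1, K2=K2))


def fbp_reconstruct(s: np.ndarray, angles: np.ndarray,
                    sentinel: float = np.nan,
                    pixel_size: float = 1.0) -> np.ndarray:
    """Filtered back projection of one ``(θ, W)`` sinogram → ``(W, W)`` image.

    Ram-Lak (ramp) filtered, linear-interpolation backprojection over the
    given angles (degrees).  Pixels outside the inscribed circular field of
    view are set to ``sentinel`` so downstream metrics can exclude them.
    ``pixel_size`` converts the output to attenuation per scene unit (leave
    at 1 when only comparing reconstructions with each other); pass the
    detector pixel pitch to compare against an analytic density map.
    """
    s = np.asarray(s, dtype=np.float64)
    angles = np.asarray(angles, dtype=np.float64)
    if s.ndim != 2:
        raise ValueError("expected a 2-D sinogram")
    if angles.shape != (s.shape[0],):
        raise ValueError(f"{angles.size} angles for {s.shape[0]} sinogram rows")
    W = s.shape[1]
    img = iradon(s.T, theta=angles, filter_name="ramp",
                 interpolation="linear", circle=True, output_size=W)
    # transpose into the scene convention (row = y, column = x) used by the
    # analytic projector and the rasterized density maps
    img = np.ascontiguousarray(img.T) / pixel_size
    yy, xx = np.mgrid[:W, :W]
    r = (W - 1) / 2.0
    outside = (xx - r) ** 2 + (yy - r) ** 2 > (W / 2.0) ** 2
    img[outside] = sentinel
    return img


def masked_quality(recon_a: np.ndarray, recon_b: np.ndarray,
                   crop: tuple[slice, slice] | None = None,
                   peak: float | None = None, method: str = "",
                   n_projections: int | None = None) -> QualityReport:
    """PSNR/SSIM of two reconstructions on a crop, excluding sentinels.

    PSNR averages over the finite pixels of the crop; SSIM is computed when
    the crop is sentinel-free and reported as ``None`` otherwise.
    """
    a = np.asarray(recon_a, dtype=np.float64)
    b = np.asarray(recon_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if crop is not None:
        a = a[crop]
        b = b[crop]
        if a.size == 0:
            raise ValueError("crop selects no pixels")
    p = psnr(a, b, peak=peak)
    s_val = None
    if np.isfinite(a).all() and np.isfinite(b).all():
        s_val = ssim(a, b, peak=peak)
    crop_desc = None
    if crop is not None:
        crop_desc = tuple((c.start, c.stop) for c in crop)
    return QualityReport(method=method, space="reconstruction", psnr_db=p,
                         ssim=s_val, n_projections=n_projections, crop=crop_desc)


def intermediate_row_indices(n_rows_full: int, down_factor: int,
                             up_factor: int) -> np.ndarray:
    """Full-resolution row indices scored after down/up-scaling.

    These are the rows the upscaler must predict: positions on the upscaled
    grid (spacing ``down_factor/up_factor`` of the full grid) that are *not*
    original undersampled rows.  For 3601 rows, factor-40 downsampling and
    2× upscaling these are rows 20, 60, …, 3580.
    """
    if down_factor % up_factor != 0:
        raise ValueError("down_factor must be divisible by up_factor")
    step = down_factor // up_factor
    idx = np.arange(0, n_rows_full, step)
    return idx[(idx % down_factor) != 0]


def upscaled_row_positions(L: int, up_factor: int) -> np.ndarray:
    """Indices of predicted (non-copied) rows within an upscaled sinogram."""
    idx = np.arange(up_factor * (L - 1) + 1)
    return idx[(idx % up_factor) != 0]


def score_sinogram_upscaling(upscaled: np.ndarray, clean_full: np.ndarray,
                             down_factor: int, up_factor: int,
                             peak: float | None = None,
                             method: str = "") -> QualityReport:
    """Score predicted intermediate rows of one sinogram against ground truth.

    Only the predicted rows enter the metric — the rows copied verbatim
    from the undersampled input are excluded so the score reflects the
    upscaler, not the input.
    """
    gt_rows = clean_full[intermediate_row_indices(clean_full.shape[0],
                                                  down_factor, up_factor)]
    L = (clean_full.shape[0] - 1) // down_factor + 1
    pred_rows = upscaled[upscaled_row_positions(L, up_factor)]
    if pred_rows.shape != gt_rows.shape:
        raise ValueError(f"predicted rows {pred_rows.shape} vs ground truth "
                         f"{gt_rows.shape}")
    if peak is None:
        peak = float(gt_rows.max() - gt_rows.min()) or 1.0
    return QualityReport(method=method, space="sinogram",
                         psnr_db=psnr(pred_rows, gt_rows, peak=peak),
                         ssim=ssim(pred_rows, gt_rows, peak=peak),
                         n_projections=up_factor * (L - 1) + 1)


def central_crop(width: int, fraction: float = 0.5) -> tuple[slice, slice]:
    """Axis-aligned central crop window used for masked reconstruction metrics."""
    margin = int(round(width * (1.0 - fraction) / 2.0))
    return (slice(margin, width - margin), slice(margin, width - margin))


def run_benchmark(clean: SinogramStack, noisy: SinogramStack,
                  methods: dict, factors=(2,), down_factor: int = 40,
                  heights=None, spaces=("sinogram", "reconstruction"),
                  crop: tuple[slice, slice] | None = None,
                  peak: float | None = None) -> pd.DataFrame:
    """Down/up-scale held-out sinograms with each method and tabulate scores.

    ``methods`` maps a label to ``callable(undersampled_2d, factor) ->
    upscaled_2d``.  Every ``heights`` sinogram (default: every 10th) of the
    noisy stack is downsampled by ``down_factor``, upscaled by each method
    and factor, and scored in sinogram space against the noiseless stack
    and (optionally) in reconstruction space against the FBP of the fully
    sampled noiseless sinogram.  Returns one row per
    (method, factor, space, height).
    """
    if heights is None:
        heights = range(0, clean.n_heights, 10)
    T = clean.n_angles
    if crop is None:
        crop = central_crop(clean.data.shape[2])
    rows = []
    for h in heights:
        g_clean = np.asarray(clean.data[h], dtype=np.float64)
        g_noisy = np.asarray(noisy.data[h], dtype=np.float64)
        under = sampling.downsample_sinogram(g_noisy, down_factor)
        recon_gt = None
        if "reconstruction" in spaces:
            recon_gt = fbp_reconstruct(g_clean, clean.angles)
        for factor in factors:
            for name, fn in methods.items():
                up = np.asarray(fn(under, factor), dtype=np.float64)
                if "sinogram" in spaces:
                    rep = score_sinogram_upscaling(up, g_clean, down_factor,
                                                   factor, peak=peak, method=name)
                    rows.append({"method": name, "factor": factor,
                                 "space": "sinogram", "height_index": h,
                                 "psnr_db": rep.psnr_db, "ssim": rep.ssim})
                if "reconstruction" in spaces:
                    angles_up = np.linspace(0.0, 180.0, up.shape[0])
                    recon = fbp_reconstruct(up, angles_up)
                    rep = masked_quality(recon, recon_gt, crop=crop, peak=peak,
                                         method=name,
                                         n_projections=up.shape[0])
                    rows.append({"method": name, "factor": factor,
                                 "space": "reconstruction", "height_index": h,
                                 "psnr_db": rep.psnr_db, "ssim": rep.ssim})
    return pd.DataFrame(rows, columns=["method", "factor", "space",
                                       "height_index", "psnr_db", "ssim"])


def oracle_method(clean_full: np.ndarray, down_factor: int):
    """Benchmark comparator that copies ground-truth rows (infinite PSNR)."""

    def fn(under: np.ndarray, factor: int) -> np.ndarray:
        step = down_factor // factor
        return np.asarray(clean_full)[::step].copy()

    return fn
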