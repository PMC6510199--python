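"""End-to-end desk-scale study: simulate → train → upscale → evaluate.

This module fixes the reference study conditions used by the command-line
``demo``, the test suite and the acceptance script, so they all exercise the
same seeded pipeline.  The conditions preserve the structure of a
synchrotron corrosion experiment at sizes a single CPU can train in
minutes: a 64-height × 721-angle × 256-pixel phantom tomogram (against
1080 × 3601 × 1280 at beamline scale), undersampled 8:1 to 91 projections
(mirroring the 40:1 ratio that maps 3601 rows to 91), Poisson noise at
incident flux 10⁴ counts, and the doubled-feature architecture with its
feature counts scaled down 8× to (16, 8).

Two phantoms are generated from disjoint seeds: the training/validation
scene carries 3 gas bubbles and the held-out testing scene 4, matching the
train/test scene distinction of the emulated experiment.  Training and
validation sinograms alternate along the height axis; every 10th height of
the testing tomogram is benchmarked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import baselines, evaluation, model, phantom, training
from .io import SinogramStack
from .model import UDNNConfig, UDNNParams
from .phantom import NoiseModel, PhantomConfig, ProjectionGeometry


@dataclass(frozen=True)
class StudyConfig:
    """Desk-scale study conditions (see module docstring for rationale)."""

    n_heights: int = 64
    n_angles: int = 721
    width: int = 256
    extent: float = 1.0
    height_center: float = 0.15     # slices cut the pin top, droplet and bubbles
    flux: float = 1.0e4
    down_factor: int = 8            # 721 rows -> 91, the undersampled regime
    gap: int = 8                    # training-patch spacing == down_factor
    feature_scale: int = 4          # udnn128 (128, 64) -> (32, 16)
    train_bubbles: int = 3
    test_bubbles: int = 4
    test_height_stride: int = 10
    # starting rates one decade below the full-scale recipe: desk-scale
    # minibatches cover ~100× fewer pixels, so their gradients are too noisy
    # for the full-scale rates to descend stably
    lr_first_two: float = 1.0e-3
    lr_last: float = 1.0e-4
    max_iterations_2x: int = 256
    max_iterations_4x: int = 224

    @property
    def geometry(self) -> ProjectionGeometry:
        return ProjectionGeometry(n_angles=self.n_angles,
                                  detector_width=self.width,
                                  n_heights=self.n_heights,
                                  pixel_size=2.0 * self.extent / self.width,
                                  height_center=self.height_center)

    def network(self, n_out: int = 1) -> UDNNConfig:
        base = model.default_configs(n_out=n_out)["udnn128"]
        return model.scaled_config(base, self.feature_scale)


@dataclass
class PhantomPair:
    """Training/validation tomogram and held-out testing tomogram."""

    train_clean: SinogramStack
    train_noisy: SinogramStack
    test_clean: SinogramStack
    test_noisy: SinogramStack


def make_phantom_pair(seed: int, cfg: StudyConfig | None = None) -> PhantomPair:
    """Simulate both tomograms from a single master seed."""
    cfg = cfg or StudyConfig()
    ss = np.random.SeedSequence(seed)
    s_train, s_test, n_train, n_test = (int(c.generate_state(1)[0] % (2 ** 31))
                                        for c in ss.spawn(4))
    geom = cfg.geometry
    scene_train = phantom.build_corrosion_phantom(
        PhantomConfig(n_bubbles=cfg.train_bubbles, extent=cfg.extent), seed=s_train)
    scene_test = phantom.build_corrosion_phantom(
        PhantomConfig(n_bubbles=cfg.test_bubbles, extent=cfg.extent), seed=s_test)
    train_clean = phantom.project_scene(scene_train, geom)
    test_clean = phantom.project_scene(scene_test, geom)
    train_noisy = phantom.apply_poisson_noise(train_clean, NoiseModel(cfg.flux, n_train))
    test_noisy = phantom.apply_poisson_noise(test_clean, NoiseModel(cfg.flux, n_test))
    return PhantomPair(train_clean, train_noisy, test_clean, test_noisy)


def split_heights(n_heights: int) -> tuple[np.ndarray, np.ndarray]:
    """Alternating train/validation height split (even → train, odd → val).

    Alternating heights keeps both halves representative of the whole
    sample, whose structure changes along the height axis.
    """
    idx = np.arange(n_heights)
    return idx[::2], idx[1::2]


def train_study_model(noisy: SinogramStack, cfg: StudyConfig, n_out: int,
                      seed: int, max_iterations: int | None = None,
                      callback=None) -> tuple[UDNNParams, UDNNConfig, training.TrainHistory]:
    """Train the scaled network on alternating heights of a noisy tomogram."""
    train_idx, val_idx = split_heights(noisy.n_heights)
    train_sinos = [np.asarray(noisy.data[i], dtype=np.float32) for i in train_idx]
    val_sinos = [np.asarray(noisy.data[i], dtype=np.float32) for i in val_idx]
    config = cfg.network(n_out=n_out)
    if max_iterations is None:
        max_iterations = (cfg.max_iterations_2x if n_out == 1
                          else cfg.max_iterations_4x)
    schedule = training.TrainSchedule(lr_first_two=cfg.lr_first_two,
                                      lr_last=cfg.lr_last,
                                      max_iterations=max_iterations, seed=seed)
    params, history = training.train(train_sinos, val_sinos, config, schedule,
                                     gap=cfg.gap, callback=callback)
    return params, config, history


@dataclass
class StudyResult:
    config: StudyConfig
    benchmark: pd.DataFrame
    trend: pd.DataFrame
    histories: dict[int, training.TrainHistory] = field(default_factory=dict)

    def mean_psnr(self, method: str, factor: int, space: str = "sinogram") -> float:
        df = self.benchmark
        sel = df[(df.method == method) & (df.factor == factor) & (df.space == space)]
        return float(sel.psnr_db.mean())


def reconstruction_trend(pair: PhantomPair, cfg: StudyConfig,
                         models: dict[int, tuple[UDNNParams, UDNNConfig]],
                         heights=None,
                         crop: tuple[slice, slice] | None = None) -> pd.DataFrame:
    """Reconstruction quality as the projection count grows.

    For each held-out height, reconstructs (a) the raw undersampled noisy
    sinogram and (b) its network upscalings, and scores them against the
    reconstruction of the fully sampled noiseless sinogram.  Returns one
    row per (n_projections, height).
    """
    if heights is None:
        heights = range(0, pair.test_clean.n_heights, cfg.test_height_stride)
    if crop is None:
        crop = evaluation.central_crop(cfg.width)
    rows = []
    for h in heights:
        g_clean = np.asarray(pair.test_clean.data[h], dtype=np.float64)
        g_noisy = np.asarray(pair.test_noisy.data[h], dtype=np.float64)
        under = g_noisy[::cfg.down_factor]
        recon_gt = evaluation.fbp_reconstruct(g_clean, pair.test_clean.angles)
        candidates: list[tuple[int, np.ndarray]] = [(under.shape[0], under)]
        for factor in sorted(models):
            params, config = models[factor]
            up = model.upscale_sinogram(params, config, under)
            candidates.append((up.shape[0], up))
        for n_proj, sino in candidates:
            angles = np.linspace(0.0, 180.0, n_proj)
            recon = evaluation.fbp_reconstruct(sino, angles)
            rep = evaluation.masked_quality(recon, recon_gt, crop=crop,
                                            n_projections=n_proj)
            rows.append({"n_projections": n_proj, "height_index": h,
                         "psnr_db": rep.psnr_db, "ssim": rep.ssim})
    return pd.DataFrame(rows, columns=["n_projections", "height_index",
                                       "psnr_db", "ssim"])


def quick_config() -> StudyConfig:
    """A sub-minute variant of the study for smoke and determinism checks.

    Exercises every pipeline stage at token sizes; its scores say nothing
    about method quality (the angular sampling is nearly complete and the
    networks barely train)."""
    return StudyConfig(n_heights=8, n_angles=121, width=64, down_factor=4,
                       gap=4, max_iterations_2x=24, max_iterations_4x=24,
                       test_height_stride=4)


def run_study(seed: int, cfg: StudyConfig | None = None, factors=(2, 4),
              pair: PhantomPair | None = None, callback=None) -> StudyResult:
    """The full seeded pipeline; returns benchmark and trend tables."""
    cfg = cfg or StudyConfig()
    ss = np.random.SeedSequence([seed, 2106])
    train_seeds = {f: int(c.generate_state(1)[0] % (2 ** 31))
                   for f, c in zip(factors, ss.spawn(len(factors)))}
    if pair is None:
        pair = make_phantom_pair(seed, cfg)
    models: dict[int, tuple[UDNNParams, UDNNConfig]] = {}
    histories: dict[int, training.TrainHistory] = {}
    for f in factors:
        params, config, hist = train_study_model(pair.train_noisy, cfg,
                                                 n_out=f - 1,
                                                 seed=train_seeds[f],
                                                 callback=callback)
        models[f] = (params, config)
        histories[f] = hist
    methods = {
        "udnn": lambda u, fac: model.upscale_sinogram(*models[fac], u),
        "cubic": lambda u, fac: baselines.cubic_upscale(u, fac),
    }
    heights = range(0, pair.test_clean.n_heights, cfg.test_height_stride)
    benchmark = evaluation.run_benchmark(pair.test_clean, pair.test_noisy,
                                         methods, factors=factors,
                                         down_factor=cfg.down_factor,
                                         heights=heights)
    trend = reconstruction_trend(pair, cfg, models, heights=heights)
    return StudyResult(cfg, benchmark, trend, histories)
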