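"""Patch geometry: angular downsampling, training pairs, tiling, merging,
interlacing and per-patch normalization.

The data construction mimics acquisition at two angular rates.  A fully
sampled sinogram ``G`` (e.g. 3601 rows) is scanned with sliding windows of
height ``gap·(m−1)+1`` (401 for the defaults ``gap=40, m=11``); the ``m``
rows at multiples of ``gap`` inside a window are the network input, and the
rows at the sub-grid positions between them are the ground-truth
intermediate rows, one output channel per sub-position.  The gap between
consecutive input rows therefore equals the row spacing of a sinogram
downsampled by ``gap``, so training pairs match the angular spacing seen at
inference exactly.

At inference an undersampled sinogram is tiled into overlapping 11-row
windows (stride 1); per-window predictions are merged by per-pixel
averaging over every window that covers a gap, and finally the predicted
intermediate rows are interlaced with the input rows to form the upscaled
sinogram.

All indexing is 0-based and half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def downsample_sinogram(s: np.ndarray, factor: int) -> np.ndarray:
    """Keep rows ``0, factor, 2·factor, …`` — ``⌊(T−1)/factor⌋ + 1`` rows.

    A 3601-row sinogram downsampled by 40 keeps 91 rows, emulating the
    undersampled acquisition.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"downsampling factor must be a positive integer, got {factor}")
    s = np.asarray(s)
    if s.shape[0] < 1:
        raise ValueError("sinogram must have at least one row")
    return s[:: int(factor)].copy()


def input_offsets(gap: int = 40, n_inputs: int = 11) -> np.ndarray:
    """Row offsets of the network input within a window: 0, gap, …, gap·(m−1)."""
    return np.arange(n_inputs) * gap


def target_offsets(n_out: int, gap: int = 40, n_inputs: int = 11) -> np.ndarray:
    """Per-channel ground-truth row offsets, shape ``(n_out, n_inputs−1)``.

    With ``gap=40``: one channel targets offsets 20, 60, …, 380; three
    channels target 10/50/…, 20/60/… and 30/70/… respectively.
    """
    if n_out < 1:
        raise ValueError("n_out must be at least 1")
    if gap % (n_out + 1) != 0:
        raise ValueError(f"gap {gap} must be divisible by the upscaling factor {n_out + 1}")
    step = gap // (n_out + 1)
    base = np.arange(n_inputs - 1) * gap
    return np.stack([base + (c + 1) * step for c in range(n_out)])


def window_height(gap: int = 40, n_inputs: int = 11) -> int:
    return gap * (n_inputs - 1) + 1


def training_patch_starts(n_rows: int, gap: int = 40, n_inputs: int = 11,
                          stride: int = 1) -> np.ndarray:
    """Window start rows for training patches: ``0 … T−(win+1)`` by ``stride``.

    The count for stride 1 is ``T − win`` (3200 for T=3601, win=401): the
    final fitting window — whose start row is the 180° duplicate of row 0 —
    is deliberately never used as a start.
    """
    win = window_height(gap, n_inputs)
    if n_rows < win + 1:
        raise ValueError(
            f"sinogram has {n_rows} rows; at least {win + 1} required for "
            f"gap={gap}, n_inputs={n_inputs}")
    return np.arange(0, n_rows - win, stride)


@dataclass
class TrainingPatchPair:
    """An input patch and its ground-truth intermediate rows.

    ``input`` has ``n_inputs`` rows; ``target`` is ``(n_out, n_inputs−1, W)``
    — channel ``c`` holds the rows at the ``c``-th sub-grid position of each
    inter-input gap.
    """

    input: np.ndarray
    target: np.ndarray
    start: int
    source_height: int | None = None

    def __post_init__(self) -> None:
        if self.input.ndim != 2 or self.target.ndim != 3:
            raise ValueError("input must be 2-D and target 3-D")
        if self.target.shape[1] != self.input.shape[0] - 1:
            raise ValueError("target must have one row per inter-input gap")
        if self.target.shape[2] != self.input.shape[1]:
            raise ValueError("input and target widths differ")


def patch_at(G: np.ndarray, start: int, n_out: int, gap: int = 40,
             n_inputs: int = 11, source_height: int | None = None) -> TrainingPatchPair:
    """Extract the training pair whose window begins at row ``start``."""
    G = np.asarray(G)
    return TrainingPatchPair(
        input=G[start + input_offsets(gap, n_inputs)],
        target=G[start + target_offsets(n_out, gap, n_inputs)],
        start=int(start),
        source_height=source_height,
    )


def extract_training_patches(G: np.ndarray, n_out: int, gap: int = 40,
                             n_inputs: int = 11, stride: int = 1,
                             source_height: int | None = None) -> list[TrainingPatchPair]:
    """All training pairs of a fully sampled sinogram (stride-1 default)."""
    G = np.asarray(G)
    if G.ndim != 2:
        raise ValueError("expected a single 2-D sinogram")
    starts = training_patch_starts(G.shape[0], gap, n_inputs, stride)
    return [patch_at(G, s, n_out, gap, n_inputs, source_height) for s in starts]


def tile_inference_patches(u: np.ndarray, n_inputs: int = 11) -> tuple[np.ndarray, np.ndarray]:
    """Overlapping ``n_inputs``-row windows of an undersampled sinogram.

    Returns ``(windows, starts)`` with starts ``0 … L−n_inputs`` (count
    ``L−n_inputs+1``); consecutive windows overlap by ``n_inputs−1`` rows.
    """
    u = np.asarray(u)
    if u.ndim != 2:
        raise ValueError("expected a 2-D sinogram")
    L = u.shape[0]
    if L < n_inputs:
        raise ValueError(f"sinogram has {L} rows; at least {n_inputs} required")
    starts = np.arange(L - n_inputs + 1)
    windows = np.stack([u[s:s + n_inputs] for s in starts])
    return windows, starts


def merge_patch_predictions(preds: np.ndarray, starts: np.ndarray, L: int) -> np.ndarray:
    """Overlap-average per-window predictions into the intermediate rows.

    ``preds`` is ``(n_windows, n_out, n_inputs−1, W)`` aligned with
    ``starts``.  The window starting at ``s`` predicts gaps ``s … s+m−2``;
    each gap/channel/pixel slot receives the mean over all windows covering
    it (edge gaps average over fewer windows).  Returns
    ``(n_out, L−1, W)``.
    """
    preds = np.asarray(preds)
    starts = np.asarray(starts)
    if preds.ndim != 4:
        raise ValueError("predictions must be (n_windows, n_out, rows, width)")
    if preds.shape[0] != starts.shape[0]:
        raise ValueError("one start per prediction window is required")
    n_out, m_gaps, W = preds.shape[1:]
    sums = np.zeros((n_out, L - 1, W), dtype=np.float64)
    counts = np.zeros(L - 1, dtype=np.int64)
    for p, s in zip(preds, starts):
        sums[:, s:s + m_gaps] += p
        counts[s:s + m_gaps] += 1
    if (counts == 0).any():
        missing = np.flatnonzero(counts == 0)
        raise ValueError(f"gaps {missing.tolist()} are covered by no window; "
                         "starts are incomplete")
    return (sums / counts[None, :, None]).astype(preds.dtype)


def interlace(inp: np.ndarray, intermediate: np.ndarray,
              n_out: int | None = None) -> np.ndarray:
    """Weave predicted intermediate rows between the input rows.

    ``inp`` is ``(L, W)``; ``intermediate`` is ``(n_out, L−1, W)``.  The
    output has ``(n_out+1)·(L−1)+1`` rows: input rows sit verbatim at
    indices divisible by ``n_out+1`` and the rows between inputs ``i`` and
    ``i+1`` are that gap's channels in order.  A 91-row input becomes 181
    rows for 2× upscaling and 361 rows for 4×.
    """
    inp = np.asarray(inp)
    intermediate = np.asarray(intermediate)
    if intermediate.ndim != 3:
        raise ValueError("intermediate rows must be (n_out, L-1, W)")
    if n_out is None:
        n_out = intermediate.shape[0]
    L, W = inp.shape
    if intermediate.shape != (n_out, L - 1, W):
        raise ValueError(
            f"intermediate shape {intermediate.shape} inconsistent with "
            f"input {inp.shape} and n_out={n_out}")
    f = n_out + 1
    out = np.empty((f * (L - 1) + 1, W), dtype=np.result_type(inp, intermediate))
    out[::f] = inp
    for c in range(n_out):
        out[c + 1::f] = intermediate[c]
    return out


@dataclass(frozen=True)
class NormalizationParams:
    """Invertible per-patch affine map ``x ↦ (x − offset)/scale``.

    Constant patches are flagged degenerate: they normalize to zeros and
    the inverse restores the constant.
    """

    offset: float
    scale: float
    degenerate: bool = False


_DEGENERATE_EPS = 1.0e-12


def normalize_patch(x: np.ndarray) -> tuple[np.ndarray, NormalizationParams]:
    """Min–max map of a patch onto [0, 1] plus the parameters to invert it."""
    x = np.asarray(x)
    if not np.isfinite(x).all():
        raise ValueError("patch contains non-finite values")
    lo = float(x.min())
    hi = float(x.max())
    scale = hi - lo
    if scale <= _DEGENERATE_EPS:
        return np.zeros_like(x), NormalizationParams(lo, 1.0, degenerate=True)
    return (x - lo) / scale, NormalizationParams(lo, scale)


def denormalize(y: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Invert :func:`normalize_patch` on a network output."""
    return np.asarray(y) * params.scale + params.offset


def iter_training_iterations(sinograms: list[np.ndarray], rng: np.random.Generator,
                             n_out: int, gap: int = 40, n_inputs: int = 11,
                             minibatch: int = 10):
    """Endless stream of training minibatches with balanced sinogram usage.

    One *iteration* draws exactly one random patch from every training
    sinogram, visiting them in a freshly shuffled order, so no sinogram is
    revisited before all others have been.  Patches are grouped into
    minibatches of ``minibatch`` (the final partial batch of an iteration is
    kept).  Yields ``(iteration_index, inputs, targets)`` with ``inputs``
    ``(b, n_inputs, W)`` and ``targets`` ``(b, n_out, n_inputs−1, W)``.
    """
    if not sinograms:
        raise ValueError("at least one training sinogram is required")
    starts = [training_patch_starts(s.shape[0], gap, n_inputs) for s in sinograms]
    iteration = 0
    while True:
        order = rng.permutation(len(sinograms))
        pairs = [patch_at(sinograms[i], rng.choice(starts[i]), n_out, gap,
                          n_inputs, source_height=int(i)) for i in order]
        for b0 in range(0, len(pairs), minibatch):
            chunk = pairs[b0:b0 + minibatch]
            yield (iteration,
                   np.stack([p.input for p in chunk]),
                   np.stack([p.target for p in chunk]))
        iteration += 1
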