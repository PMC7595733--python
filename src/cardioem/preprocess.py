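"""Stack preprocessing: slice alignment, per-slice denoising, intensity matching.

Serial block-face stacks drift laterally between sections; alignment is
translation-only, pairwise-chained (each slice registered to its predecessor
by cross-correlation, then chained to the frame of slice 0).  Denoising is
non-local means applied strictly per 2D slice.  Cross-sample brightness
differences are removed by an affine grayscale map matching mean and SD to a
reference volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from skimage.restoration import denoise_nl_means

from .volumes import LabelVolume, VoxelVolume


@dataclass
class SliceShiftTable:
    """Per-slice (di, dj) translations, in voxels, relative to slice 0.

    ``shifts[k]`` is the translation APPLIED to raw slice k to bring it into
    the reference frame; ``score[k]`` is the normalized cross-correlation of
    slice k with slice k−1 after alignment (NaN for the reference slice and
    for constant slices where correlation is undefined).
    """

    shifts: np.ndarray   # (n_slices, 2) float
    scores: np.ndarray   # (n_slices,) float

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.shifts.shape[0] != self.scores.shape[0]:
            raise ValueError("one score per slice required")
        if not np.allclose(self.shifts[0], 0.0):
            raise ValueError("reference slice shift must be (0, 0)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "slice": np.arange(self.shifts.shape[0]),
            "di": self.shifts[:, 0],
            "dj": self.shifts[:, 1],
            "score": self.scores,
        })


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(float).ravel()
    b = b.astype(float).ravel()
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return float("nan")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def _translate_slice(img: np.ndarray, shift: tuple[float, float],
                     wrap: bool) -> np.ndarray:
    if wrap and float(shift[0]).is_integer() and float(shift[1]).is_integer():
        return np.roll(img, (int(shift[0]), int(shift[1])), axis=(0, 1))
    mode = "grid-wrap" if wrap else "constant"
    out = ndimage.shift(img.astype(float), shift, order=1, mode=mode,
                        cval=float(img.mean()))
    if np.issubdtype(img.dtype, np.integer):
        info = np.iinfo(img.dtype)
        out = np.clip(np.rint(out), info.min, info.max)
    return out.astype(img.dtype)


def align_stack(volume: VoxelVolume, upsample_factor: int = 10,
                wrap: bool = True) -> tuple[VoxelVolume, SliceShiftTable]:
    """Register every slice to its predecessor and chain to a global frame.

    Each pairwise shift is the cross-correlation peak (subvoxel via Fourier
    upsampling); cumulative shifts place all slices in the frame of slice 0.
    Constant slices have undefined correlation: they receive shift (0, 0)
    relative to their predecessor and a NaN score flag.

    Returns the aligned volume and the :class:`SliceShiftTable`; applying the
    reported shifts to the raw stack reproduces the aligned stack.
    """
    data = volume.data
    n = data.shape[2]
    if n < 2:
        raise ValueError("alignment requires at least 2 slices")
    pair = np.zeros((n, 2))
    scores = np.full(n, np.nan)
    for k in range(1, n):
        ref, mov = data[:, :, k - 1], data[:, :, k]
        if ref.std() == 0 or mov.std() == 0:
            pair[k] = 0.0
            continue
        shift, _, _ = phase_cross_correlation(
            ref.astype(float), mov.astype(float),
            upsample_factor=upsample_factor, normalization=None)
        pair[k] = shift
    cumulative = np.cumsum(pair, axis=0)
    aligned = np.empty_like(data)
    aligned[:, :, 0] = data[:, :, 0]
    for k in range(1, n):
        aligned[:, :, k] = _translate_slice(data[:, :, k], tuple(cumulative[k]), wrap)
        scores[k] = _ncc(aligned[:, :, k - 1], aligned[:, :, k])
    return (VoxelVolume(aligned, volume.geometry),
            SliceShiftTable(cumulative, scores))


def apply_shifts(volume: VoxelVolume, table: SliceShiftTable,
                 wrap: bool = True) -> VoxelVolume:
    """Apply a shift table to a raw stack (reproduces ``align_stack`` output)."""
    data = volume.data
    out = np.empty_like(data)
    for k in range(data.shape[2]):
        out[:, :, k] = _translate_slice(data[:, :, k], tuple(table.shifts[k]), wrap)
    return VoxelVolume(out, volume.geometry)


def denoise_slices(volume: VoxelVolume, patch_size: int = 5,
                   search_window: int = 13, strength: float = 0.1) -> VoxelVolume:
    """Non-local means denoising applied independently to every 2D slice.

    ``strength`` is the NLM filtering parameter h relative to the slice's
    value range; 0 is the identity.  No cross-slice mixing occurs.
    """
    if strength < 0:
        raise ValueError("strength must be >= 0")
    data = volume.data
    if patch_size > min(data.shape[0], data.shape[1]):
        raise ValueError("patch size exceeds slice dimensions")
    if strength == 0:
        return volume.copy()
    out = np.empty(data.shape, dtype=float)
    for k in range(data.shape[2]):
        sl = data[:, :, k].astype(float)
        rng_val = sl.max() - sl.min()
        if rng_val == 0:
            out[:, :, k] = sl
            continue
        sigma = float(np.sqrt(max(0.0, _noise_variance(sl))))
        out[:, :, k] = denoise_nl_means(
            sl, patch_size=patch_size, patch_distance=search_window // 2,
            h=strength * rng_val, sigma=sigma, fast_mode=True,
            preserve_range=True)
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        out = np.clip(np.rint(out), info.min, info.max).astype(data.dtype)
    return VoxelVolume(out, volume.geometry)


def _noise_variance(img: np.ndarray) -> float:
    """Crude white-noise variance estimate from the half-pixel difference."""
    d = np.diff(img, axis=1)
    return float(np.var(d) / 2.0)


def match_intensity(volume: VoxelVolume, reference: VoxelVolume) -> VoxelVolume:
    """Affine grayscale map a·I + b so output mean/SD equal the reference's.

    Rejects label volumes (brightness matching is meaningless for class ids)
    and zero-variance inputs when the reference has spread.
    """
    if isinstance(volume, LabelVolume) or isinstance(reference, LabelVolume):
        raise TypeError("match_intensity operates on grayscale volumes, not labels")
    if reference.data.size == 0:
        raise ValueError("reference volume is empty")
    data = volume.data.astype(float)
    m_in, s_in = data.mean(), data.std()
    m_ref, s_ref = float(reference.data.mean()), float(reference.data.std())
    if s_in == 0 and s_ref > 0:
        raise ValueError("cannot match a zero-variance volume to a varying reference")
    a = 1.0 if s_in == 0 else s_ref / s_in
    b = m_ref - a * m_in
    return VoxelVolume(a * data + b, volume.geometry)
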