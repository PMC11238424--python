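"""Static structure factor of the image intensity.

S(q) = ⟨|FT[I(r, t)]|²⟩_t, computed per frame on the mean-subtracted image
(otherwise the q = 0 peak dominates everything), averaged over frames, and
angularly averaged over annular bins of one frequency step. Wavenumbers are
physical: q = 2π k / (N · pixel_size) in 1/μm. The 2D map is normalized by
the pixel count so Parseval's identity reads Σ S(q) = N_px × Var[I];
the overall scale is otherwise arbitrary, as for any image structure factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stack import ImageStack

__all__ = ["StructureFactor", "static_structure_factor"]


@dataclass
class StructureFactor:
    """2D and angle-averaged structure factor of a movie."""

    sq2d: np.ndarray  # (H, W), fftshifted, q=0 at center
    qx: np.ndarray  # (W,) 1/μm, fftshifted
    qy: np.ndarray  # (H,) 1/μm
    q_grid: np.ndarray  # radial bin centers, 1/μm
    sq_radial: np.ndarray  # angle-averaged S(q), DC bin excluded


def static_structure_factor(
    stack: ImageStack, window: str | None = None
) -> StructureFactor:
    """Frame-averaged |FFT|² of the mean-subtracted intensity.

    ``window="hann"`` applies a separable Hann window before the transform
    (off by default; the bare transform is the plain definition). Radial
    averaging uses annuli of width one frequency step of the shorter image
    axis and excludes the DC bin.
    """
    f = stack.frames.astype(np.float64)
    T, H, W = f.shape
    if window == "hann":
        win = np.outer(np.hanning(H), np.hanning(W))
    elif window is None:
        win = 1.0
    else:
        raise ValueError(f"unknown window {window!r}")
    sq = np.zeros((H, W))
    for frame in f:
        g = (frame - frame.mean()) * win
        sq += np.abs(np.fft.fft2(g)) ** 2
    sq /= T * H * W  # pixel-count normalization: Parseval gives N_px * Var
    sq = np.fft.fftshift(sq)
    ps = stack.pixel_size
    qx = 2 * np.pi * np.fft.fftshift(np.fft.fftfreq(W, d=ps))
    qy = 2 * np.pi * np.fft.fftshift(np.fft.fftfreq(H, d=ps))
    QX, QY = np.meshgrid(qx, qy)
    qr = np.hypot(QX, QY)
    dq = 2 * np.pi / (min(H, W) * ps)
    nbins = int(qr.max() / dq) + 1
    idx = np.minimum((qr / dq + 0.5).astype(int), nbins - 1)
    counts = np.bincount(idx.ravel(), minlength=nbins)
    sums = np.bincount(idx.ravel(), weights=sq.ravel(), minlength=nbins)
    with np.errstate(invalid="ignore", divide="ignore"):
        radial = sums / counts
    q_grid = np.arange(nbins) * dq
    # drop the DC bin and any empty bins
    good = (q_grid > 0) & (counts > 0)
    return StructureFactor(
        sq2d=sq, qx=qx, qy=qy, q_grid=q_grid[good], sq_radial=radial[good]
    )
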