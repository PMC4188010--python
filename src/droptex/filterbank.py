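"""Rotation-invariant texture filter bank.

The bank follows the Varma–Zisserman root filter set: 18 edge filters
(first derivative of an anisotropic Gaussian, 6 orientations x 3 scales),
18 bar filters (second derivative, same grid), one isotropic Gaussian and
one Laplacian of Gaussian.  An image is convolved with all 38 kernels, but
for each edge/bar scale only the maximum response over the 6 orientations
is kept, so every pixel is described by an 8-vector

    [edge s0, edge s1, edge s2, bar s0, bar s1, bar s2, gaussian, log]

which is quasi-invariant to rotations of the underlying texture (exactly
invariant for rotations that are multiples of 30 degrees, up to sampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "FilterKernel",
    "FilterBank",
    "ResponseImage",
    "build_filter_bank",
    "apply_filter_bank",
]

#: (sigma_perpendicular, sigma_elongated) of the full-scale bank, per scale.
BASE_SCALES = ((1.0, 3.0), (2.0, 6.0), (4.0, 12.0))
#: sigma of the full-scale Gaussian and LoG kernels.
BASE_BLOB_SIGMA = 10.0
#: support of the full-scale bank in pixels (odd).
BASE_SUPPORT = 49
N_ORIENTATIONS = 6
N_SCALES = 3
N_CHANNELS = 8


@dataclass(frozen=True)
class FilterKernel:
    """One kernel of the bank.

    kind is one of ``edge``, ``bar``, ``gaussian``, ``log``; scale_index and
    orientation_index are meaningful for edge/bar kernels only (-1 otherwise).
    """

    kind: str
    scale_index: int
    orientation_index: int
    kernel: np.ndarray


@dataclass(frozen=True)
class FilterBank:
    kernels: tuple[FilterKernel, ...]
    scale_factor: float
    support: int

    def __len__(self) -> int:
        return len(self.kernels)

    def to_frame(self) -> pd.DataFrame:
        """Tabular dump (one row per kernel) for inspection/serialization."""
        rows = []
        for i, k in enumerate(self.kernels):
            row = {
                "index": i,
                "kind": k.kind,
                "scale_index": k.scale_index,
                "orientation_index": k.orientation_index,
            }
            row.update(
                {f"w{j:04d}": v for j, v in enumerate(k.kernel.ravel())}
            )
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class ResponseImage:
    """Per-pixel 8-channel rotation-invariant filter responses.

    ``valid`` flags pixels farther than half the kernel support from the
    image border; responses at flagged-False pixels are computed with
    reflected padding and must not enter texton histograms.
    """

    responses: np.ndarray  # H x W x 8
    valid: np.ndarray  # H x W bool
    channel_names: tuple[str, ...] = field(
        default=(
            "edge_s0", "edge_s1", "edge_s2",
            "bar_s0", "bar_s1", "bar_s2",
            "gaussian", "log",
        )
    )


def _gauss1d(sigma: float, x: np.ndarray, order: int) -> np.ndarray:
    g = np.exp(-(x ** 2) / (2.0 * sigma ** 2))
    if order == 0:
        return g
    if order == 1:
        return -(x / sigma ** 2) * g
    if order == 2:
        return ((x ** 2 - sigma ** 2) / sigma ** 4) * g
    raise ValueError(f"unsupported derivative order {order}")


def _normalise(kernel: np.ndarray) -> np.ndarray:
    # zero mean, then unit L1 norm for comparable response magnitudes
    kernel = kernel - kernel.mean()
    s = np.abs(kernel).sum()
    if s > 0:
        kernel = kernel / s
    return kernel


def _oriented_kernel(
    sigma_perp: float, sigma_elong: float, angle: float, order: int, support: int
) -> np.ndarray:
    half = support // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    # rotate coordinates so the filter is elongated along x', derivative
    # taken along y'
    c, s = np.cos(angle), np.sin(angle)
    xr = c * x + s * y
    yr = -s * x + c * y
    kern = _gauss1d(sigma_elong, xr, 0) * _gauss1d(sigma_perp, yr, order)
    return _normalise(kern)


def _gaussian_kernel(sigma: float, support: int) -> np.ndarray:
    half = support // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    g = np.exp(-(x ** 2 + y ** 2) / (2.0 * sigma ** 2))
    return g / g.sum()


def _log_kernel(sigma: float, support: int) -> np.ndarray:
    half = support // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    r2 = x ** 2 + y ** 2
    log = (r2 - 2.0 * sigma ** 2) / sigma ** 4 * np.exp(-r2 / (2.0 * sigma ** 2))
    return _normalise(log)


def build_filter_bank(scale_factor: float = 0.5) -> FilterBank:
    """Construct the 38-kernel bank at ``scale_factor`` times the full scale.

    All sigmas of the full-scale bank are multiplied by ``scale_factor`` and
    the square support shrinks proportionally (49 px at scale 1, 25 px at the
    default half scale).  Edge/bar/LoG kernels are zero-mean with unit L1
    norm; the Gaussian sums to one.
    """
    if not scale_factor > 0:
        raise ValueError("scale_factor must be positive")
    support = int(round(BASE_SUPPORT * scale_factor))
    if support % 2 == 0:
        support += 1
    support = max(support, 3)

    kernels: list[FilterKernel] = []
    angles = [np.pi * o / N_ORIENTATIONS for o in range(N_ORIENTATIONS)]
    for kind, order in (("edge", 1), ("bar", 2)):
        for si, (sp, se) in enumerate(BASE_SCALES):
            for oi, ang in enumerate(angles):
                kern = _oriented_kernel(
                    sp * scale_factor, se * scale_factor, ang, order, support
                )
                kernels.append(FilterKernel(kind, si, oi, kern))
    kernels.append(
        FilterKernel(
            "gaussian", -1, -1,
            _gaussian_kernel(BASE_BLOB_SIGMA * scale_factor, support),
        )
    )
    kernels.append(
        FilterKernel(
            "log", -1, -1,
            _log_kernel(BASE_BLOB_SIGMA * scale_factor, support),
        )
    )
    return FilterBank(tuple(kernels), scale_factor, support)


def apply_filter_bank(
    image: np.ndarray, bank: FilterBank, keep_all: bool = False
) -> ResponseImage | tuple[ResponseImage, np.ndarray]:
    """Filter ``image`` with the whole bank and max-collapse orientations.

    Border handling is by reflection; pixels within half the kernel support
    of the border are flagged invalid in the result.  With ``keep_all`` the
    raw H x W x 38 response stack is returned as well (used by tests to
    verify the max-collapse).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D greyscale image")
    half = bank.support // 2
    if min(image.shape) < bank.support:
        raise ValueError(
            f"image {image.shape} smaller than kernel support {bank.support}"
        )
    padded = np.pad(image, half, mode="reflect")

    raw = np.empty(image.shape + (len(bank.kernels),), dtype=float)
    for i, fk in enumerate(bank.kernels):
        raw[:, :, i] = signal.fftconvolve(padded, fk.kernel, mode="valid")

    responses = np.empty(image.shape + (N_CHANNELS,), dtype=float)
    idx = 0
    for block in range(2):  # edge block then bar block
        for si in range(N_SCALES):
            lo = (block * N_SCALES + si) * N_ORIENTATIONS
            responses[:, :, idx] = raw[:, :, lo : lo + N_ORIENTATIONS].max(axis=2)
            idx += 1
    responses[:, :, 6] = raw[:, :, 36]
    responses[:, :, 7] = raw[:, :, 37]

    valid = np.zeros(image.shape, dtype=bool)
    valid[half : image.shape[0] - half, half : image.shape[1] - half] = True

    out = ResponseImage(responses, valid)
    if keep_all:
        return out, raw
    return out
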