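"""Droplet pre-processing before texture analysis.

Covers greyscale/contrast normalization of raw images, per-pixel gamma
correction that lifts the shadowed droplet rim without disturbing the
centre, radial extension of the droplet boundary (so filter responses at
the rim are not dominated by the boundary edge itself), and the final
intensity standardization plus downscaling that matches new images to the
resolution at which the texton dictionary was built.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .segmentation import DropletBoundary, N_ANGLES, _polar_sample

__all__ = [
    "ProcessedDroplet",
    "ExtendedDroplet",
    "to_grey_full_range",
    "gamma_correct",
    "extend_boundary",
    "normalize_and_scale",
]

PAD_WIDTH = 13  # radial pixels added beyond the boundary (half filter + 1)
MEDIAN_WINDOW = 10  # innermost boundary-adjacent pixels feeding the median
GAMMA_MIN = 0.05
#: crop margin so the polar image can hold the 13-px extension ring
CROP_MARGIN = 2 * (PAD_WIDTH + 1)

# luminance weights for colour conversion (ITU-R 601)
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class ExtendedDroplet:
    """Cropped droplet with its radially extended ring.

    ``droplet_mask`` marks original droplet pixels (the only ones whose
    texton labels may be counted); ``ring_mask`` marks the synthetic
    extension ring, excluded from histograms.
    """

    image: np.ndarray
    droplet_mask: np.ndarray
    ring_mask: np.ndarray
    origin: tuple[int, int]  # top-left of the crop in the source image


@dataclass
class ProcessedDroplet:
    image: np.ndarray  # float, mean 0 / std 1
    valid_mask: np.ndarray  # droplet pixels eligible for histograms
    ring_mask: np.ndarray
    scale: float


def to_grey_full_range(image: np.ndarray) -> np.ndarray:
    """Greyscale conversion plus linear stretch to the full 0-255 range.

    Colour images are reduced to luminance first; a constant image maps to
    all zeros.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img[..., :3] @ _LUMA
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) * (255.0 / (hi - lo))


def gamma_correct(
    droplet: np.ndarray, mask: np.ndarray | None = None, sigma: float = 1.0
) -> np.ndarray:
    """Shadow-lifting per-pixel gamma correction.

    Each pixel's gamma is its low-pass-filtered intensity mapped to [0, 1]
    and clamped below at 0.05, so dark (shadowed) neighbourhoods get a
    strong boost (gamma << 1) while bright regions pass through unchanged
    (gamma = 1):  out = 255 * (I/255) ** gamma.  Monotone per pixel and
    range preserving.  With a mask, pixels outside it are left untouched.
    """
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    img = np.asarray(droplet, dtype=float)
    im_lp = ndimage.gaussian_filter(img, sigma)
    gamma = np.clip(im_lp / 255.0, GAMMA_MIN, 1.0)
    out = 255.0 * (np.clip(img, 0, 255) / 255.0) ** gamma
    if mask is not None:
        res = img.copy()
        m = np.asarray(mask, dtype=bool)
        res[m] = out[m]
        return res
    return out


def _crop_with_margin(shape, mask, margin):
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0 = max(rows[0] - margin, 0)
    r1 = min(rows[-1] + margin + 1, shape[0])
    c0 = max(cols[0] - margin, 0)
    c1 = min(cols[-1] + margin + 1, shape[1])
    return r0, r1, c0, c1


def polar_droplet(image: np.ndarray, mask: np.ndarray):
    """Polar resampling of the cropped droplet about its centroid.

    The crop keeps a margin around the droplet bounding box so that the
    extension ring fits; the polar image has R rows (R = half the larger
    crop dimension, 1-px radial sampling) and 360 one-degree columns.
    Returns (polar image, polar mask, per-degree boundary radius, centre,
    crop origin).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty droplet mask")
    r0, r1, c0, c1 = _crop_with_margin(image.shape, mask, CROP_MARGIN)
    crop = np.asarray(image, dtype=float)[r0:r1, c0:c1]
    mcrop = mask[r0:r1, c0:c1]
    rr, cc = np.nonzero(mcrop)
    centre = (float(rr.mean()), float(cc.mean()))
    R = int(np.ceil(max(crop.shape) / 2))
    polar = _polar_sample(crop, centre, R)
    polar_mask = _polar_sample(mcrop.astype(float), centre, R) >= 0.5
    # boundary radius per degree: outermost in-mask radius of the column
    radius = np.zeros(N_ANGLES, dtype=int)
    for t in range(N_ANGLES):
        inside = np.flatnonzero(polar_mask[:, t])
        radius[t] = inside[-1] if inside.size else 0
    return polar, polar_mask, radius, centre, (r0, c0)


def extend_polar(polar: np.ndarray, radius: np.ndarray,
                 pad: int = PAD_WIDTH, window: int = MEDIAN_WINDOW):
    """Replace, per angular column, the ``pad`` radii beyond the boundary
    with the median of the ``window`` innermost boundary-adjacent pixels.
    Returns the extended polar image and the boolean polar ring mask."""
    out = polar.copy()
    ring = np.zeros_like(polar, dtype=bool)
    R = polar.shape[0]
    for t in range(polar.shape[1]):
        rb = int(radius[t])
        lo = max(rb - window + 1, 0)
        med = np.median(polar[lo : rb + 1, t])
        hi = min(rb + 1 + pad, R)
        out[rb + 1 : hi, t] = med
        ring[rb + 1 : hi, t] = True
    return out, ring


def extend_boundary(
    image: np.ndarray, boundary: DropletBoundary | np.ndarray
) -> ExtendedDroplet:
    """Radially extend the droplet by a 13-px ring of boundary-like pixels.

    The cropped droplet is resampled to polar coordinates about its
    centroid, each angular column is padded beyond the boundary with the
    median of the ten innermost adjacent pixels (median, not mean, to shrug
    off stray segmentation outliers), and only the ring of added pixels is
    written back into the Cartesian crop.  Filter responses computed over
    the ring are excluded from histograms downstream.
    """
    mask = boundary.mask if isinstance(boundary, DropletBoundary) else boundary
    polar, _, radius, centre, (r0, c0) = polar_droplet(image, mask)
    extended, _ = extend_polar(polar, radius)

    rr0, rr1, cc0, cc1 = _crop_with_margin(np.asarray(image).shape, mask, CROP_MARGIN)
    crop = np.asarray(image, dtype=float)[rr0:rr1, cc0:cc1].copy()
    mcrop = np.asarray(mask, dtype=bool)[rr0:rr1, cc0:cc1]

    # Cartesian ring: pixels whose radius lies in (boundary, boundary+13]
    yy, xx = np.mgrid[0 : crop.shape[0], 0 : crop.shape[1]].astype(float)
    dy, dx = yy - centre[0], xx - centre[1]
    r = np.hypot(dy, dx)
    theta = np.mod(np.degrees(np.arctan2(dy, dx)), 360.0)
    t_idx = np.mod(np.round(theta).astype(int), N_ANGLES)
    rb = radius[t_idx].astype(float)
    ring = (~mcrop) & (r > rb) & (r <= rb + PAD_WIDTH)

    # sample the extended polar image back at the ring pixels (bilinear in
    # r and theta, with angular wrap handled by a padded column)
    R = extended.shape[0]
    pol_wrap = np.concatenate([extended, extended[:, :1]], axis=1)
    coords = np.vstack(
        [np.clip(r[ring], 0, R - 1), theta[ring] * (N_ANGLES / 360.0)]
    )
    crop[ring] = ndimage.map_coordinates(pol_wrap, coords, order=1, mode="nearest")

    return ExtendedDroplet(crop, mcrop, ring, (rr0, cc0))


def normalize_and_scale(
    image: np.ndarray,
    mask: np.ndarray,
    scale: float = 0.25,
    ring_mask: np.ndarray | None = None,
) -> ProcessedDroplet:
    """Standardize intensities and downscale to the dictionary resolution.

    The image is z-scored (so the descriptor is invariant to affine
    intensity changes), bilinearly downscaled by ``scale``, and re-centred
    so the delivered array has mean 0 and unit standard deviation to within
    1e-6.  Masks are downscaled with nearest-neighbour sampling.
    """
    from skimage.transform import rescale

    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    img = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    mu, sd = img[mask].mean() if mask.any() else img.mean(), None
    sd = img[mask].std() if mask.any() else img.std()
    if sd == 0:
        sd = 1.0
    z = (img - mu) / sd

    if scale != 1.0:
        z = rescale(z, scale, order=1, anti_aliasing=True)
        mask = rescale(mask.astype(float), scale, order=0) >= 0.5
        if ring_mask is not None:
            ring_mask = rescale(
                np.asarray(ring_mask, float), scale, order=0
            ) >= 0.5
    if ring_mask is None:
        ring_mask = np.zeros_like(mask)

    # enforce the exact mean-0 / std-1 contract on the delivered array
    sd = z.std()
    z = (z - z.mean()) / (sd if sd > 0 else 1.0)
    return ProcessedDroplet(z, mask, ring_mask, scale)
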