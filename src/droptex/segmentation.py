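"""Well registration and droplet boundary segmentation.

Each plate type has a background model built from an empty plate: a
pixel-wise mean image per subwell position plus a mask of the well frame
(the plastic structure whose strong edges would otherwise hijack boundary
tracing).  New images are rigidly registered to the background by
exhaustive translation search, the frame gradients are suppressed, and the
droplet boundary is traced as the circular shortest path through the
negated gradient magnitude in polar coordinates around a seed point inside
the drop.  If the traced region fails plausibility checks the search is
retried on a strongly gamma-corrected image (which flattens large dark
precipitate masses without touching the high-frequency droplet rim) and
finally on a blurred image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import draw, filters, measure

__all__ = [
    "BackgroundModel",
    "WellRegistration",
    "DropletBoundary",
    "build_background",
    "register_well",
    "circular_shortest_path",
    "segment_droplet",
]

log = logging.getLogger(__name__)

N_ANGLES = 360


@dataclass
class BackgroundModel:
    """Per-subwell mean empty-well image and derived frame mask."""

    backgrounds: dict  # subwell id -> 2-D float array
    frame_masks: dict = field(default_factory=dict)  # subwell id -> bool array
    plate_type: str = "default"

    def background(self, subwell) -> np.ndarray:
        return self.backgrounds[subwell]

    def frame_mask(self, subwell) -> np.ndarray:
        return self.frame_masks[subwell]


@dataclass(frozen=True)
class WellRegistration:
    dx: int  # column shift of the background that best matches the image
    dy: int  # row shift
    residual: float


@dataclass
class DropletBoundary:
    centre: tuple[float, float]  # (row, col) of the polar origin
    radius_by_degree: np.ndarray  # length-360, pixels
    mask: np.ndarray  # bool image, filled boundary polygon
    area: float = 0.0
    centroid: tuple[float, float] = (0.0, 0.0)
    eccentricity: float = 0.0
    major_axis: float = 0.0
    minor_axis: float = 0.0
    used_fallback: str = "none"  # none | gamma | blur

    def __post_init__(self):
        if self.mask.any():
            props = measure.regionprops(self.mask.astype(np.uint8))[0]
            self.area = float(props.area)
            self.centroid = tuple(map(float, props.centroid))
            self.eccentricity = float(props.eccentricity)
            self.major_axis = float(props.axis_major_length)
            self.minor_axis = float(props.axis_minor_length)

    def radii_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"degree": np.arange(N_ANGLES), "radius": self.radius_by_degree}
        )


def _frame_mask_from_background(bg: np.ndarray) -> np.ndarray:
    """Frame = dark plastic plus its strong edges, dilated a little."""
    thr = filters.threshold_otsu(bg)
    dark = bg < thr
    grad = filters.sobel(bg / 255.0)
    strong = grad > max(0.05, 0.25 * grad.max())
    structure = np.ones((7, 7), dtype=bool)
    return ndimage.binary_dilation(dark | strong, structure=structure)


def build_background(
    empty_plate_images: dict, plate_type: str = "default"
) -> BackgroundModel:
    """Average the empty-plate images of each subwell position."""
    backgrounds, frames = {}, {}
    for subwell, images in empty_plate_images.items():
        if len(images) == 0:
            raise ValueError(f"no empty images for subwell {subwell!r}")
        stack = np.stack([np.asarray(im, dtype=float) for im in images])
        bg = stack.mean(axis=0)
        backgrounds[subwell] = bg
        frames[subwell] = _frame_mask_from_background(bg)
    return BackgroundModel(backgrounds, frames, plate_type)


def register_well(
    image: np.ndarray, background: np.ndarray, max_shift: int = 10
) -> WellRegistration:
    """Find the integer translation of the background minimizing the mean
    absolute pixel difference against ``image`` over a +/-max_shift window.

    Ties are broken towards the smallest |dx|+|dy|, then lexicographically
    on (dy, dx).
    """
    image = np.asarray(image, dtype=float)
    background = np.asarray(background, dtype=float)
    if image.shape != background.shape:
        raise ValueError("image and background must have the same shape")
    H, W = image.shape
    best = None
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            isl_r = slice(max(dy, 0), H + min(dy, 0))
            isl_c = slice(max(dx, 0), W + min(dx, 0))
            bsl_r = slice(max(-dy, 0), H + min(-dy, 0))
            bsl_c = slice(max(-dx, 0), W + min(-dx, 0))
            diff = np.abs(image[isl_r, isl_c] - background[bsl_r, bsl_c])
            res = diff.mean()
            key = (res, abs(dx) + abs(dy), dy, dx)
            if best is None or key < best[0]:
                best = (key, dy, dx, res)
    _, dy, dx, res = best
    return WellRegistration(dx=dx, dy=dy, residual=float(res))


def circular_shortest_path(cost: np.ndarray, step: int = 1) -> np.ndarray:
    """Minimum-cost circularly closed path across the columns of ``cost``.

    The path picks one row per column, may move at most ``step`` rows
    between adjacent columns, and must close on itself (|p[last] - p[0]|
    <= step, treating the last and first columns as adjacent).  Dynamic
    programming is run from every candidate start row simultaneously and
    the global minimum is returned as an array of row indices.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2 or cost.shape[0] < 2:
        raise ValueError("cost must be a 2-D matrix with at least 2 rows")
    if not np.isfinite(cost).all():
        raise ValueError("cost matrix contains non-finite values")
    R, T = cost.shape

    def shift_min(D):
        out = D.copy()
        for s in range(1, step + 1):
            up = np.full_like(D, np.inf)
            up[:, s:] = D[:, :-s]
            dn = np.full_like(D, np.inf)
            dn[:, :-s] = D[:, s:]
            out = np.minimum(out, np.minimum(up, dn))
        return out

    # D[s, r]: cheapest cost of a path starting at row s in column 0 and
    # currently at row r
    D = np.full((R, R), np.inf)
    D[np.arange(R), np.arange(R)] = cost[:, 0]
    for t in range(1, T):
        D = shift_min(D) + cost[None, :, t]

    # closure: end row within `step` of the start row
    close = np.full((R, R), np.inf)
    for s in range(-step, step + 1):
        idx = np.arange(R)
        tgt = idx + s
        ok = (tgt >= 0) & (tgt < R)
        close[idx[ok], tgt[ok]] = 0.0
    totals = D + close
    start = int(np.argmin(totals.min(axis=1)))

    # backtrack for the best start row
    dp = np.full((T, R), np.inf)
    dp[0, start] = cost[start, 0]
    for t in range(1, T):
        prev = dp[t - 1]
        for r in range(R):
            lo, hi = max(0, r - step), min(R, r + step + 1)
            dp[t, r] = prev[lo:hi].min() + cost[r, t]
    end_ok = np.full(R, np.inf)
    lo, hi = max(0, start - step), min(R, start + step + 1)
    end_ok[lo:hi] = 0.0
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmin(dp[-1] + end_ok))
    for t in range(T - 2, -1, -1):
        r = path[t + 1]
        lo, hi = max(0, r - step), min(R, r + step + 1)
        path[t] = lo + int(np.argmin(dp[t, lo:hi]))
    return path


def _polar_sample(image: np.ndarray, centre, n_radii: int) -> np.ndarray:
    """Bilinear polar resampling: rows = integer radii, cols = degrees."""
    theta = np.deg2rad(np.arange(N_ANGLES))
    r = np.arange(n_radii)
    rr = r[:, None] * np.sin(theta)[None, :] + centre[0]
    cc = r[:, None] * np.cos(theta)[None, :] + centre[1]
    return ndimage.map_coordinates(image, [rr, cc], order=1, mode="nearest")


def _seed_centre(image, bg_shifted, interior):
    """Centroid of the background-subtracted foreground inside the well."""
    diff = np.abs(np.asarray(image, float) - bg_shifted)
    fg = (diff > 15) & interior
    fg = ndimage.binary_opening(fg, structure=np.ones((5, 5), dtype=bool))
    if fg.sum() < 50:
        fg = interior
    r, c = np.nonzero(fg)
    return float(r.mean()), float(c.mean())


def _shift_image(arr: np.ndarray, dy: int, dx: int, fill=0) -> np.ndarray:
    out = np.full_like(arr, fill)
    H, W = arr.shape
    osl_r = slice(max(dy, 0), H + min(dy, 0))
    osl_c = slice(max(dx, 0), W + min(dx, 0))
    isl_r = slice(max(-dy, 0), H + min(-dy, 0))
    isl_c = slice(max(-dx, 0), W + min(-dx, 0))
    out[osl_r, osl_c] = arr[isl_r, isl_c]
    return out


def segment_droplet(
    image: np.ndarray,
    reg: WellRegistration,
    bg: np.ndarray,
    frame_mask: np.ndarray,
    min_area_frac: float = 0.02,
    max_area_frac: float = 0.95,
    max_frame_frac: float = 0.10,
    min_radius_ratio: float = 0.45,
    fallback_gamma_sigma: float = 10.0,
    blur_sigma: float = 3.0,
) -> DropletBoundary | None:
    """Trace the droplet boundary; returns None when unsegmentable.

    The gradient magnitude of the image is zeroed on the registered well
    frame, resampled to polar coordinates around a seed centre inside the
    drop, and the circular shortest path through the negated gradient gives
    the boundary radius per degree.  A result whose area falls outside
    [min_area_frac, max_area_frac] of the well interior, or whose boundary
    runs along the frame for more than ``max_frame_frac`` of its length,
    triggers the gamma-corrected then the blurred retry; so does a deep
    radial collapse (minimum radius below ``min_radius_ratio`` of the
    median), which betrays a path that dipped onto a dark interior mass
    rather than following the roughly convex drop outline.
    """
    from .preprocess import gamma_correct

    image = np.asarray(image, dtype=float)
    bg_shift = _shift_image(np.asarray(bg, float), reg.dy, reg.dx, fill=255.0)
    frame_shift = _shift_image(frame_mask.astype(bool), reg.dy, reg.dx, fill=True)
    interior = ~frame_shift
    well_area = max(int(interior.sum()), 1)
    centre = _seed_centre(image, bg_shift, interior)

    def attempt(img, tag):
        grad = filters.sobel(ndimage.gaussian_filter(img, 1.0) / 255.0)
        grad[frame_shift] = 0.0
        max_r = int(
            min(
                centre[0],
                centre[1],
                image.shape[0] - 1 - centre[0],
                image.shape[1] - 1 - centre[1],
            )
        )
        if max_r < 8:
            return None
        polar = _polar_sample(grad, centre, max_r)
        # weight by radius so the path optimizes the physical line integral
        # of gradient along the contour (a one-degree step spans an arc
        # proportional to r); this stops the path collapsing onto small
        # high-contrast loops around interior precipitate/crystal clusters
        weighted = polar * np.arange(max_r, dtype=float)[:, None]
        # skip tiny radii so the path cannot collapse onto the seed point
        r0 = 4
        path = circular_shortest_path(-weighted[r0:], step=1) + r0
        radii = path.astype(float)
        theta = np.deg2rad(np.arange(N_ANGLES))
        rr = centre[0] + radii * np.sin(theta)
        cc = centre[1] + radii * np.cos(theta)
        mask = np.zeros(image.shape, dtype=bool)
        fr, fc = draw.polygon(rr, cc, shape=image.shape)
        mask[fr, fc] = True

        area_frac = mask.sum() / well_area
        bi = np.clip(np.round(rr).astype(int), 0, image.shape[0] - 1)
        bj = np.clip(np.round(cc).astype(int), 0, image.shape[1] - 1)
        frame_frac = frame_shift[bi, bj].mean()
        ok = (
            (min_area_frac <= area_frac <= max_area_frac)
            and frame_frac <= max_frame_frac
            and radii.min() >= min_radius_ratio * np.median(radii)
        )
        if not ok:
            return None
        return DropletBoundary(centre, radii, mask, used_fallback=tag)

    result = attempt(image, "none")
    if result is None:
        corrected = gamma_correct(image, sigma=fallback_gamma_sigma)
        result = attempt(corrected, "gamma")
    if result is None:
        blurred = ndimage.gaussian_filter(image, blur_sigma)
        result = attempt(blurred, "blur")
    if result is None:
        log.warning("droplet unsegmentable after gamma and blur fallbacks")
    return result
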