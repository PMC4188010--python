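"""Seeded synthetic crystallization-well images with ground truth.

Renders the elements a plate imager sees — the dark plastic well frame with
corner shadows, a sessile drop with a shadowed rim, and a per-class texture
inside the drop — for eight outcome classes: clear drops, granular
precipitate, needle/plate crystals with strong straight edges, microcrystal
showers, smooth phase-separation blobs, and three dispensing/imaging faults
(empty well, undersized drop, off-frame well).  Textures are designed for
controllable statistical structure rather than photorealism: crystal edges
drive the oriented-edge filter channels, precipitate grain drives the
mid-scale bar/LoG channels, and clear drops stay smooth.

Every image is a deterministic function of (spec, seed); ground-truth
droplet and crystal masks are emitted alongside.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw

__all__ = [
    "CLASSES",
    "FAULT_CLASSES",
    "FixtureSpec",
    "WellTruth",
    "generate_well",
    "generate_texture",
    "generate_plate",
    "generate_empty_plate",
    "dictionary_training_set",
]

CLASSES = (
    "clear",
    "precipitate",
    "microcrystal_shower",
    "crystal",
    "phase_separation",
    "fault_empty",
    "fault_small",
    "fault_offframe",
)
FAULT_CLASSES = ("fault_empty", "fault_small", "fault_offframe")

DEFAULT_SIZE = 256
FRAME_WIDTH = 14


@dataclass(frozen=True)
class FixtureSpec:
    klass: str
    seed: int
    centre: tuple[float, float] | None = None  # (row, col); None = jittered
    radius: float | None = None  # pixels; None = class default
    rim_depth: float | None = None  # rim shadow depth; None = default 70
    texture: dict = field(default_factory=dict)


@dataclass
class WellTruth:
    klass: str
    droplet_mask: np.ndarray
    crystal_mask: np.ndarray
    centre: tuple[float, float]
    radius: float


def _well_base(size: int, rng: np.random.Generator) -> np.ndarray:
    """Bright well interior, dark plastic frame, soft corner shadows."""
    img = np.full((size, size), 205.0)
    # illumination gradient across the interior
    yy, xx = np.mgrid[0:size, 0:size] / size
    img += 12.0 * (yy - 0.5) + 8.0 * (xx - 0.5)
    # frame band around the border
    w = FRAME_WIDTH
    img[:w, :] = img[-w:, :] = 60.0
    img[:, :w] = img[:, -w:] = 60.0
    # corner shadows bleeding into the interior
    for cy in (w, size - w):
        for cx in (w, size - w):
            d = np.hypot(np.arange(size)[:, None] - cy, np.arange(size)[None, :] - cx)
            img -= 35.0 * np.exp(-(d / 26.0) ** 2)
    return np.clip(img, 0, 255)


def _frame_interior_mask(size: int) -> np.ndarray:
    m = np.zeros((size, size), dtype=bool)
    w = FRAME_WIDTH
    m[w:-w, w:-w] = True
    return m


def _droplet_mask(size, centre, radius, rng):
    """Slightly irregular disk: radius modulated by a low-order harmonic."""
    theta = np.deg2rad(np.arange(360))
    amp = rng.uniform(0.0, 0.04, size=2)
    phase = rng.uniform(0, 2 * np.pi, size=2)
    r = radius * (
        1.0
        + amp[0] * np.sin(2 * theta + phase[0])
        + amp[1] * np.sin(3 * theta + phase[1])
    )
    rr = centre[0] + r * np.sin(theta)
    cc = centre[1] + r * np.cos(theta)
    mask = np.zeros((size, size), dtype=bool)
    fr, fc = draw.polygon(rr, cc, shape=(size, size))
    mask[fr, fc] = True
    return mask


def _rim_shadow(size, centre, radius, depth=70.0, width_frac=0.14):
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    r = np.hypot(yy - centre[0], xx - centre[1])
    inner = radius * (1.0 - width_frac)
    t = np.clip((r - inner) / (radius - inner), 0.0, 1.0)
    shadow = depth * t ** 2
    shadow[r > radius] = 0.0
    return shadow


def generate_texture(
    kind: str,
    size: int,
    seed: int,
    strength: float = 1.0,
    clump: float = 0.0,
    clump_soft: float = 5.0,
    n_items: int | None = None,
):
    """A plain texture patch (no well/droplet geometry).

    Returns (additive intensity field, crystal mask).  Used both to fill
    droplets and as a stand-alone texture for rotation-invariance checks.
    """
    rng = np.random.default_rng(seed)
    tex = np.zeros((size, size))
    cmask = np.zeros((size, size), dtype=bool)
    if kind == "clear":
        yy, xx = np.mgrid[0:size, 0:size] / size
        tex = 6.0 * np.sin(2 * np.pi * (0.7 * yy + 0.4 * xx) + rng.uniform(0, 6))
        tex += rng.normal(0, 1.5, (size, size))
    elif kind == "precipitate":
        grain = ndimage.gaussian_filter(rng.normal(0, 1, (size, size)), 2.5)
        grain /= max(grain.std(), 1e-9)
        tex = -28.0 * strength * np.clip(grain, -2.5, 2.5)
        tex += rng.normal(0, 2.0, (size, size))
        if clump:
            # one large, very dark precipitate mass with a soft edge (its
            # gradient is spread over many pixels, unlike the sharp drop rim)
            cy, cx = rng.uniform(size * 0.35, size * 0.65, 2)
            blob = np.zeros((size, size))
            fr, fc = draw.disk((cy, cx), clump * size, shape=(size, size))
            blob[fr, fc] = -170.0
            tex += ndimage.gaussian_filter(blob, clump_soft)
    elif kind == "microcrystal_shower":
        n = rng.integers(100, 501)
        for _ in range(n):
            cy, cx = rng.uniform(3, size - 3, 2)
            rad = rng.uniform(1.2, 2.6)
            fr, fc = draw.disk((cy, cx), rad, shape=(size, size))
            tex[fr, fc] += rng.uniform(45, 70)
            cmask[fr, fc] = True
        tex += rng.normal(0, 2.0, (size, size))
    elif kind == "crystal":
        # n_items overrides the sparse default, giving a statistically
        # homogeneous field of needles/plates across the whole patch
        lo, hi = (0.2, 0.8) if n_items is None else (0.05, 0.95)
        n = rng.integers(1, 6) if n_items is None else n_items
        for _ in range(n):
            cy, cx = rng.uniform(size * lo, size * hi, 2)
            angle = rng.uniform(0, np.pi)
            length = rng.uniform(0.25, 0.55) * size / 2
            width = rng.uniform(5, 12)
            dy, dx = np.sin(angle), np.cos(angle)
            py, px = -dx, dy
            corners_r = [
                cy - dy * length - py * width, cy + dy * length - py * width,
                cy + dy * length + py * width, cy - dy * length + py * width,
            ]
            corners_c = [
                cx - dx * length - px * width, cx + dx * length - px * width,
                cx + dx * length + px * width, cx - dx * length + px * width,
            ]
            fr, fc = draw.polygon(corners_r, corners_c, shape=(size, size))
            tex[fr, fc] = rng.uniform(45, 65)
            cmask[fr, fc] = True
        tex += rng.normal(0, 2.0, (size, size))
    elif kind == "phase_separation":
        n = rng.integers(2, 7)
        for _ in range(n):
            cy, cx = rng.uniform(size * 0.15, size * 0.85, 2)
            rad = rng.uniform(0.06, 0.16) * size
            fr, fc = draw.disk((cy, cx), rad, shape=(size, size))
            tex[fr, fc] -= rng.uniform(25, 40)
        tex = ndimage.gaussian_filter(tex, 2.0)
        tex += rng.normal(0, 1.5, (size, size))
    else:
        raise ValueError(f"unknown texture kind {kind!r}")
    return tex, cmask


def generate_well(
    spec: FixtureSpec, size: int = DEFAULT_SIZE
) -> tuple[np.ndarray, WellTruth]:
    """Render one subwell image and its ground truth for ``spec``."""
    if spec.klass not in CLASSES:
        raise ValueError(f"unknown class {spec.klass!r}")
    rng = np.random.default_rng(spec.seed)
    img = _well_base(size, rng)
    interior = _frame_interior_mask(size)

    droplet_mask = np.zeros((size, size), dtype=bool)
    crystal_mask = np.zeros((size, size), dtype=bool)
    centre = (float(size / 2), float(size / 2))
    radius = 0.0

    if spec.klass != "fault_empty":
        if spec.klass == "fault_small":
            radius = spec.radius or rng.uniform(10, 16)
        else:
            radius = spec.radius or rng.uniform(0.28, 0.36) * size
        jitter = rng.uniform(-0.04, 0.04, 2) * size
        centre = spec.centre or (size / 2 + jitter[0], size / 2 + jitter[1])
        centre = (float(centre[0]), float(centre[1]))
        droplet_mask = _droplet_mask(size, centre, radius, rng) & interior

        # droplet is slightly darker than the well floor, with a shadowed rim
        img[droplet_mask] -= 12.0
        depth = 70.0 if spec.rim_depth is None else spec.rim_depth
        img -= _rim_shadow(size, centre, radius, depth=depth) * droplet_mask

        kind = {
            "fault_small": "clear",
            "fault_offframe": "clear",
        }.get(spec.klass, spec.klass)
        tex, cmask = generate_texture(
            kind, size, int(rng.integers(2**31)), **spec.texture
        )
        img[droplet_mask] += tex[droplet_mask]
        crystal_mask = cmask & droplet_mask

    if spec.klass == "fault_offframe":
        shift = int(size * 0.4)
        img = np.roll(img, shift, axis=1)
        img[:, :shift] = 30.0 + rng.normal(0, 2, (size, shift))
        droplet_mask = np.roll(droplet_mask, shift, axis=1)
        droplet_mask[:, :shift] = False
        centre = (centre[0], centre[1] + shift)

    img += rng.normal(0, 2.0, (size, size))
    img = np.clip(img, 0, 255)
    return img.astype(np.uint8), WellTruth(
        spec.klass, droplet_mask, crystal_mask, centre, float(radius)
    )


def generate_empty_plate(
    n_wells: int, seed: int, size: int = DEFAULT_SIZE, subwells=(1, 2, 3)
) -> dict:
    """Empty-well image stacks per subwell position, for background models."""
    rng = np.random.default_rng(seed)
    out = {}
    for sw in subwells:
        out[sw] = [
            generate_well(
                FixtureSpec("fault_empty", int(rng.integers(2**31))), size
            )[0]
            for _ in range(n_wells)
        ]
    return out


def _well_names(n: int) -> list[str]:
    names = []
    for row in string.ascii_uppercase:
        for col in range(1, 13):
            names.append(f"{row}{col}")
            if len(names) == n:
                return names
    raise ValueError("too many wells requested")


def generate_plate(
    n_wells: int,
    class_mix: dict,
    seed: int,
    out_dir: str | Path | None = None,
    size: int = DEFAULT_SIZE,
    n_subwells: int = 3,
    plate_id: str = "PLATE1",
):
    """Generate a plate of ``n_wells`` x ``n_subwells`` droplet images.

    Classes are drawn i.i.d. from ``class_mix`` (probabilities, normalized
    internally).  Returns a manifest DataFrame with columns image_path (or
    image_id when kept in memory), plate, well, subwell, true_class, plus
    the list of (image, WellTruth) pairs in manifest order.  With
    ``out_dir`` set, PNG images and manifest/truth CSVs are written there.
    """
    rng = np.random.default_rng(seed)
    classes = list(class_mix)
    p = np.asarray([class_mix[c] for c in classes], dtype=float)
    p = p / p.sum()
    rows, items = [], []
    for well in _well_names(n_wells):
        for sw in range(1, n_subwells + 1):
            klass = classes[rng.choice(len(classes), p=p)]
            spec = FixtureSpec(klass, int(rng.integers(2**31)))
            img, truth = generate_well(spec, size)
            image_id = f"{plate_id}_{well}_{sw}"
            rows.append(
                {
                    "image_id": image_id,
                    "image_path": f"{image_id}.png",
                    "plate": plate_id,
                    "well": well,
                    "subwell": sw,
                    "true_class": klass,
                    "crystal_pixels": int(truth.crystal_mask.sum()),
                }
            )
            items.append((img, truth))
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        import imageio.v3 as iio

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for row, (img, _) in zip(rows, items):
            iio.imwrite(out_dir / row["image_path"], img)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        manifest[
            ["image_id", "true_class", "crystal_pixels"]
        ].to_csv(out_dir / "truth.csv", index=False)
    return manifest, items


def dictionary_training_set(
    n_precipitate: int = 100,
    n_crystal: int = 52,
    seed: int = 0,
    size: int = DEFAULT_SIZE,
):
    """The seeded fixture sets the reference dictionary is built from:
    precipitation-pattern wells and crystal-containing wells with their
    ground-truth masks."""
    rng = np.random.default_rng(seed)
    precip = [
        generate_well(FixtureSpec("precipitate", int(rng.integers(2**31))), size)
        for _ in range(n_precipitate)
    ]
    crystal = [
        generate_well(FixtureSpec("crystal", int(rng.integers(2**31))), size)
        for _ in range(n_crystal)
    ]
    return precip, crystal
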