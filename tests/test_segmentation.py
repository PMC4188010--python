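import itertools

import numpy as np
import pytest

from droptex.segmentation import (
    build_background,
    circular_shortest_path,
    register_well,
    segment_droplet,
)
from droptex.synthetic import FixtureSpec, generate_well

# ------------------------------------------------------------- background


def test_background_mean_of_inputs(rng):
    a = rng.uniform(0, 255, (32, 32))
    bg = build_background({1: [a, a, a]})
    assert np.allclose(bg.background(1), a)
    b = rng.uniform(0, 255, (32, 32))
    bg2 = build_background({1: [a, b]})
    assert np.allclose(bg2.background(1), (a + b) / 2)


def test_background_requires_images():
    with pytest.raises(ValueError):
        build_background({1: []})


def test_background_keeps_frame_edges(background):
    """The synthetic well frame must survive averaging and be flagged."""
    frame = background.frame_mask(1)
    assert frame[:5, :].all()  # border band is frame
    assert not frame[100:150, 100:150].any()  # well centre is interior


# ------------------------------------------------------------- registration


def test_register_recovers_known_shift(rng):
    bg = rng.uniform(0, 255, (64, 64))
    img = np.full_like(bg, bg.mean())
    dy, dx = 3, -2
    img[3:, :-2] = bg[:-3, 2:]
    reg = register_well(img, bg, max_shift=5)
    assert (reg.dy, reg.dx) == (dy, dx)


def test_register_zero_shift_under_noise(rng):
    bg = rng.uniform(50, 200, (64, 64))
    img = bg + rng.normal(0, 5, bg.shape)
    reg = register_well(img, bg, max_shift=5)
    assert (reg.dy, reg.dx) == (0, 0)


def test_register_matches_exhaustive_oracle(rng):
    bg = rng.uniform(0, 255, (40, 40))
    img = rng.uniform(0, 255, (40, 40))
    reg = register_well(img, bg, max_shift=4)
    best = None
    H, W = img.shape
    for dy in range(-4, 5):
        for dx in range(-4, 5):
            isl = (slice(max(dy, 0), H + min(dy, 0)), slice(max(dx, 0), W + min(dx, 0)))
            bsl = (slice(max(-dy, 0), H + min(-dy, 0)), slice(max(-dx, 0), W + min(-dx, 0)))
            res = np.abs(img[isl] - bg[bsl]).mean()
            key = (res, abs(dx) + abs(dy), dy, dx)
            if best is None or key < best:
                best = key
    assert reg.residual == pytest.approx(best[0])
    assert (best[2], best[3]) == (reg.dy, reg.dx)


def test_register_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        register_well(np.zeros((10, 10)), np.zeros((12, 10)))


# ------------------------------------------------------------- shortest path


def test_csp_follows_zero_cost_row(rng):
    cost = rng.uniform(1, 2, (6, 20))
    cost[3, :] = 0.0
    path = circular_shortest_path(cost)
    assert (path == 3).all()


def brute_force_csp(cost, step=1):
    R, T = cost.shape
    best = np.inf
    for start in range(R):
        for deltas in itertools.product(range(-step, step + 1), repeat=T - 1):
            rows = [start]
            for d in deltas:
                rows.append(rows[-1] + d)
            arr = np.asarray(rows)
            if arr.min() < 0 or arr.max() >= R:
                continue
            if abs(arr[-1] - start) > step:
                continue
            best = min(best, cost[arr, np.arange(T)].sum())
    return best


@pytest.mark.parametrize("case", range(30))
def test_csp_matches_exhaustive_enumeration(case):
    r = np.random.default_rng(case)
    R, T = int(r.integers(2, 7)), int(r.integers(3, 9))
    cost = r.uniform(0, 1, (R, T))
    path = circular_shortest_path(cost)
    assert abs(path[0] - path[-1]) <= 1
    assert np.abs(np.diff(path)).max() <= 1
    total = cost[path, np.arange(T)].sum()
    assert total == pytest.approx(brute_force_csp(cost), abs=1e-9)


def test_csp_input_validation():
    with pytest.raises(ValueError):
        circular_shortest_path(np.ones((1, 5)))
    bad = np.ones((4, 5))
    bad[2, 2] = np.nan
    with pytest.raises(ValueError):
        circular_shortest_path(bad)


# ------------------------------------------------------------- droplet


def _segment(background, spec):
    img, truth = generate_well(spec)
    reg = register_well(
        img.astype(float), background.background(1), max_shift=4
    )
    b = segment_droplet(
        img, reg, background.background(1), background.frame_mask(1)
    )
    return b, truth


def iou(a, b):
    return (a & b).sum() / (a | b).sum()


def test_segment_recovers_exact_disk(background, rng):
    """A perfectly circular drop of radius 80 drawn onto the real background
    is recovered within 2 px at every angle."""
    img = background.background(1).copy()
    yy, xx = np.mgrid[0:256, 0:256].astype(float)
    r = np.hypot(yy - 128, xx - 128)
    img[r <= 80] -= 60.0
    img += rng.normal(0, 2, img.shape)
    reg = register_well(img, background.background(1), max_shift=4)
    b = segment_droplet(
        img, reg, background.background(1), background.frame_mask(1)
    )
    assert b is not None
    theta = np.deg2rad(np.arange(360))
    rr = b.centre[0] + b.radius_by_degree * np.sin(theta)
    cc = b.centre[1] + b.radius_by_degree * np.cos(theta)
    assert np.abs(np.hypot(rr - 128, cc - 128) - 80).max() <= 2.0


def test_segment_ignores_well_frame(background):
    """A drop touching the frame must not lock onto the frame edges."""
    spec = FixtureSpec("crystal", 202, centre=(98.0, 128.0), radius=95.0)
    b, truth = _segment(background, spec)
    assert b is not None
    assert iou(b.mask, truth.droplet_mask) > 0.85
    frame = background.frame_mask(1)
    assert (b.mask & frame).sum() / b.mask.sum() < 0.05


def test_fallback_rescues_dark_precipitate_mass(background):
    """A weak-rimmed drop with a large dark mass defeats the first pass;
    the gamma-corrected retry recovers the true boundary."""
    spec = FixtureSpec(
        "precipitate",
        948,
        rim_depth=12,
        texture={"strength": 0.3, "clump": 0.055, "clump_soft": 2.5},
    )
    b, truth = _segment(background, spec)
    assert b is not None
    assert b.used_fallback == "gamma"
    assert iou(b.mask, truth.droplet_mask) > 0.9


def test_boundary_properties_populated(background):
    b, truth = _segment(background, FixtureSpec("clear", 21))
    assert b.area > 0
    assert 0 <= b.eccentricity < 1
    assert b.major_axis >= b.minor_axis > 0
    assert len(b.radius_by_degree) == 360
    assert (b.radius_by_degree > 0).all()
    df = b.radii_frame()
    assert list(df.columns) == ["degree", "radius"]
    assert len(df) == 360
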