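"""Generator contracts: determinism, exact leak accounting, ground truth."""

import numpy as np
import pytest

from gliavasc import (
    CellSpec,
    NoiseSpec,
    SceneConfig,
    generate_scene,
    generate_timelapse,
    process_motility,
)
from gliavasc.errors import SceneError


def test_same_seed_is_bit_identical():
    cfg = SceneConfig(seed=7, cells=CellSpec(count=4),
                      noise=NoiseSpec.default_on())
    a, _ = generate_scene(cfg)
    b, _ = generate_scene(cfg)
    assert np.array_equal(a.data, b.data)


def test_different_seed_differs():
    a, _ = generate_scene(SceneConfig(seed=1, noise=NoiseSpec.default_on()))
    b, _ = generate_scene(SceneConfig(seed=2, noise=NoiseSpec.default_on()))
    assert not np.array_equal(a.data, b.data)


def test_no_cells_yields_empty_truth_and_flat_reporter():
    cfg = SceneConfig(cells=CellSpec(count=0))
    stack, truth = generate_scene(cfg)
    assert truth.cells == []
    assert np.all(stack.channel("microglia") == cfg.background)


def test_zero_leak_background_exact_outside_tube():
    cfg = SceneConfig(cells=CellSpec(count=0),
                      leak_fraction_per_channel={70: 0.0})
    stack, truth = generate_scene(cfg)
    chan = stack.channel("dextran_70kDa")
    lumen2d = truth.projected_vessel_mask()
    # everything outside the (generously dilated) tube is pure background
    from scipy import ndimage as ndi

    dilated = ndi.binary_dilation(lumen2d, iterations=3)
    outside = ~np.broadcast_to(dilated, chan.shape)
    assert np.all(chan[outside] == cfg.background)


@pytest.mark.parametrize("fraction", [0.1, 0.3, 0.9])
def test_leak_integral_matches_configured_fraction(fraction):
    """Extravascular / intravascular integral equals the leak fraction."""
    cfg = SceneConfig(field_size_px=(256, 256), cells=CellSpec(count=0),
                      leak_fraction_per_channel={10: fraction})
    stack, truth = generate_scene(cfg)
    chan = stack.channel("dextran_10kDa") - cfg.background
    # independent reconstruction of the tube interior from the geometry
    v = truth.vessels[0]
    zz = (np.arange(cfg.n_z) - v.center_z_index)[:, None, None] * cfg.z_step_um
    yy = (np.arange(cfg.field_size_px[0])[None, :, None]
          - v.center_y_px) * cfg.pixel_size_um
    inside = np.broadcast_to(
        np.sqrt(zz ** 2 + yy ** 2) <= v.radius_um, chan.shape)
    ratio = chan[~inside].sum() / chan[inside].sum()
    assert ratio == pytest.approx(fraction, rel=0.01)


def test_contact_flags_are_thresholded_gaps():
    gaps = (0.0, 0.5, 2.0, 5.0)
    _, truth = generate_scene(SceneConfig(cells=CellSpec(count=4, gaps_um=gaps)))
    assert [c.gap_um for c in truth.cells] == list(gaps)
    assert [c.contact for c in truth.cells] == [g < 1.0 for g in gaps]
    assert sum(c.contact for c in truth.cells) == 2


def test_default_gap_population_hits_contact_fraction():
    cfg = SceneConfig(field_size_px=(512, 512), seed=11,
                      cells=CellSpec(count=20, n_processes=0,
                                     contact_fraction=0.2))
    _, truth = generate_scene(cfg)
    assert sum(c.contact for c in truth.cells) == 4


@pytest.mark.parametrize("bad", [-0.1, 1.5])
def test_invalid_leak_fraction_rejected(bad):
    with pytest.raises(SceneError):
        generate_scene(SceneConfig(leak_fraction_per_channel={10: bad}))


def test_unfittable_cells_rejected():
    # a 9 um gap on a 64 px (16 um) field cannot host soma + vessel
    cfg = SceneConfig(field_size_px=(64, 64),
                      cells=CellSpec(count=1, gaps_um=(9.0,)))
    with pytest.raises(SceneError):
        generate_scene(cfg)


def test_crowded_field_rejected():
    cfg = SceneConfig(field_size_px=(128, 128),
                      cells=CellSpec(count=12, gaps_um=(2.0,) * 12))
    with pytest.raises(SceneError):
        generate_scene(cfg)


# -- time-lapse --------------------------------------------------------------

def test_static_timelapse_frames_identical():
    cfg = SceneConfig(seed=3, cells=CellSpec(count=2, gaps_um=(3.0, 5.0)))
    stack, truth = generate_timelapse(cfg, n_frames=4)
    for t in range(1, 4):
        assert np.array_equal(stack.data[:, t], stack.data[:, 0])
    assert truth.shifts_px == [(0, 0)] * 4


def test_recorded_shifts_within_jitter_bound():
    cfg = SceneConfig(seed=5, cells=CellSpec(count=2, gaps_um=(3.0, 5.0)))
    _, truth = generate_timelapse(cfg, n_frames=8, jitter_px=4)
    assert truth.shifts_px[0] == (0, 0)
    assert all(abs(dy) <= 4 and abs(dx) <= 4 for dy, dx in truth.shifts_px)


def test_cumulative_tip_path_length():
    """A tip moved 0.5 um/frame over 5 frames travels 2.0 um in total."""
    cfg = SceneConfig(seed=3, cells=CellSpec(count=1, gaps_um=(4.0,)))
    stack, truth = generate_timelapse(cfg, n_frames=5,
                                      motility_um_per_frame=0.5)
    assert truth.tip_step_um_per_frame == 0.5
    mots = process_motility(stack.channel("microglia"), cfg.pixel_size_um)
    moving = max(mots)
    assert moving * 4 == pytest.approx(2.0, abs=0.4)


def test_timelapse_validation():
    cfg = SceneConfig(cells=CellSpec(count=1, gaps_um=(3.0,)))
    with pytest.raises(SceneError):
        generate_timelapse(cfg, n_frames=1)
    with pytest.raises(SceneError):
        generate_timelapse(cfg, n_frames=3, jitter_px=400)
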