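"""Profile-gap contact classification and Pearson colocalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliavasc import (
    AnalysisConfig,
    CellSpec,
    NoiseSpec,
    Profile,
    SceneConfig,
    call_contact_for_cell,
    classify_contact,
    extract_profile,
    generate_scene,
    pearson_coloc,
    vessel_associated_fraction,
    vessel_mask,
    z_project_max,
)
from gliavasc.errors import IndeterminateContactError, ZeroVarianceError

PX = 0.25


# -- profile extraction ------------------------------------------------------

def test_horizontal_segment_sample_count():
    img = np.arange(400, dtype=float).reshape(20, 20)
    prof = extract_profile(img, img, (5.0, 3.0), (5.0, 13.0), PX)
    assert prof.green.size == 11  # 10 px span -> 11 samples
    assert np.array_equal(prof.green, img[5, 3:14])


def test_profile_of_constant_image_is_constant():
    img = np.full((20, 20), 4.0)
    prof = extract_profile(img, img, (2.0, 2.0), (15.0, 17.0), PX)
    assert np.all(prof.green == 4.0) and np.all(prof.red == 4.0)


def test_identical_points_rejected():
    img = np.zeros((10, 10))
    with pytest.raises(ValueError):
        extract_profile(img, img, (3.0, 3.0), (3.0, 3.0), PX)


def test_profile_peaks_at_soma_and_decays(canonical_scene, canonical_channels):
    _cfg, _stack, truth = canonical_scene
    cell = truth.cells[3]  # 5 um gap
    green = canonical_channels["microglia"]
    red = canonical_channels["dextran_70kDa"]
    vy = truth.vessels[0].center_y_px
    prof = extract_profile(green, red, cell.center_zyx_px[1:],
                           (vy, cell.center_zyx_px[2]), PX)
    assert prof.green[0] == prof.green.max()
    assert prof.green[-1] < prof.green[0]


# -- gap rule ----------------------------------------------------------------

def _step_profile(green_zero_at, red_rise_at, n=25):
    green = np.where(np.arange(n) < green_zero_at, 100.0, 0.0)
    red = np.where(np.arange(n) >= red_rise_at, 100.0, 0.0)
    return Profile(green=green, red=red, pixel_size_um=0.254)


@pytest.mark.parametrize("rise,expected_gap,expected_contact", [
    (13, 3, True),    # gap 3 px, below 4 px -> contact
    (14, 4, False),   # gap exactly 4 px -> strictly not a contact
    (8, -2, True),    # red rises before green decays -> overlap
])
def test_gap_rule_on_synthetic_steps(rise, expected_gap, expected_contact):
    call = classify_contact(_step_profile(10, rise))
    assert call.gap_px == expected_gap
    assert call.is_contact is expected_contact


def test_verdict_flips_exactly_at_four_pixels():
    verdicts = [classify_contact(_step_profile(10, 10 + g)).is_contact
                for g in range(1, 7)]
    assert verdicts == [g < 4 for g in range(1, 7)]


def test_indeterminate_profile_raises():
    prof = Profile(green=np.full(20, 80.0), red=np.zeros(20),
                   pixel_size_um=PX)
    with pytest.raises(IndeterminateContactError):
        classify_contact(prof)


def test_noise_free_scene_calls_match_ground_truth(canonical_scene,
                                                   canonical_channels):
    cfg, _stack, truth = canonical_scene
    green = canonical_channels["microglia"]
    red = canonical_channels["dextran_70kDa"]
    vm = vessel_mask(red, cfg.pixel_size_um)
    for cell in truth.cells:
        call = call_contact_for_cell(green, red, cell.center_zyx_px[1:],
                                     vm.mask, cfg.pixel_size_um,
                                     cell_id=cell.cell_id)
        assert call.is_contact == cell.contact, f"gap {cell.gap_um} um"


def test_noisy_scene_agreement_at_least_95pct():
    cfg_a = AnalysisConfig()
    agree = total = 0
    for seed in (0, 1):
        cfg = SceneConfig(field_size_px=(512, 512), seed=seed,
                          cells=CellSpec(count=25, n_processes=0,
                                         gaps_um=(0.0, 0.5, 2.0, 5.0) * 6 + (3.0,)),
                          noise=NoiseSpec.default_on())
        stack, truth = generate_scene(cfg)
        chan = dict(zip(stack.channel_labels, z_project_max(stack)))
        vm = vessel_mask(chan["dextran_70kDa"], cfg.pixel_size_um)
        for cell in truth.cells:
            call = call_contact_for_cell(
                chan["microglia"], chan["dextran_70kDa"],
                cell.center_zyx_px[1:], vm.mask, cfg.pixel_size_um, cfg_a)
            agree += call.is_contact == cell.contact
            total += 1
    assert agree / total >= 0.95


# -- fraction ----------------------------------------------------------------

def _call(contact):
    from gliavasc import ContactCall

    return ContactCall(cell_id=0, green_zero_index=0, red_rise_index=0,
                       gap_px=0.0, gap_um=0.0, is_contact=contact)


def test_fraction_arithmetic():
    calls = [_call(True)] * 3 + [_call(False)] * 7
    assert vessel_associated_fraction(calls, 10) == pytest.approx(0.30)
    assert vessel_associated_fraction([_call(True)] * 4, 4) == 1.0


def test_fraction_rejects_empty_or_inconsistent():
    with pytest.raises(ValueError):
        vessel_associated_fraction([], 0)
    with pytest.raises(ValueError):
        vessel_associated_fraction([_call(True)] * 3, 2)


def test_twenty_percent_construction_recovered():
    """A field built with 20% of cells at sub-micron gaps reports ~0.20."""
    cfg = SceneConfig(field_size_px=(512, 512), seed=4,
                      cells=CellSpec(count=20, n_processes=0,
                                     contact_fraction=0.2))
    stack, truth = generate_scene(cfg)
    chan = dict(zip(stack.channel_labels, z_project_max(stack)))
    vm = vessel_mask(chan["dextran_70kDa"], cfg.pixel_size_um)
    calls = [call_contact_for_cell(chan["microglia"], chan["dextran_70kDa"],
                                   c.center_zyx_px[1:], vm.mask,
                                   cfg.pixel_size_um, cell_id=c.cell_id)
             for c in truth.cells]
    frac = vessel_associated_fraction(calls, 20)
    assert abs(frac - 0.20) <= 1 / 20  # within one cell


# -- Pearson colocalization --------------------------------------------------

def test_pearson_perfect_and_anti_correlation():
    rng = np.random.default_rng(0)
    a = rng.uniform(0, 100, (40, 40))
    assert pearson_coloc(a, a) == pytest.approx(1.0)
    assert pearson_coloc(a, -2.0 * a + 7.0) == pytest.approx(-1.0)


def test_pearson_independent_noise_near_zero():
    rng = np.random.default_rng(1)
    a = rng.normal(size=(100, 100))
    b = rng.normal(size=(100, 100))
    assert abs(pearson_coloc(a, b)) < 0.05


def test_pearson_respects_roi():
    a = np.zeros((10, 10))
    b = np.zeros((10, 10))
    a[:5], b[:5] = np.arange(50).reshape(5, 10), np.arange(50).reshape(5, 10)
    roi = np.zeros((10, 10), bool)
    roi[:5] = True
    assert pearson_coloc(a, b, roi) == pytest.approx(1.0)


def test_pearson_zero_variance_rejected():
    with pytest.raises(ZeroVarianceError):
        pearson_coloc(np.ones((5, 5)), np.arange(25.0).reshape(5, 5))


@settings(deadline=None, max_examples=20, derandomize=True)
@given(gain=st.floats(0.1, 50), offset=st.floats(-100, 100))
def test_pearson_invariant_under_positive_affine_rescaling(gain, offset):
    rng = np.random.default_rng(7)
    a = rng.uniform(0, 50, (30, 30))
    b = a + rng.normal(0, 10, (30, 30))
    r0 = pearson_coloc(a, b)
    r1 = pearson_coloc(a, gain * b + offset)
    assert r1 == pytest.approx(r0, abs=1e-8)
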