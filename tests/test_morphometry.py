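"""Morphometry, puncta rules, pericyte coverage and motility recovery."""

import numpy as np
import pytest

from gliavasc import (
    CellSpec,
    PunctaSpec,
    SceneConfig,
    detect_cells,
    generate_scene,
    generate_timelapse,
    pericyte_coverage,
    process_motility,
    puncta_positivity,
    register_translation,
    soma_area,
    trace_processes,
    z_project_max,
)
from gliavasc.errors import EmptyMaskError
from conftest import match_truth_cell

PX = 0.25


def _single_cell(process_length=20.0, soma_radius=3.0, seed=2):
    cfg = SceneConfig(seed=seed,
                      cells=CellSpec(count=1, gaps_um=(4.0,),
                                     process_length_um=process_length,
                                     soma_radius_um=soma_radius))
    stack, truth = generate_scene(cfg)
    rep = z_project_max(stack)[0]
    return detect_cells(rep, PX)[0], truth


def test_four_straight_processes_of_20um():
    dc, _ = _single_cell(20.0)
    n, lengths = trace_processes(dc.cell_mask, dc.soma_mask, PX)
    assert n == 4
    assert all(abs(l - 20.0) <= 1.0 for l in lengths)


def test_soma_only_cell_has_no_processes():
    soma = np.zeros((40, 40), bool)
    yy, xx = np.mgrid[:40, :40]
    soma[(yy - 20) ** 2 + (xx - 20) ** 2 <= 100] = True
    n, lengths = trace_processes(soma, soma, PX)
    assert (n, lengths) == (0, [])


def test_lengths_invariant_under_translation():
    dc, _ = _single_cell(20.0)
    n0, l0 = trace_processes(dc.cell_mask, dc.soma_mask, PX)
    cell = np.roll(dc.cell_mask, (7, -11), axis=(0, 1))
    soma = np.roll(dc.soma_mask, (7, -11), axis=(0, 1))
    n1, l1 = trace_processes(cell, soma, PX)
    assert n1 == n0
    assert sorted(l0) == pytest.approx(sorted(l1))


def test_empty_cell_mask_rejected():
    with pytest.raises(EmptyMaskError):
        trace_processes(np.zeros((10, 10), bool), np.zeros((10, 10), bool), PX)


# -- soma area ---------------------------------------------------------------

def test_soma_area_arithmetic():
    mask = np.zeros((20, 20), bool)
    mask[:10, :10] = True  # 100 px
    assert soma_area(mask, 0.5) == pytest.approx(25.0)


def test_rendered_disk_area_close_to_pi_r_squared():
    dc, _ = _single_cell(soma_radius=5.0)
    assert soma_area(dc.soma_mask, PX) == pytest.approx(np.pi * 25.0, abs=3.0)


def test_soma_area_increases_with_radius():
    small, _ = _single_cell(soma_radius=2.5, seed=4)
    large, _ = _single_cell(soma_radius=4.0, seed=4)
    assert soma_area(large.soma_mask, PX) > soma_area(small.soma_mask, PX)


# -- puncta ------------------------------------------------------------------

@pytest.mark.parametrize("count,positive", [(3, True), (2, False), (0, False)])
def test_cd68_puncta_rule(count, positive):
    cfg = SceneConfig(seed=1, cells=CellSpec(count=1, gaps_um=(3.0,)),
                      puncta=PunctaSpec(counts_per_cell=(count,)))
    stack, truth = generate_scene(cfg)
    chan = dict(zip(stack.channel_labels, z_project_max(stack)))
    dc = detect_cells(chan["microglia"], PX)[0]
    n, pos = puncta_positivity(dc.cell_mask, chan["puncta"], PX)
    assert n == count
    assert pos is positive


def test_puncta_counts_recovered_across_cells():
    counts = (4, 1, 3)
    cfg = SceneConfig(field_size_px=(448, 448), seed=6,
                      cells=CellSpec(count=3, gaps_um=(2.0, 3.0, 4.0)),
                      puncta=PunctaSpec(counts_per_cell=counts))
    stack, truth = generate_scene(cfg)
    chan = dict(zip(stack.channel_labels, z_project_max(stack)))
    for dc in detect_cells(chan["microglia"], PX):
        ct = match_truth_cell(dc, truth)
        n, pos = puncta_positivity(dc.cell_mask, chan["puncta"], PX)
        assert n == ct.puncta_count
        assert pos is (ct.puncta_count > 2)


def test_aqp4_inclusion_variant_any_punctum_counts():
    cfg = SceneConfig(seed=1, cells=CellSpec(count=1, gaps_um=(3.0,)),
                      puncta=PunctaSpec(counts_per_cell=(1,)))
    stack, _ = generate_scene(cfg)
    chan = dict(zip(stack.channel_labels, z_project_max(stack)))
    dc = detect_cells(chan["microglia"], PX)[0]
    n, included = puncta_positivity(dc.cell_mask, chan["puncta"], PX,
                                    count_threshold=0)
    assert (n, included) == (1, True)


def test_puncta_empty_cell_rejected():
    with pytest.raises(EmptyMaskError):
        puncta_positivity(np.zeros((10, 10), bool), np.zeros((10, 10)), PX)


# -- pericyte coverage -------------------------------------------------------

def test_coverage_extremes():
    vessel = np.zeros((50, 50), bool)
    vessel[20:30, :] = True
    assert pericyte_coverage(np.ones((50, 50), bool), vessel) == 100.0
    assert pericyte_coverage(~vessel, vessel) == 0.0


def test_half_covered_tube():
    vessel = np.zeros((60, 80), bool)
    vessel[25:35, :] = True
    marker = np.zeros((60, 80), bool)
    marker[:, :40] = True  # left half of the field
    assert pericyte_coverage(marker, vessel) == pytest.approx(50.0, abs=2.0)


def test_empty_vessel_surface_rejected():
    with pytest.raises(EmptyMaskError):
        pericyte_coverage(np.ones((5, 5), bool), np.zeros((5, 5), bool))


# -- motility ----------------------------------------------------------------

def test_static_cell_zero_motility():
    cfg = SceneConfig(seed=3, cells=CellSpec(count=1, gaps_um=(4.0,)))
    stack, _ = generate_timelapse(cfg, n_frames=4)
    mots = process_motility(stack.channel("microglia"), PX)
    assert max(mots) == 0.0


def test_moving_tip_recovered_within_tolerance():
    cfg = SceneConfig(seed=3, cells=CellSpec(count=1, gaps_um=(4.0,)))
    stack, truth = generate_timelapse(cfg, n_frames=6,
                                      motility_um_per_frame=0.5)
    mots = process_motility(stack.channel("microglia"), PX)
    assert max(mots) == pytest.approx(0.5, abs=0.1)


def test_motility_invariant_to_registered_jitter():
    """Jitter removed by registration does not change the motility readout."""
    cfg = SceneConfig(seed=3, cells=CellSpec(count=1, gaps_um=(4.0,)))
    still, _ = generate_timelapse(cfg, n_frames=6,
                                  motility_um_per_frame=0.5)
    shaky, _ = generate_timelapse(cfg, n_frames=6, jitter_px=6,
                                  motility_um_per_frame=0.5)
    aligned, _rec = register_translation(shaky.channel("microglia"))
    m_still = max(process_motility(still.channel("microglia"), PX))
    m_shaky = max(process_motility(aligned, PX))
    assert m_shaky == pytest.approx(m_still, abs=0.1)


def test_motility_requires_tips():
    with pytest.raises(EmptyMaskError):
        process_motility(np.zeros((3, 20, 20)), PX, threshold=0.5)
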