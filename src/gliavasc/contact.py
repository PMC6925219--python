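"""Vessel-associated-microglia calls from dual-channel line profiles.

A cell is classified by drawing a line from its presumed center to the
nearest vessel surface, reading both fluorescence channels along that line,
subtracting each profile's own standard deviation from its samples (clamping
at zero), and measuring the pixel distance between the point where the
microglial (green) signal falls to zero and the point where the vessel (red)
signal rises from zero.  A gap strictly below 1 um (4 px at 0.254 um/px)
calls the cell vessel-associated; overlap (gap <= 0) is always a contact.

Also provides the Pearson colocalization coefficient over an ROI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy import stats

from .config import AnalysisConfig
from .errors import EmptyMaskError, IndeterminateContactError, ZeroVarianceError


@dataclass
class Profile:
    """Intensity samples from cell center toward the vessel, per channel."""

    green: np.ndarray
    red: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green, dtype=float)
        self.red = np.asarray(self.red, dtype=float)
        if self.green.ndim != 1 or self.green.shape != self.red.shape:
            raise ValueError("green and red must be 1-D and equally long")
        if self.green.size < 2:
            raise ValueError("a profile needs at least 2 samples")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")


@dataclass
class ContactCall:
    cell_id: int
    green_zero_index: int | None
    red_rise_index: int | None
    gap_px: float
    gap_um: float
    is_contact: bool


def extract_profile(green_img: np.ndarray, red_img: np.ndarray,
                    cell_center: tuple[float, float],
                    vessel_point: tuple[float, float],
                    pixel_size_um: float) -> Profile:
    """Sample both channels at unit-pixel steps along a straight segment.

    Nearest-pixel sampling (no interpolation), so a segment of Euclidean
    length L px yields ``round(L) + 1`` samples and measured gaps are
    integers in pixels.
    """
    (y0, x0), (y1, x1) = cell_center, vessel_point
    if (y0, x0) == (y1, x1):
        raise ValueError("cell center and vessel point must differ")
    length = float(np.hypot(y1 - y0, x1 - x0))
    n = int(round(length))
    ts = np.linspace(0.0, 1.0, n + 1)
    ys = np.clip(np.rint(y0 + ts * (y1 - y0)).astype(int), 0,
                 green_img.shape[0] - 1)
    xs = np.clip(np.rint(x0 + ts * (x1 - x0)).astype(int), 0,
                 green_img.shape[1] - 1)
    return Profile(green=np.asarray(green_img, float)[ys, xs],
                   red=np.asarray(red_img, float)[ys, xs],
                   pixel_size_um=pixel_size_um)


def _first_zero_run(adjusted: np.ndarray) -> int | None:
    """First index where the signal is zero and stays zero for >= 1 step."""
    zero = adjusted == 0
    for i in range(zero.size):
        if zero[i] and (i + 1 >= zero.size or zero[i + 1]):
            return i
    return None


def classify_contact(profile: Profile, config: AnalysisConfig | None = None,
                     cell_id: int = 0) -> ContactCall:
    """Apply the profile-gap rule to one cell.

    Per channel, the profile's own standard deviation is subtracted from
    every sample and negatives are clamped to zero.  Walking from the cell
    toward the vessel, ``green_zero_index`` is the first point where the
    adjusted microglial signal has fallen to zero (and stays there for at
    least one further step), and ``red_rise_index`` the first point where
    the adjusted vessel signal exceeds zero.  The gap is their difference;
    a gap <= 0 (signals overlap) is a contact, and a positive gap calls a
    contact only when it is strictly below the criterion distance.
    """
    config = config or AnalysisConfig()
    g = np.clip(profile.green - profile.green.std(), 0.0, None)
    r = np.clip(profile.red - profile.red.std(), 0.0, None)
    green_zero = _first_zero_run(g)
    rise = np.nonzero(r > 0)[0]
    red_rise = int(rise[0]) if rise.size else None

    n = g.size
    if green_zero is None and red_rise is None:
        raise IndeterminateContactError(
            "green never extinguishes and red never rises")
    if green_zero is None:
        # microglial signal persists into the vessel: overlap
        gap_px = float(red_rise - (n - 1))
    elif red_rise is None:
        # vessel signal absent along the profile: gap at least to the end
        gap_px = float((n - 1) - green_zero)
        gap_px = max(gap_px, config.contact_gap_um / profile.pixel_size_um)
    else:
        gap_px = float(red_rise - green_zero)
    gap_um = gap_px * profile.pixel_size_um
    is_contact = gap_px <= 0 or gap_um < config.contact_gap_um
    return ContactCall(cell_id=cell_id, green_zero_index=green_zero,
                       red_rise_index=red_rise, gap_px=gap_px,
                       gap_um=gap_um, is_contact=is_contact)


def call_contact_for_cell(green_img: np.ndarray, red_img: np.ndarray,
                          soma_centroid: tuple[float, float],
                          vessel_mask: np.ndarray, pixel_size_um: float,
                          config: AnalysisConfig | None = None,
                          cell_id: int = 0,
                          overshoot_px: int = 8) -> ContactCall:
    """Full per-cell call: pick the vessel point, extract, classify.

    The line runs from the soma centroid to the nearest vessel-mask pixel
    (a deterministic surrogate for the manually drawn line) and overshoots
    it by ``overshoot_px`` so the profile crosses the vessel wall into the
    lumen — otherwise the red channel would contribute only border pixels
    and its standard deviation would not suppress the background.  A
    centroid lying inside the vessel mask is a contact with gap 0.
    """
    config = config or AnalysisConfig()
    vm = np.asarray(vessel_mask, bool)
    if not vm.any():
        raise EmptyMaskError("vessel mask is empty")
    iy, ix = int(round(soma_centroid[0])), int(round(soma_centroid[1]))
    if vm[iy, ix]:
        return ContactCall(cell_id=cell_id, green_zero_index=0,
                           red_rise_index=0, gap_px=0.0, gap_um=0.0,
                           is_contact=True)
    _dist, (ny_idx, nx_idx) = ndi.distance_transform_edt(
        ~vm, return_indices=True)
    ty, tx = float(ny_idx[iy, ix]), float(nx_idx[iy, ix])
    norm = float(np.hypot(ty - iy, tx - ix))
    end = (ty + overshoot_px * (ty - iy) / norm,
           tx + overshoot_px * (tx - ix) / norm)
    prof = extract_profile(green_img, red_img, (float(iy), float(ix)),
                           end, pixel_size_um)
    return classify_contact(prof, config, cell_id=cell_id)


def vessel_associated_fraction(calls: Sequence[ContactCall],
                               n_cells_in_field: int | None = None) -> float:
    """Share of microglia in the field classified as vessel-associated."""
    if n_cells_in_field is None:
        n_cells_in_field = len(calls)
    if n_cells_in_field <= 0 or len(calls) == 0:
        raise ValueError("need at least one cell")
    if n_cells_in_field < len(calls):
        raise ValueError("n_cells_in_field smaller than number of calls")
    return sum(c.is_contact for c in calls) / n_cells_in_field


def pearson_coloc(ch1: np.ndarray, ch2: np.ndarray,
                  roi: np.ndarray | None = None) -> float:
    """Pearson correlation of paired pixel intensities within an ROI.

    The standard (unthresholded) colocalization coefficient in [-1, 1].
    """
    ch1, ch2 = np.asarray(ch1, float), np.asarray(ch2, float)
    if ch1.shape != ch2.shape:
        raise ValueError("channel shapes differ")
    if roi is None:
        a, b = ch1.ravel(), ch2.ravel()
    else:
        roi = np.asarray(roi, bool)
        a, b = ch1[roi], ch2[roi]
    if a.size < 2:
        raise ZeroVarianceError("need at least 2 ROI pixels")
    if a.std() == 0 or b.std() == 0:
        raise ZeroVarianceError("a channel is constant inside the ROI")
    return float(stats.pearsonr(a, b).statistic)
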