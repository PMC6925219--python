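"""Analysis configuration: the fixed quantification parameters.

All stage functions take an :class:`AnalysisConfig` so a whole run is
reproducible from one YAML file.  Defaults are the values the quantification
protocol fixes: a 40 um^2 minimum particle area for vessel delineation, a
1 um (4 px at 0.254 um/px) microglia-vessel contact gap, the >2-puncta CD68
positivity rule, 2 um z-steps with 10-slice maximum-intensity projections,
and the 100-200 um cortical depth window (layer II/III, below the two
superficial 50 um sections).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters shared across all quantification stages.

    Parameters
    ----------
    min_particle_area_um2 : float
        Smallest connected component (um^2) kept in a vessel mask; the
        filter is inclusive ("40-Infinity").
    contact_gap_um : float
        A microglia is vessel-associated when the profile gap between the
        green-extinction point and the red-rise point is strictly below
        this distance (1 um, i.e. 4 px at 0.254 um/px).
    cd68_count_threshold : int
        A cell is CD68-positive when its puncta count strictly exceeds
        this value (more than two puncta).
    projection_slices : int
        Number of z-slices combined in a maximum-intensity projection.
    z_step_um : float
        Axial spacing between focal planes.
    depth_window_um : tuple of float
        Half-open [lower, upper) cortical depth window analysed, in um
        from the pia.
    normalization_reference : str
        ``"group"`` (normalize to a control group) or ``"baseline_day"``
        (normalize a time series to its pre-treatment baseline).
    histogram_bins : int
        Bins for maximum-entropy thresholding (8-bit ImageJ convention).
    mask_dilation_px : int
        Dilation applied to the vessel mask before the extravascular mean,
        to suppress border bleed.
    puncta_area_um2 : tuple of float
        Accepted connected-component area band for a punctum.
    tip_link_gate_um : float
        Maximum per-frame displacement allowed when linking process tips
        across time-lapse frames.
    seed : int
        Root seed for any stochastic stage.
    """

    min_particle_area_um2: float = 40.0
    contact_gap_um: float = 1.0
    cd68_count_threshold: int = 2
    projection_slices: int = 10
    z_step_um: float = 2.0
    depth_window_um: tuple[float, float] = (100.0, 200.0)
    normalization_reference: str = "group"
    histogram_bins: int = 256
    mask_dilation_px: int = 1
    puncta_area_um2: tuple[float, float] = (0.1, 5.0)
    tip_link_gate_um: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_particle_area_um2 <= 0:
            raise ValueError("min_particle_area_um2 must be positive")
        if self.contact_gap_um <= 0:
            raise ValueError("contact_gap_um must be positive")
        if self.cd68_count_threshold < 0:
            raise ValueError("cd68_count_threshold must be nonnegative")
        lo, hi = self.depth_window_um
        if not hi > lo:
            raise ValueError("depth window must be nondegenerate")
        if self.histogram_bins < 2:
            raise ValueError("histogram_bins must be >= 2")
        if self.normalization_reference not in ("group", "baseline_day"):
            raise ValueError(
                "normalization_reference must be 'group' or 'baseline_day'"
            )

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["depth_window_um"] = list(self.depth_window_um)
        d["puncta_area_um2"] = list(self.puncta_area_um2)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "depth_window_um" in d:
            d["depth_window_um"] = tuple(d["depth_window_um"])
        if "puncta_area_um2" in d:
            d["puncta_area_um2"] = tuple(d["puncta_area_um2"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Stable short hash identifying this parameter set in reports."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def contact_gap_px(self, pixel_size_um: float) -> float:
        """Gap criterion expressed in pixels at a given calibration."""
        return self.contact_gap_um / pixel_size_um
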