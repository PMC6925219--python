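"""Multi-channel image stacks with physical calibration.

The in-memory container for everything the pipeline touches: a 4-D array
indexed ``(channel, z, y, x)`` for z-stacks or ``(channel, t, y, x)`` for
time-lapses, together with the lateral pixel size, the axial step and
channel labels.  Stacks round-trip through multi-page TIFF with the
calibration and labels stored as JSON in the image description, so files
written by the simulator are self-describing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import CalibrationError, MissingChannelError


@dataclass
class ImageStack:
    """A calibrated multi-channel 3-D (or time-lapse) image.

    Parameters
    ----------
    data : ndarray
        Nonnegative intensities, shape ``(n_channels, n_z_or_t, ny, nx)``.
    pixel_size_um : float
        Lateral calibration, micrometres per pixel (y and x).
    z_step_um : float
        Axial spacing in micrometres (ignored for time-lapses).
    channel_labels : tuple of str
        Unique name per channel, e.g. ``("microglia", "dextran_70kDa")``.
    axes : str
        ``"CZYX"`` for a z-stack, ``"CTYX"`` for a time-lapse.
    """

    data: np.ndarray
    pixel_size_um: float
    z_step_um: float
    channel_labels: tuple[str, ...]
    axes: str = "CZYX"
    depth_offset_um: float = 0.0  # depth of slice 0 below the pia

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("stack data must be 4-D (channel, z/t, y, x)")
        if not (self.pixel_size_um > 0 and self.z_step_um > 0):
            raise CalibrationError("pixel size and z-step must be positive")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.axes not in ("CZYX", "CTYX"):
            raise ValueError("axes must be 'CZYX' or 'CTYX'")

    # -- accessors ---------------------------------------------------------

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_planes(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> np.ndarray:
        """Return the 3-D ``(z/t, y, x)`` array for a named channel."""
        try:
            i = self.channel_labels.index(label)
        except ValueError:
            raise MissingChannelError(
                f"channel {label!r} not in {self.channel_labels}"
            ) from None
        return self.data[i]

    def has_channel(self, label: str) -> bool:
        return label in self.channel_labels

    # -- persistence -------------------------------------------------------

    def to_tiff(self, path: str | Path) -> None:
        """Write as multi-page TIFF with a JSON sidecar description."""
        meta = {
            "axes": self.axes,
            "pixel_size_um": self.pixel_size_um,
            "z_step_um": self.z_step_um,
            "channel_labels": list(self.channel_labels),
            "depth_offset_um": self.depth_offset_um,
        }
        tifffile.imwrite(
            str(path),
            self.data.astype(np.float32),
            description=json.dumps(meta),
            photometric="minisblack",
        )

    @classmethod
    def from_tiff(cls, path: str | Path) -> "ImageStack":
        with tifffile.TiffFile(str(path)) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description
        try:
            meta = json.loads(desc)
            data = data.reshape(
                (len(meta["channel_labels"]), -1) + data.shape[-2:]
            )
            return cls(
                data=data,
                pixel_size_um=float(meta["pixel_size_um"]),
                z_step_um=float(meta["z_step_um"]),
                channel_labels=tuple(meta["channel_labels"]),
                axes=meta.get("axes", "CZYX"),
                depth_offset_um=float(meta.get("depth_offset_um", 0.0)),
            )
        except (TypeError, KeyError, AttributeError, json.JSONDecodeError):
            raise CalibrationError(
                f"{path}: no calibration metadata in TIFF description"
            ) from None
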