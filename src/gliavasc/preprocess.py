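"""Registration, maximum-intensity projection and depth-window selection.

These run before any quantification: time-lapses are corrected for lateral
drift by translation-only registration (cross-correlation maximization,
integer shifts by default), z-stacks are reduced by maximum-intensity
projection over a slice window, and only the 100-200 um cortical depth
band (layer II/III, below the two superficial 50 um sections) is analysed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.registration import phase_cross_correlation

from .errors import DepthWindowError, RegistrationError
from .stack import ImageStack


@dataclass
class ShiftRecord:
    """Estimated per-frame translation corrections ``(dy, dx)`` in pixels.

    The corrective shift is what must be applied to a frame to align it to
    the reference (frame 0), i.e. the negative of the drift the sample
    underwent.  The reference frame's entry is always (0, 0).
    """

    shifts_px: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if self.shifts_px and tuple(self.shifts_px[0]) != (0.0, 0.0):
            raise ValueError("reference frame shift must be (0, 0)")

    def applied_displacements(self) -> list[tuple[float, float]]:
        """The drift each frame had undergone (negated corrections)."""
        return [(-dy, -dx) for dy, dx in self.shifts_px]


def _image_mode(img: np.ndarray, bins: int = 256) -> float:
    """Most frequent intensity, via a histogram peak for float data."""
    lo, hi = float(img.min()), float(img.max())
    if lo == hi:
        return lo
    hist, edges = np.histogram(img, bins=bins, range=(lo, hi))
    k = int(np.argmax(hist))
    return 0.5 * (edges[k] + edges[k + 1])


def register_translation(frames: np.ndarray, subpixel: bool = False,
                         ) -> tuple[np.ndarray, ShiftRecord]:
    """Align a single-channel time-lapse ``(t, y, x)`` to its first frame.

    Shifts are estimated per frame by cross-correlation maximization
    against frame 0 and applied as pure translations; pixels shifted in
    from outside the field are filled with the frame's modal intensity so
    they do not bias extravascular statistics.

    Parameters
    ----------
    frames : ndarray, shape (t, y, x)
        At least two same-shaped frames.
    subpixel : bool
        When True, refine shifts to 1/10 px and interpolate; default off
        so repeated runs are bit-identical.

    Returns
    -------
    aligned : ndarray
        Registered frames.
    record : ShiftRecord
        Estimated corrective shifts, frame 0 first.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (t, y, x) array with >= 2 frames")
    for t, fr in enumerate(frames):
        if fr.max() == fr.min():
            raise RegistrationError(f"frame {t} is constant; unregistrable")

    from scipy import ndimage as ndi

    ref = frames[0]
    aligned = np.empty_like(frames)
    aligned[0] = ref
    shifts: list[tuple[float, float]] = [(0.0, 0.0)]
    upsample = 10 if subpixel else 1
    half = (frames.shape[1] // 2, frames.shape[2] // 2)
    for t in range(1, frames.shape[0]):
        shift, _err, _ = phase_cross_correlation(
            ref, frames[t], upsample_factor=upsample, normalization=None)
        dy, dx = float(shift[0]), float(shift[1])
        if abs(dy) > half[0] or abs(dx) > half[1]:  # pragma: no cover
            raise RegistrationError("estimated shift exceeds half the field")
        fill = _image_mode(frames[t])
        order = 1 if subpixel else 0
        aligned[t] = ndi.shift(frames[t], (dy, dx), order=order,
                               mode="constant", cval=fill)
        shifts.append((dy, dx))
    return aligned, ShiftRecord(shifts_px=shifts)


def z_project_max(stack: ImageStack, z_range: slice | tuple[int, int] | None = None,
                  ) -> np.ndarray:
    """Maximum-intensity projection per channel over a slice window.

    Returns an array of shape ``(n_channels, ny, nx)``.
    """
    if isinstance(z_range, tuple):
        z_range = slice(*z_range)
    if z_range is None:
        z_range = slice(0, stack.n_planes)
    sub = stack.data[:, z_range]
    if sub.shape[1] == 0:
        raise ValueError("empty z range")
    return sub.max(axis=1)


def select_depth_window(stack: ImageStack, pia_offset_um: float = 0.0,
                        window_um: tuple[float, float] = (100.0, 200.0),
                        ) -> ImageStack:
    """Keep the slices whose center depth lies in ``[lower, upper)`` um.

    Depth of slice i is ``pia_offset_um + i * z_step_um``.  The default
    window discards the two superficial 50 um sections (surgical-damage
    zone) and keeps the 100-200 um band.  Raises if the stack does not
    reach deep enough to cover the window.
    """
    lo, hi = window_um
    dz = stack.z_step_um
    depths = stack.depth_offset_um + pia_offset_um + np.arange(stack.n_planes) * dz
    idx = np.nonzero((depths >= lo) & (depths < hi))[0]
    expected = int(round((hi - lo) / dz))
    if len(idx) < expected:
        raise DepthWindowError(
            f"stack spans {depths[0]:.0f}-{depths[-1]:.0f} um from pia; "
            f"cannot cover the [{lo:.0f}, {hi:.0f}) um window"
        )
    return ImageStack(
        data=stack.data[:, idx[0]: idx[-1] + 1],
        pixel_size_um=stack.pixel_size_um,
        z_step_um=stack.z_step_um,
        channel_labels=stack.channel_labels,
        axes=stack.axes,
        depth_offset_um=float(depths[idx[0]]),
    )
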