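"""Synthetic two-photon-like phantoms with exact ground truth.

Renders the image content the in vivo protocol quantifies — bright tubular
vessels in the dextran channels, ramified microglia in the reporter channel
placed at controlled edge-to-edge gaps from the vessel wall, an extravascular
leak halo per dextran channel, intracellular puncta — plus time-lapses with
frame jitter and process-tip movement.  Every stochastic choice flows from
the scene seed, so a configuration renders bit-identically.

Geometry conventions: arrays are indexed ``(z, y, x)``, 0-based, with pixel
centers at integer coordinates.  Vessels run along x as straight cylinders
centered on the middle z-plane.  The per-channel leak halo decays
exponentially with distance from the vessel wall and is scaled so that its
integrated extravascular intensity equals ``leak_fraction`` times the
integrated intravascular intensity — the quantity the leakage index is
built to recover.

Microglial processes are straight tubes of ~0.75 px radius drawn at
multiples of 45 degrees, never toward the vessel, so that skeleton path
lengths are exact on the pixel lattice and the cell-to-vessel profile axis
stays unobstructed.  These are phantom choices, not claims about microglial
biology; see docs/methods.md.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import SceneError
from .stack import ImageStack

_SQ2 = np.sqrt(2.0)


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VesselSpec:
    """Straight cylindrical vessels running along x."""

    count: int = 1
    radius_um: float = 3.0
    orientation: str = "x"


@dataclass(frozen=True)
class CellSpec:
    """Microglia: spherical soma plus straight tapering processes.

    ``gaps_um`` lists the true edge-to-edge distance from each soma surface
    to the nearest vessel wall; when omitted, gaps are drawn so that
    ``contact_fraction`` of the cells sit closer than 1 um (the baseline
    proportion of vessel-associated microglia) and the remainder lie 2-8 um
    into the parenchyma.
    """

    count: int = 4
    soma_radius_um: float = 3.0
    n_processes: int = 4
    process_length_um: float = 10.0
    gaps_um: tuple[float, ...] | None = None
    contact_fraction: float = 0.2


@dataclass(frozen=True)
class PunctaSpec:
    """Intracellular puncta rendered in their own channel."""

    counts_per_cell: tuple[int, ...] = ()
    radius_um: float = 0.4
    intensity: float = 200.0


@dataclass(frozen=True)
class NoiseSpec:
    """Shot + read noise: Poisson(signal*gain)/gain then Gaussian(0, sd).

    Both default off so unit fixtures are exact; ``default_on`` gives the
    noise level used by the integration tests.
    """

    poisson_gain: float = 0.0
    gaussian_sd: float = 0.0

    @classmethod
    def default_on(cls) -> "NoiseSpec":
        return cls(poisson_gain=1.0, gaussian_sd=2.0)


@dataclass(frozen=True)
class SceneConfig:
    field_size_px: tuple[int, int] = (384, 384)
    n_z: int = 9
    pixel_size_um: float = 0.25
    z_step_um: float = 2.0
    vessel: VesselSpec = field(default_factory=VesselSpec)
    cells: CellSpec = field(default_factory=CellSpec)
    leak_fraction_per_channel: Mapping[int, float] = field(
        default_factory=lambda: {70: 0.0}
    )
    puncta: PunctaSpec | None = None
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    leak_length_um: float = 10.0
    background: float = 10.0
    vessel_intensity: float = 200.0
    soma_intensity: float = 150.0
    process_intensity: float = 80.0
    seed: int = 0

    def validate(self) -> None:
        ny, nx = self.field_size_px
        if ny <= 0 or nx <= 0 or self.n_z <= 0:
            raise SceneError("field dimensions must be positive")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise SceneError("calibration must be positive")
        for kda, f in self.leak_fraction_per_channel.items():
            if not (0.0 <= f <= 1.0):
                raise SceneError(
                    f"leak fraction for {kda} kDa must lie in [0, 1], got {f}"
                )
        if self.vessel.count < 1 or self.vessel.radius_um <= 0:
            raise SceneError("need at least one vessel of positive radius")
        if self.cells.count < 0:
            raise SceneError("cell count must be nonnegative")
        if self.cells.count and self.cells.gaps_um is not None:
            if len(self.cells.gaps_um) != self.cells.count:
                raise SceneError("gaps_um length must equal cell count")
            if any(g < 0 for g in self.cells.gaps_um):
                raise SceneError("gaps must be nonnegative")
        if not 0 <= self.cells.n_processes <= 5 and self.cells.count:
            raise SceneError("0-5 processes per cell supported")
        if self.puncta is not None and self.cells.count:
            if len(self.puncta.counts_per_cell) != self.cells.count:
                raise SceneError("puncta counts must match cell count")


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class VesselTruth:
    center_y_px: float
    center_z_index: int
    radius_um: float
    orientation: str = "x"


@dataclass
class CellTruth:
    cell_id: int
    center_zyx_px: tuple[float, float, float]
    gap_um: float
    contact: bool
    process_lengths_um: tuple[float, ...]
    puncta_count: int
    side: int  # +1 below the vessel (larger y), -1 above


@dataclass
class GroundTruth:
    """Everything the renderer did, recorded for downstream oracles."""

    vessels: list[VesselTruth]
    cells: list[CellTruth]
    leak_fraction_per_channel: dict[int, float]
    pixel_size_um: float
    z_step_um: float
    field_size_px: tuple[int, int]
    contact_criterion_um: float = 1.0
    shifts_px: list[tuple[int, int]] = field(default_factory=list)
    tip_step_um_per_frame: float = 0.0

    def projected_vessel_mask(self) -> np.ndarray:
        """True vessel lumen footprint on the maximum projection."""
        ny, nx = self.field_size_px
        yy = np.arange(ny)[:, None] * self.pixel_size_um
        mask = np.zeros((ny, nx), dtype=bool)
        for v in self.vessels:
            dy = np.abs(yy - v.center_y_px * self.pixel_size_um)
            mask |= np.broadcast_to(dy <= v.radius_um, (ny, nx))
        return mask

    def cells_table(self) -> pd.DataFrame:
        rows = [
            {
                "cell_id": c.cell_id,
                "z_px": c.center_zyx_px[0],
                "y_px": c.center_zyx_px[1],
                "x_px": c.center_zyx_px[2],
                "gap_um": c.gap_um,
                "contact": c.contact,
                "n_processes": len(c.process_lengths_um),
                "total_process_length_um": float(sum(c.process_lengths_um)),
                "puncta_count": c.puncta_count,
            }
            for c in self.cells
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "cell_id", "z_px", "y_px", "x_px", "gap_um", "contact",
                "n_processes", "total_process_length_um", "puncta_count",
            ],
        )


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------

def _paint_disk(canvas: np.ndarray, yc: float, xc: float, r_px: float,
                value: float) -> None:
    """Composite a filled disk into ``canvas`` by maximum."""
    ny, nx = canvas.shape
    y0, y1 = int(np.floor(yc - r_px)), int(np.ceil(yc + r_px)) + 1
    x0, x1 = int(np.floor(xc - r_px)), int(np.ceil(xc + r_px)) + 1
    y0, x0 = max(y0, 0), max(x0, 0)
    y1, x1 = min(y1, ny), min(x1, nx)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (yy - yc) ** 2 + (xx - xc) ** 2 <= r_px ** 2
    region = canvas[y0:y1, x0:x1]
    np.maximum(region, np.where(inside, value, 0.0), out=region)


def _paint_segment(canvas: np.ndarray, y0: float, x0: float, dy: float,
                   dx: float, length_px: float, r_px: float,
                   base_value: float, tip_value: float) -> None:
    """Draw a straight tapering tube from (y0,x0) along unit vector (dy,dx)."""
    n_steps = max(int(np.ceil(length_px / 0.4)), 1)
    for i in range(n_steps + 1):
        s = length_px * i / n_steps
        val = base_value + (tip_value - base_value) * (s / length_px)
        _paint_disk(canvas, y0 + dy * s, x0 + dx * s, r_px, val)


def _process_directions(n: int, side: int) -> list[tuple[float, float]]:
    """Unit (dy, dx) directions at 45-degree multiples, pointing away from
    the vessel (the vessel lies on the -side in y)."""
    away = float(side)
    dirs = [
        (0.0, 1.0),
        (0.0, -1.0),
        (away / _SQ2, 1.0 / _SQ2),
        (away / _SQ2, -1.0 / _SQ2),
        (away, 0.0),
    ]
    return dirs[:n]


def _default_gaps(n: int, contact_fraction: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Gap population with an exact share of sub-micron (contact) cells."""
    n_contact = int(round(contact_fraction * n))
    gaps = np.concatenate([
        rng.uniform(0.0, 0.5, size=n_contact),
        rng.uniform(2.0, 8.0, size=n - n_contact),
    ])
    rng.shuffle(gaps)
    return gaps


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

def _vessel_geometry(cfg: SceneConfig) -> list[VesselTruth]:
    ny, _ = cfg.field_size_px
    zc = cfg.n_z // 2
    # vessels evenly spaced in y
    centers = [(k + 1) * ny / (cfg.vessel.count + 1) for k in range(cfg.vessel.count)]
    return [VesselTruth(center_y_px=c, center_z_index=zc,
                        radius_um=cfg.vessel.radius_um) for c in centers]


def _vessel_distance_um(cfg: SceneConfig, vessels: list[VesselTruth]) -> np.ndarray:
    """Signed-free distance (um) from every voxel to the nearest vessel
    surface; negative inside replaced by 0 via the separate lumen mask."""
    ny, nx = cfg.field_size_px
    zz = (np.arange(cfg.n_z) - cfg.n_z // 2)[:, None] * cfg.z_step_um
    yy = np.arange(ny)[None, :] * cfg.pixel_size_um
    d = None
    for v in vessels:
        dy = yy - v.center_y_px * cfg.pixel_size_um
        dzy = np.sqrt(zz ** 2 + dy ** 2) - v.radius_um  # (n_z, ny)
        d = dzy if d is None else np.minimum(d, dzy)
    return np.broadcast_to(d[:, :, None], (cfg.n_z, ny, nx)).copy()


def _place_cells(cfg: SceneConfig, vessels: list[VesselTruth],
                 rng: np.random.Generator) -> list[CellTruth]:
    ny, nx = cfg.field_size_px
    spec = cfg.cells
    if spec.count == 0:
        return []
    if spec.gaps_um is not None:
        gaps = np.asarray(spec.gaps_um, dtype=float)
    else:
        gaps = _default_gaps(spec.count, spec.contact_fraction, rng)
    r_s = spec.soma_radius_um
    px = cfg.pixel_size_um
    zc = cfg.n_z // 2
    # x half-extent of one cell's footprint (soma + processes + tube width);
    # same-side cells are kept in disjoint x slots so neighboring processes
    # can never cross and merge two cells into one component
    r_s_px = r_s / px
    reach_px = (r_s + spec.process_length_um) / px
    dxs = [abs(dx) for _dy, dx in
           _process_directions(spec.n_processes, 1)] or [0.0]
    half_x = max(r_s_px, max(dxs) * reach_px) + 3
    margin_x = half_x + 2
    usable = nx - 2 * margin_x
    if usable <= 0:
        raise SceneError("field too narrow for the requested cells")
    # alternate sides of the (first) vessel, spread along x
    v = vessels[0]
    cells: list[CellTruth] = []
    n_per_side = (spec.count + 1) // 2
    slot = usable / max(n_per_side, 1)
    if slot < 2 * half_x and spec.count > 1:
        raise SceneError(
            "too many cells to fit without overlapping footprints")
    jitter_amp = 0.4 * max(0.0, slot - 2 * half_x)
    for i, g in enumerate(gaps):
        side = 1 if i % 2 == 0 else -1
        k = i // 2
        xc = margin_x + (k + 0.5) * slot + rng.uniform(-1.0, 1.0) * jitter_amp
        yc = v.center_y_px + side * (v.radius_um + g + r_s) / px
        if not (0 <= yc - r_s / px and yc + r_s / px < ny):
            raise SceneError(
                f"cell {i} at gap {g} um does not fit in the field"
            )
        cells.append(CellTruth(
            cell_id=i,
            center_zyx_px=(float(zc), float(yc), float(xc)),
            gap_um=float(g),
            contact=bool(g < 1.0),
            process_lengths_um=(spec.process_length_um,) * spec.n_processes,
            puncta_count=(cfg.puncta.counts_per_cell[i]
                          if cfg.puncta is not None else 0),
            side=side,
        ))
    return cells


def _render_reporter(cfg: SceneConfig, cells: list[CellTruth],
                     tip_extension_um: float = 0.0) -> np.ndarray:
    """Microglia reporter channel, background-free (composited by max)."""
    ny, nx = cfg.field_size_px
    px = cfg.pixel_size_um
    canvas3 = np.zeros((cfg.n_z, ny, nx), dtype=float)
    # ~3 px wide tubes (0.75 um diameter at 0.25 um/px); thinner diagonal
    # staircases are degenerate for skeletonization and lose their tips
    r_proc_px = 1.5
    for c in cells:
        zc, yc, xc = c.center_zyx_px
        r_s = cfg.cells.soma_radius_um
        # soma: sphere sampled per z-plane
        for iz in range(cfg.n_z):
            dz_um = (iz - zc) * cfg.z_step_um
            if abs(dz_um) > r_s:
                continue
            r_plane = np.sqrt(r_s ** 2 - dz_um ** 2) / px
            _paint_disk(canvas3[iz], yc, xc, r_plane, cfg.soma_intensity)
        # processes: central plane only, starting at the soma surface
        plane = canvas3[int(zc)]
        dirs = _process_directions(len(c.process_lengths_um), c.side)
        for j, ((dy, dx), L) in enumerate(zip(dirs, c.process_lengths_um)):
            L_eff = L + (tip_extension_um if j == 0 else 0.0)
            y0 = yc + dy * r_s / px
            x0 = xc + dx * r_s / px
            _paint_segment(plane, y0, x0, dy, dx, L_eff / px, r_proc_px,
                           cfg.process_intensity, 0.6 * cfg.process_intensity)
    return canvas3


def _render_dextran(cfg: SceneConfig, vessels: list[VesselTruth],
                    leak_fraction: float) -> np.ndarray:
    """One dextran channel: vessel tube plus a normalized leak halo."""
    dist = _vessel_distance_um(cfg, vessels)
    inside = dist <= 0
    chan = np.where(inside, cfg.vessel_intensity, 0.0)
    if leak_fraction > 0:
        halo = np.where(inside, 0.0, np.exp(-dist / cfg.leak_length_um))
        total_in = cfg.vessel_intensity * inside.sum()
        halo_sum = halo.sum()
        if halo_sum > 0:
            chan += halo * (leak_fraction * total_in / halo_sum)
    return chan


def _render_puncta(cfg: SceneConfig, cells: list[CellTruth],
                   rng: np.random.Generator) -> np.ndarray:
    ny, nx = cfg.field_size_px
    px = cfg.pixel_size_um
    canvas3 = np.zeros((cfg.n_z, ny, nx), dtype=float)
    assert cfg.puncta is not None
    r_px = cfg.puncta.radius_um / px
    for c in cells:
        zc, yc, xc = c.center_zyx_px
        plane = canvas3[int(zc)]
        placed: list[tuple[float, float]] = []
        r_max = 0.55 * cfg.cells.soma_radius_um / px
        for _ in range(c.puncta_count):
            for _attempt in range(200):
                rho = r_max * np.sqrt(rng.uniform())
                theta = rng.uniform(0, 2 * np.pi)
                py, qx = yc + rho * np.sin(theta), xc + rho * np.cos(theta)
                if all((py - a) ** 2 + (qx - b) ** 2 > (3 * r_px) ** 2
                       for a, b in placed):
                    placed.append((py, qx))
                    break
            else:  # pragma: no cover - dense packing fallback
                raise SceneError("could not place puncta without merging")
        for py, qx in placed:
            _paint_disk(plane, py, qx, r_px, cfg.puncta.intensity)
    return canvas3


def _apply_noise(data: np.ndarray, noise: NoiseSpec,
                 rng: np.random.Generator) -> np.ndarray:
    out = data.astype(float)
    if noise.poisson_gain > 0:
        out = rng.poisson(out * noise.poisson_gain) / noise.poisson_gain
    if noise.gaussian_sd > 0:
        out = out + rng.normal(0.0, noise.gaussian_sd, size=out.shape)
    return np.clip(out, 0.0, None)


def dextran_label(kda: int) -> str:
    return f"dextran_{kda}kDa"


def generate_scene(cfg: SceneConfig) -> tuple[ImageStack, GroundTruth]:
    """Render a multi-channel z-stack and its exact ground truth.

    Channels: ``microglia`` (reporter), one ``dextran_<size>kDa`` per entry
    of ``leak_fraction_per_channel`` and, when ``puncta`` is configured, a
    ``puncta`` channel.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    vessels = _vessel_geometry(cfg)
    cells = _place_cells(cfg, vessels, rng)

    channels: list[np.ndarray] = [_render_reporter(cfg, cells)]
    labels: list[str] = ["microglia"]
    for kda in sorted(cfg.leak_fraction_per_channel):
        f = cfg.leak_fraction_per_channel[kda]
        channels.append(_render_dextran(cfg, vessels, f))
        labels.append(dextran_label(kda))
    if cfg.puncta is not None:
        channels.append(_render_puncta(cfg, cells, rng))
        labels.append("puncta")

    data = np.stack(channels) + cfg.background
    data = _apply_noise(data, cfg.noise, rng)
    stack = ImageStack(data=data, pixel_size_um=cfg.pixel_size_um,
                       z_step_um=cfg.z_step_um, channel_labels=tuple(labels),
                       axes="CZYX")
    truth = GroundTruth(
        vessels=vessels, cells=cells,
        leak_fraction_per_channel=dict(cfg.leak_fraction_per_channel),
        pixel_size_um=cfg.pixel_size_um, z_step_um=cfg.z_step_um,
        field_size_px=tuple(cfg.field_size_px),
    )
    return stack, truth


# ---------------------------------------------------------------------------
# time-lapse
# ---------------------------------------------------------------------------

def generate_timelapse(cfg: SceneConfig, n_frames: int, jitter_px: int = 0,
                       motility_um_per_frame: float = 0.0,
                       ) -> tuple[ImageStack, GroundTruth]:
    """Render a 2-D time-lapse of one scene with jitter and tip movement.

    All frames share one underlying scene.  Each frame t >= 1 is translated
    by a recorded integer shift drawn uniformly from [-jitter_px, jitter_px]
    per axis, and the first (along-x) process of every cell lengthens by
    ``motility_um_per_frame`` per frame, so its tip displaces by exactly
    that amount between consecutive frames.
    """
    cfg.validate()
    if n_frames < 2:
        raise SceneError("a time-lapse needs at least 2 frames")
    ny, nx = cfg.field_size_px
    if jitter_px < 0 or 2 * jitter_px >= min(ny, nx):
        raise SceneError("jitter must be nonnegative and smaller than the field")
    if motility_um_per_frame < 0:
        raise SceneError("motility must be nonnegative")

    flat = dataclasses.replace(cfg, n_z=1)
    rng = np.random.default_rng(cfg.seed)
    vessels = _vessel_geometry(flat)
    cells = _place_cells(flat, vessels, rng)

    dextran = {kda: _render_dextran(flat, vessels, f)
               for kda, f in sorted(cfg.leak_fraction_per_channel.items())}
    shifts: list[tuple[int, int]] = [(0, 0)]
    for _ in range(1, n_frames):
        shifts.append((int(rng.integers(-jitter_px, jitter_px + 1)),
                       int(rng.integers(-jitter_px, jitter_px + 1))))

    labels = ["microglia"] + [dextran_label(k) for k in sorted(dextran)]
    frames = np.empty((len(labels), n_frames, ny, nx), dtype=float)
    for t in range(n_frames):
        reporter = _render_reporter(flat, cells,
                                    tip_extension_um=motility_um_per_frame * t)
        planes = [reporter[0]] + [dextran[k][0] for k in sorted(dextran)]
        dy, dx = shifts[t]
        for ci, plane in enumerate(planes):
            shifted = _integer_shift(plane, dy, dx)
            frames[ci, t] = shifted
    frames += cfg.background
    frames = _apply_noise(frames, cfg.noise, rng)

    stack = ImageStack(data=frames, pixel_size_um=cfg.pixel_size_um,
                       z_step_um=cfg.z_step_um, channel_labels=tuple(labels),
                       axes="CTYX")
    truth = GroundTruth(
        vessels=vessels, cells=cells,
        leak_fraction_per_channel=dict(cfg.leak_fraction_per_channel),
        pixel_size_um=cfg.pixel_size_um, z_step_um=cfg.z_step_um,
        field_size_px=tuple(cfg.field_size_px),
        shifts_px=shifts,
        tip_step_um_per_frame=float(motility_um_per_frame),
    )
    return stack, truth


def _integer_shift(plane: np.ndarray, dy: int, dx: int,
                   fill: float = 0.0) -> np.ndarray:
    """Translate by integer pixels, filling vacated pixels with ``fill``."""
    out = np.full_like(plane, fill)
    ny, nx = plane.shape
    ys = slice(max(dy, 0), min(ny + dy, ny))
    xs = slice(max(dx, 0), min(nx + dx, nx))
    ys_src = slice(max(-dy, 0), min(ny - dy, ny))
    xs_src = slice(max(-dx, 0), min(nx - dx, nx))
    out[ys, xs] = plane[ys_src, xs_src]
    return out


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_scene(prefix: str | Path, stack: ImageStack, truth: GroundTruth,
                cfg: SceneConfig) -> dict[str, Path]:
    """Write TIFF stack + ground-truth CSV + config echo YAML.

    Returns the paths written, keyed ``tiff``/``cells_csv``/``config_yaml``.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "tiff": prefix.with_suffix(".tif"),
        "cells_csv": prefix.parent / (prefix.name + "_cells.csv"),
        "config_yaml": prefix.parent / (prefix.name + "_config.yaml"),
    }
    stack.to_tiff(paths["tiff"])
    truth.cells_table().to_csv(paths["cells_csv"], index=False)
    cfg_dict = dataclasses.asdict(cfg)
    cfg_dict["leak_fraction_per_channel"] = {
        int(k): float(v) for k, v in cfg.leak_fraction_per_channel.items()
    }
    paths["config_yaml"].write_text(yaml.safe_dump(cfg_dict, sort_keys=True))
    return paths
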