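"""BBB-leakage indexing: extravascular fluorescence relative to control.

Permeability is quantified as the mean fluorescence intensity outside the
delineated vessels, expressed relative to a reference (control) group whose
averaged index is 1.00 by construction.  Size selectivity is probed by
repeating the measurement for each dextran channel (10/40/70 kDa), always
excluding the vessel lumen defined on the impermeant 70 kDa channel so
leak cannot erode its own mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .errors import MissingChannelError, NoParenchymaError, NormalizationError
from .vesselseg import VesselMask


def extravascular_mean(image: np.ndarray, mask: VesselMask | np.ndarray,
                       dilate_px: int | None = None,
                       config: AnalysisConfig | None = None) -> float:
    """Mean intensity over parenchymal (non-vessel) pixels.

    The vessel mask is dilated by ``dilate_px`` pixels first (default from
    the config, 1 px) to keep partial-volume bleed at the vessel border out
    of the parenchymal average.
    """
    config = config or AnalysisConfig()
    if dilate_px is None:
        dilate_px = config.mask_dilation_px
    if isinstance(mask, VesselMask):
        excl = mask.dilated(dilate_px)
    else:
        from scipy import ndimage as ndi

        excl = np.asarray(mask, bool)
        if dilate_px > 0:
            excl = ndi.binary_dilation(excl, np.ones((3, 3), bool),
                                       iterations=dilate_px)
    image = np.asarray(image)
    if image.shape != excl.shape:
        raise ValueError("image and mask shapes differ")
    outside = ~excl
    if not outside.any():
        raise NoParenchymaError("vessel mask covers the entire field")
    return float(image[outside].mean())


@dataclass
class LeakageResult:
    """Relative leakage indices for one dextran size.

    ``samples`` has one row per image (columns ``extravascular_mean`` and
    ``relative_index``); ``reference_index_mean`` is exactly 1.0 whenever
    the reference group is normalized against itself.
    """

    samples: pd.DataFrame
    reference_mean_intensity: float
    group_index_mean: float
    group_index_sd: float
    reference_index_mean: float


def relative_leakage(sample_means: Sequence[float],
                     reference_means: Sequence[float]) -> LeakageResult:
    """Normalize extravascular means to the control group.

    Each sample's relative index is its extravascular mean divided by the
    control-group mean; the control group's own averaged index is therefore
    1.00 identically.
    """
    reference_means = np.asarray(reference_means, dtype=float)
    if reference_means.size == 0:
        raise NormalizationError("reference group is empty")
    ref = float(reference_means.mean())
    if ref <= 0:
        raise NormalizationError("reference mean must be positive")
    sample_means = np.asarray(sample_means, dtype=float)
    idx = sample_means / ref
    ref_idx = reference_means / ref
    samples = pd.DataFrame({
        "extravascular_mean": sample_means,
        "relative_index": idx,
    })
    return LeakageResult(
        samples=samples,
        reference_mean_intensity=ref,
        group_index_mean=float(idx.mean()) if idx.size else float("nan"),
        group_index_sd=float(idx.std(ddof=1)) if idx.size > 1 else 0.0,
        reference_index_mean=float(ref_idx.mean()),
    )


def size_selectivity_table(
    images: Mapping[str, Sequence[Mapping[int, np.ndarray]]],
    masks: Mapping[str, Sequence[VesselMask]],
    reference_condition: str = "control",
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Relative leakage index per dextran size and condition.

    Parameters
    ----------
    images : mapping condition -> list of per-image {dextran_kDa: 2-D image}
        Projected dextran channels for every image of every condition.
        All images must carry the same set of dextran sizes.
    masks : mapping condition -> list of VesselMask
        One vessel mask per image (delineated on the impermeant channel).
    reference_condition : str
        Condition whose group mean defines index 1.00 for every size.

    Returns
    -------
    DataFrame with columns condition, dextran_kDa, n, index_mean, index_sd.
    """
    config = config or AnalysisConfig()
    if reference_condition not in images:
        raise NormalizationError(
            f"reference condition {reference_condition!r} missing")
    sizes = sorted({k for imgs in images.values() for im in imgs for k in im})
    means: dict[str, dict[int, list[float]]] = {}
    for cond, imgs in images.items():
        if len(imgs) != len(masks[cond]):
            raise ValueError(f"{cond}: images and masks differ in length")
        means[cond] = {k: [] for k in sizes}
        for im, mk in zip(imgs, masks[cond]):
            for kda in sizes:
                if kda not in im:
                    raise MissingChannelError(
                        f"{cond}: image lacks the {kda} kDa channel")
                means[cond][kda].append(
                    extravascular_mean(im[kda], mk, config=config))
    rows = []
    for cond in images:
        for kda in sizes:
            res = relative_leakage(means[cond][kda],
                                   means[reference_condition][kda])
            rows.append({
                "condition": cond,
                "dextran_kDa": kda,
                "n": len(means[cond][kda]),
                "index_mean": res.group_index_mean,
                "index_sd": res.group_index_sd,
            })
    return pd.DataFrame(rows, columns=["condition", "dextran_kDa", "n",
                                       "index_mean", "index_sd"])
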