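"""ROI index extraction.

A sample's representative T1 or T2 value is the mean relaxation time over a
segmented region of interest, optionally restricted to pixels whose fit R²
clears a quality threshold. SDs use the sample convention (n - 1
denominator) to match mean ± SD reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .fitting import RelaxationMap

__all__ = ["RoiMask", "SampleMeasurement", "roi_index", "collect_cohort", "cohort_table"]


@dataclass
class RoiMask:
    """A binary region-of-interest mask for one sample."""

    label: str
    mask: np.ndarray
    sample_id: str
    group: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"ROI {self.label!r} is empty")


@dataclass
class SampleMeasurement:
    """One sample's ROI-mean relaxation indices."""

    sample_id: str
    group: str
    t1_index_ms: float
    t2_index_ms: float
    t1_sd_ms: float
    t2_sd_ms: float
    n_pixels: int


def roi_index(
    rmap: RelaxationMap, roi: RoiMask, r2_min: float = 0.0
) -> tuple[float, float, int]:
    """Mean, sample SD and pixel count of a map over an ROI.

    Pixels must lie in the intersection of the ROI with the map's converged
    mask and have ``r2_map >= r2_min``.
    """
    if not 0 <= r2_min < 1:
        raise ValueError(f"r2_min must be in [0, 1), got {r2_min}")
    if roi.mask.shape != rmap.value_map.shape:
        raise ValueError(
            f"ROI {roi.label!r} shape {roi.mask.shape} does not match map"
        )
    sel = roi.mask & rmap.mask & (rmap.r2_map >= r2_min)
    n = int(sel.sum())
    if n == 0:
        raise ValueError(
            f"ROI {roi.label!r} (sample {roi.sample_id}): no pixels survive "
            f"the map mask and r2_min={r2_min} filter"
        )
    values = rmap.value_map[sel]
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    return float(values.mean()), sd, n


def collect_cohort(
    t1_maps: Mapping[str, RelaxationMap],
    t2_maps: Mapping[str, RelaxationMap],
    rois: Mapping[str, RoiMask],
    r2_min: float = 0.0,
) -> list[SampleMeasurement]:
    """Reduce per-sample T1/T2 maps + ROIs to one measurement per sample.

    Mappings are keyed by a per-measurement key (sample_id alone, or
    sample_id + timepoint when the same specimen is measured twice); the
    ROI's own ``sample_id``/``group`` fields carry the identity, so paired
    pre-/post-treatment entries of one physical specimen share sample_id.
    """
    missing = [
        key
        for key in rois
        if key not in t1_maps or key not in t2_maps
    ]
    if missing:
        raise ValueError(f"samples missing a T1 or T2 map: {sorted(missing)}")

    out = []
    for key, roi in rois.items():
        t1_mean, t1_sd, n1 = roi_index(t1_maps[key], roi, r2_min)
        t2_mean, t2_sd, n2 = roi_index(t2_maps[key], roi, r2_min)
        out.append(
            SampleMeasurement(
                sample_id=roi.sample_id,
                group=roi.group,
                t1_index_ms=t1_mean,
                t2_index_ms=t2_mean,
                t1_sd_ms=t1_sd,
                t2_sd_ms=t2_sd,
                n_pixels=min(n1, n2),
            )
        )
    return out


def cohort_table(measurements: list[SampleMeasurement]) -> pd.DataFrame:
    """Cohort measurements as a tidy DataFrame (CSV-export ready)."""
    return pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "group": m.group,
                "t1_index_ms": m.t1_index_ms,
                "t1_sd_ms": m.t1_sd_ms,
                "t2_index_ms": m.t2_index_ms,
                "t2_sd_ms": m.t2_sd_ms,
                "n_pixels": m.n_pixels,
            }
            for m in measurements
        ]
    )
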