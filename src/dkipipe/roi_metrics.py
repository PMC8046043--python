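"""ROI aggregation of scalar metric maps over a segregated thalamus atlas.

All volumes are processed in voxel space and must share one grid; spatial
normalisation happens upstream.  Voxels inside the ventricle mask are
excluded from every ROI mean.  Hemisphere ("whole thalamus") values are
voxel-weighted means over all of a hemisphere's subregion voxels, and the
bilateral value is (left + right) / 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import SUBREGIONS, HEMISPHERES

__all__ = ["LabelAtlas", "summarize_rois", "whole_thalamus"]

#: names accepted in an atlas dictionary: the seven thalamic subregions plus
#: the superior-frontal-gyrus stand-in used by the connectivity analysis
VALID_SUBREGIONS = set(SUBREGIONS) | {"SFG"}


@dataclass
class LabelAtlas:
    """Integer label volume with a (hemisphere, subregion) dictionary and an
    optional boolean ventricle mask on the same grid."""

    label_volume: np.ndarray
    label_dictionary: dict[int, tuple[str, str]]
    ventricle_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        vol = np.asarray(self.label_volume)
        if not np.issubdtype(vol.dtype, np.integer):
            raise ValueError("label volume must be integer-typed")
        present = set(np.unique(vol)) - {0}
        declared = set(self.label_dictionary)
        if present != declared:
            raise ValueError(
                f"label dictionary mismatch: volume has {sorted(present)}, "
                f"dictionary declares {sorted(declared)}"
            )
        for lab, (hemi, sub) in self.label_dictionary.items():
            if hemi not in HEMISPHERES:
                raise ValueError(f"label {lab}: hemisphere must be L or R")
            if sub not in VALID_SUBREGIONS:
                raise ValueError(f"label {lab}: unknown subregion {sub!r}")
        if self.ventricle_mask is not None and \
                np.asarray(self.ventricle_mask).shape != vol.shape:
            raise ValueError("ventricle mask grid must match the label volume")
        object.__setattr__(self, "label_volume", vol)

    def label_for(self, hemisphere: str, subregion: str) -> int:
        for lab, pair in self.label_dictionary.items():
            if pair == (hemisphere, subregion):
                return lab
        raise KeyError(f"no label for ({hemisphere}, {subregion})")

    def mask_for(self, hemisphere: str, subregion: str) -> np.ndarray:
        return self.label_volume == self.label_for(hemisphere, subregion)


def summarize_rois(metric_maps: dict[str, np.ndarray],
                   atlas: LabelAtlas) -> pd.DataFrame:
    """Per-ROI arithmetic means of each metric map.

    Returns a tidy frame with columns hemisphere, subregion, metric, mean,
    n_included, n_masked_out.  ROIs fully inside the ventricle mask are
    reported with n_included = 0 and mean = NaN, never dropped.
    """
    shape = atlas.label_volume.shape
    for name, m in metric_maps.items():
        if np.asarray(m).shape != shape:
            raise ValueError(f"metric map {name!r} grid does not match the atlas")
    vent = (np.zeros(shape, dtype=bool) if atlas.ventricle_mask is None
            else np.asarray(atlas.ventricle_mask, dtype=bool))
    rows = []
    for lab, (hemi, sub) in sorted(atlas.label_dictionary.items()):
        roi = atlas.label_volume == lab
        included = roi & ~vent
        n_inc = int(included.sum())
        n_out = int((roi & vent).sum())
        for name, m in metric_maps.items():
            vals = np.asarray(m, dtype=float)[included]
            vals = vals[np.isfinite(vals)]
            mean = float(vals.mean()) if vals.size else float("nan")
            rows.append({"hemisphere": hemi, "subregion": sub, "metric": name,
                         "mean": mean, "n_included": len(vals),
                         "n_masked_out": n_out})
    return pd.DataFrame(rows)


def whole_thalamus(summary: pd.DataFrame, metric: str,
                   mode: str = "voxel_weighted") -> float:
    """Bilateral whole-thalamus average of one metric: (left + right) / 2.

    ``mode="voxel_weighted"`` (default) weights each subregion mean by its
    included voxel count within the hemisphere; ``mode="subregion_means"``
    averages the subregion means directly.
    """
    sel = summary[(summary["metric"] == metric)
                  & summary["subregion"].isin(SUBREGIONS)]
    hemi_means = {}
    for hemi in HEMISPHERES:
        part = sel[(sel["hemisphere"] == hemi) & (sel["n_included"] > 0)]
        if part.empty:
            raise ValueError(f"no included voxels in hemisphere {hemi}")
        if mode == "voxel_weighted":
            hemi_means[hemi] = float(
                np.average(part["mean"], weights=part["n_included"]))
        elif mode == "subregion_means":
            hemi_means[hemi] = float(part["mean"].mean())
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return (hemi_means["L"] + hemi_means["R"]) / 2.0


def ventricle_mask_from_b0(mean_b0: np.ndarray, quantile: float = 0.9) -> np.ndarray:
    """Simple intensity-threshold ventricle mask for synthetic data: CSF is
    bright on b0, so voxels above the given intensity quantile are masked."""
    b0 = np.asarray(mean_b0, dtype=float)
    thr = np.quantile(b0[np.isfinite(b0)], quantile)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return b0 > thr
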