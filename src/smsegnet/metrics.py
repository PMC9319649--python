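"""Overlap and boundary metrics for segmentation masks.

Given a ground-truth mask s and a predicted mask s', the package reports

* Dice similarity coefficient  DSC = 2|s n s'| / (|s| + |s'|),
* Jaccard index                JI  = |s n s'| / |s u s'|,
* Hausdorff distance           HD  = max of the two directed maxima of
  Euclidean nearest-point distances between the foreground voxel centres,
  in pixel units (optionally scaled by voxel spacing).

DSC and JI measure the same overlap on different scales and are related by
JI = DSC / (2 - DSC).  Metrics for a class absent from both maps are
undefined and reported as missing (NaN), not zero; a class present in
exactly one map has DSC = JI = 0 and an undefined HD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import nan, isnan

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .volume import LabelMap, CLASS_NAMES

__all__ = ["dice", "jaccard", "hausdorff", "evaluate", "MetricsReport"]


def _masks(s, s_pred):
    s = np.asarray(s, dtype=bool)
    s_pred = np.asarray(s_pred, dtype=bool)
    if s.shape != s_pred.shape:
        raise ValueError(f"mask shapes differ: {s.shape} vs {s_pred.shape}")
    return s, s_pred


def dice(s, s_pred) -> float:
    """Dice similarity coefficient; NaN when both masks are empty."""
    s, s_pred = _masks(s, s_pred)
    denom = int(s.sum()) + int(s_pred.sum())
    if denom == 0:
        return nan
    return 2.0 * int((s & s_pred).sum()) / denom


def jaccard(s, s_pred) -> float:
    """Jaccard index |intersection| / |union|; NaN when both masks are empty."""
    s, s_pred = _masks(s, s_pred)
    union = int((s | s_pred).sum())
    if union == 0:
        return nan
    return int((s & s_pred).sum()) / union


def hausdorff(s, s_pred, spacing=None) -> float:
    """Symmetric Hausdorff distance between foreground voxel centres.

    Computed on the point sets of foreground coordinates (no surface
    extraction), in pixel units unless ``spacing`` scales each axis.
    NaN when either mask is empty.
    """
    s, s_pred = _masks(s, s_pred)
    a = np.argwhere(s).astype(np.float64)
    b = np.argwhere(s_pred).astype(np.float64)
    if len(a) == 0 or len(b) == 0:
        return nan
    if spacing is not None:
        scale = np.asarray(spacing, dtype=np.float64)
        if scale.shape != (s.ndim,):
            raise ValueError(f"spacing must have {s.ndim} entries")
        a *= scale
        b *= scale
    # directed maxima via nearest-neighbour queries; scales to volume masks
    d_ab = cKDTree(b).query(a, k=1)[0].max()
    d_ba = cKDTree(a).query(b, k=1)[0].max()
    return float(max(d_ab, d_ba))


@dataclass
class MetricsReport:
    """Per-class DSC/JI/HD for one predicted vs. ground-truth pair.

    ``per_class`` maps a class name to ``{"dsc": ..., "ji": ..., "hd": ...}``
    at full precision; missing values are NaN.  ``rounded`` applies the
    2-decimal reporting convention without touching the stored values.
    """

    per_class: dict[str, dict[str, float]]
    subject: str | None = None

    def mean(self, metric: str) -> float:
        vals = [m[metric] for m in self.per_class.values()
                if not isnan(m[metric])]
        return float(np.mean(vals)) if vals else nan

    @property
    def means(self) -> dict[str, float]:
        return {m: self.mean(m) for m in ("dsc", "ji", "hd")}

    def rounded(self, ndigits: int = 2) -> dict[str, dict[str, float]]:
        return {cls: {k: round(v, ndigits) for k, v in m.items()}
                for cls, m in self.per_class.items()}

    def to_frame(self) -> pd.DataFrame:
        """One row per class x metric, suitable for CSV export."""
        rows = [
            {"subject": self.subject, "class": cls, "metric": metric,
             "value": value}
            for cls, m in self.per_class.items()
            for metric, value in m.items()
        ]
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        import json
        doc = {"subject": self.subject, "per_class": self.per_class,
               "means": self.means}
        return json.dumps(doc, default=lambda x: None if isnan(x) else x)


def evaluate(pred: "LabelMap | np.ndarray", truth: "LabelMap | np.ndarray",
             classes=(1, 2, 3), spacing=None,
             subject: str | None = None) -> MetricsReport:
    """Per-class DSC, JI and HD between predicted and true label maps.

    Background (class 0) is excluded from the report by default.  Each class
    is binarized and the three metrics computed on the mask pair; classes
    absent from both maps yield missing values.
    """
    p = pred.data if isinstance(pred, LabelMap) else np.asarray(pred)
    t = truth.data if isinstance(truth, LabelMap) else np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"label map shapes differ: {p.shape} vs {t.shape}")
    per_class = {}
    for c in classes:
        name = CLASS_NAMES[c] if c < len(CLASS_NAMES) else str(c)
        mask_t, mask_p = t == c, p == c
        per_class[name] = {
            "dsc": dice(mask_t, mask_p),
            "ji": jaccard(mask_t, mask_p),
            "hd": hausdorff(mask_t, mask_p, spacing=spacing),
        }
    return MetricsReport(per_class=per_class, subject=subject)
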