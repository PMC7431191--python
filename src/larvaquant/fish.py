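"""Nascent-transcript intensity-ratio quantification (col / nau).

Pipeline per stack: sum-slices z-projection of each channel, per-channel
background thresholding (percentile with soft subtraction), then
ROI-integrated intensities inside each nuclear mask and their ratio
R = I_col / I_nau.  The nau channel is the internal reference, so R is
robust to acquisition-wide intensity scaling; per-nucleus ratios are
averaged per group (never a ratio of group sums).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ImageStack, NucleusMaskSet


@dataclass
class NucleusMeasurement:
    nucleus_id: int
    I_col: float
    I_nau: float
    R: Optional[float]
    valid: bool = True
    stage: str = ""
    genotype: str = ""


@dataclass
class GroupSummary:
    mean: float
    sem: float
    n: int


def sum_projection(stack: ImageStack) -> dict:
    """Pixelwise sum over z per channel; preserves integrated intensity.

    Returns {channel_name: 2D float array}.
    """
    if stack.pixels.shape[1] < 1:
        raise ValueError("stack has no z slices")
    proj = stack.pixels.astype(float).sum(axis=1)
    return {name: proj[i] for i, name in enumerate(stack.channel_names)}


def apply_threshold(image: np.ndarray, method: str = "percentile",
                    q: float = 50.0) -> np.ndarray:
    """Background removal: pixels at or below the threshold go to zero,
    pixels above it have the threshold subtracted (soft subtraction).

    ``method='percentile'`` computes the threshold as the q-th percentile
    of the image (the default median tracks the background mode when the
    foci are sparse).  ``method='fixed'`` uses ``q`` as an absolute value.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2D projected image")
    if method == "percentile":
        thr = float(np.percentile(image, q))
    elif method == "fixed":
        thr = float(q)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return np.where(image > thr, image - thr, 0.0)


def roi_ratio(proj_col: np.ndarray, proj_nau: np.ndarray,
              masks: NucleusMaskSet, nucleus_id: int,
              stage: str = "", genotype: str = "") -> NucleusMeasurement:
    """Integrated intensities and their ratio inside one nuclear ROI.

    Both projections must have been thresholded with the same method.  A
    zero nau integral flags the measurement invalid (excluded from group
    summaries) rather than raising.
    """
    roi = masks.roi(nucleus_id)
    I_col = float(proj_col[roi].sum())
    I_nau = float(proj_nau[roi].sum())
    if I_nau <= 0:
        return NucleusMeasurement(nucleus_id, I_col, I_nau, R=None,
                                  valid=False, stage=stage, genotype=genotype)
    return NucleusMeasurement(nucleus_id, I_col, I_nau, R=I_col / I_nau,
                              stage=stage, genotype=genotype)


def quantify_stack(stack: ImageStack, masks: NucleusMaskSet,
                   method: str = "percentile", q: float = 50.0,
                   stage: str = "", genotype: str = "") -> pd.DataFrame:
    """Run the full quantification on one stack; one row per nucleus."""
    proj = sum_projection(stack)
    pc = apply_threshold(proj["col"], method=method, q=q)
    pn = apply_threshold(proj["nau"], method=method, q=q)
    rows = []
    for nid in masks.ids:
        m = roi_ratio(pc, pn, masks, int(nid), stage=stage, genotype=genotype)
        rows.append({"nucleus_id": m.nucleus_id, "I_col": m.I_col,
                     "I_nau": m.I_nau, "R": m.R, "valid": m.valid,
                     "stage": m.stage, "genotype": m.genotype})
    return pd.DataFrame(rows, columns=["nucleus_id", "I_col", "I_nau", "R",
                                       "valid", "stage", "genotype"])


def _ratios(measurements) -> np.ndarray:
    if isinstance(measurements, pd.DataFrame):
        df = measurements
        vals = df.loc[df["valid"].astype(bool), "R"].to_numpy(dtype=float)
    else:
        vals = np.array([m.R for m in measurements if m.valid], dtype=float)
    return vals[np.isfinite(vals)]


def summarize_group(measurements) -> GroupSummary:
    r = _ratios(measurements)
    if r.size < 1:
        raise ValueError("no valid measurements in group")
    sem = float(sps.sem(r)) if r.size > 1 else float("nan")
    return GroupSummary(mean=float(r.mean()), sem=sem, n=int(r.size))


def group_compare(group_a, group_b) -> Tuple[GroupSummary, GroupSummary,
                                             float, float]:
    """Unpaired two-sample t-test on per-nucleus ratios.

    Returns (summary_a, summary_b, t, p).  Both groups need n >= 2; two
    zero-variance groups with identical means degenerate to t = 0, p = 1.
    """
    ra, rb = _ratios(group_a), _ratios(group_b)
    if ra.size < 2 or rb.size < 2:
        raise ValueError("each group needs at least 2 valid measurements")
    sa = GroupSummary(float(ra.mean()), float(sps.sem(ra)), int(ra.size))
    sb = GroupSummary(float(rb.mean()), float(sps.sem(rb)), int(rb.size))
    if ra.std() == 0 and rb.std() == 0:
        if ra.mean() == rb.mean():
            return sa, sb, 0.0, 1.0
        return sa, sb, float("inf"), 0.0
    t, p = sps.ttest_ind(ra, rb, equal_var=True)
    return sa, sb, float(t), float(p)
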