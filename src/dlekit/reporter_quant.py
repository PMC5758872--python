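"""Quantitative two-channel reporter-ratio image analysis.

Pipeline for GFP translation reporters co-injected with a rhodamine
tracer: pick the in-focus block of optical sections, maximum-project it,
segment the blastoderm ROI by thresholding the tracer channel, subtract
background estimated from un-injected control embryos processed by the
same pipeline, and report the per-embryo background-subtracted GFP/RFP
ratio.  Group comparison is a two-way ANOVA (genotype group x stage) on
the ratio with Bonferroni-adjusted per-stage contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .seqio import ValidationError

__all__ = [
    "EmbryoStack",
    "EmbryoMeasurement",
    "EmptyROIError",
    "best_focus_window",
    "project",
    "segment_roi",
    "measure",
    "compare_groups",
    "measurements_frame",
]

ALPHA = 0.05


class EmptyROIError(ValidationError):
    """Threshold segmentation found no suprathreshold pixels."""


@dataclass
class EmbryoStack:
    """Two-channel z-stack for one embryo (shapes must agree)."""

    embryo_id: str
    group: str
    stage: str
    gfp: np.ndarray  # (n_slices, h, w)
    rfp: np.ndarray
    is_control: bool = False

    def __post_init__(self) -> None:
        self.gfp = np.asarray(self.gfp, dtype=float)
        self.rfp = np.asarray(self.rfp, dtype=float)
        if self.gfp.shape != self.rfp.shape:
            raise ValidationError(
                f"embryo {self.embryo_id!r}: channel shapes differ "
                f"{self.gfp.shape} vs {self.rfp.shape}"
            )
        if self.gfp.ndim != 3:
            raise ValidationError("stacks must be (n_slices, h, w)")
        if (self.gfp < 0).any() or (self.rfp < 0).any():
            raise ValidationError("negative intensities")


@dataclass
class EmbryoMeasurement:
    """Per-embryo background-subtracted means and normalized ratio."""

    embryo_id: str
    group: str
    stage: str
    roi_area: int
    mean_gfp: float
    mean_rfp: float
    bg_gfp: float
    bg_rfp: float
    ratio: float = field(init=False)
    flagged: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        denom = self.mean_rfp - self.bg_rfp
        if self.roi_area <= 0 or denom <= 0:
            self.flagged = True
            self.ratio = float("nan")
        else:
            self.ratio = (self.mean_gfp - self.bg_gfp) / denom


def best_focus_window(stack: np.ndarray, window: int = 4) -> tuple[int, int]:
    """Contiguous slice window with maximal total intensity (the in-focus block)."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValidationError("empty or non-3D stack")
    n = stack.shape[0]
    if window > n:
        raise ValidationError(f"window {window} exceeds {n} slices")
    sums = stack.reshape(n, -1).sum(axis=1)
    totals = np.convolve(sums, np.ones(window), mode="valid")
    start = int(np.argmax(totals))
    return start, start + window


def project(
    stack: np.ndarray, window: int = 4, slices: tuple[int, int] | None = None
) -> np.ndarray:
    """Maximum-intensity projection of the best (or given) focus window."""
    stack = np.asarray(stack, dtype=float)
    if slices is None:
        slices = best_focus_window(stack, window)
    a, b = slices
    if not (0 <= a < b <= stack.shape[0]):
        raise ValidationError(f"bad slice window {slices}")
    return stack[a:b].max(axis=0)


def segment_roi(rfp_plane: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Largest connected component above threshold (Otsu unless given)."""
    plane = np.asarray(rfp_plane, dtype=float)
    if plane.size == 0:
        raise ValidationError("empty plane")
    if threshold is None:
        if np.ptp(plane) == 0:
            raise EmptyROIError("uniform plane: no suprathreshold pixels")
        threshold = threshold_otsu(plane)
    mask = plane > threshold
    if not mask.any():
        raise EmptyROIError("no suprathreshold pixels")
    labels = label(mask)
    regions = regionprops(labels)
    biggest = max(regions, key=lambda r: (r.area, -r.label))
    return labels == biggest.label


def _central_rectangle(shape: tuple[int, int], fraction: float = 0.5) -> np.ndarray:
    """Fallback background region for controls with no segmentable signal."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    dh, dw = int(h * fraction / 2), int(w * fraction / 2)
    mask[h // 2 - dh:h // 2 + dh, w // 2 - dw:w // 2 + dw] = True
    return mask


def _control_means(
    control: EmbryoStack,
    window: int,
    threshold: float | None,
    control_mode: str,
) -> tuple[float, float]:
    win = best_focus_window(control.rfp, window)
    gplane = project(control.gfp, slices=win)
    rplane = project(control.rfp, slices=win)
    if control_mode == "whole-image":
        mask = np.ones(rplane.shape, dtype=bool)
    else:
        try:
            mask = segment_roi(rplane, threshold)
        except EmptyROIError:
            mask = _central_rectangle(rplane.shape)
    return float(gplane[mask].mean()), float(rplane[mask].mean())


def measure(
    embryo: EmbryoStack,
    controls: list[EmbryoStack],
    window: int = 4,
    threshold: float | None = None,
    slices: tuple[int, int] | None = None,
    control_mode: str = "roi",
) -> EmbryoMeasurement:
    """Full per-embryo pipeline: project, segment, background-subtract, ratio.

    The focus window is chosen on the tracer (rhodamine) channel and
    applied to both channels; ``slices`` overrides the automatic choice.
    Background means come from the controls run through the same pipeline
    (``control_mode="roi"``), falling back to a fixed central rectangle
    for controls with no segmentable signal; ``"whole-image"`` uses plain
    whole-plane control means instead.
    """
    if not controls:
        raise ValidationError("at least one un-injected control stack is required")
    if control_mode not in ("roi", "whole-image"):
        raise ValidationError(f"unknown control_mode {control_mode!r}")
    win = slices if slices is not None else best_focus_window(embryo.rfp, window)
    gplane = project(embryo.gfp, slices=win)
    rplane = project(embryo.rfp, slices=win)
    mask = segment_roi(rplane, threshold)
    bg = [_control_means(c, window, threshold, control_mode) for c in controls]
    bg_gfp = float(np.mean([g for g, _ in bg]))
    bg_rfp = float(np.mean([r for _, r in bg]))
    return EmbryoMeasurement(
        embryo_id=embryo.embryo_id,
        group=embryo.group,
        stage=embryo.stage,
        roi_area=int(mask.sum()),
        mean_gfp=float(gplane[mask].mean()),
        mean_rfp=float(rplane[mask].mean()),
        bg_gfp=bg_gfp,
        bg_rfp=bg_rfp,
    )


def measurements_frame(measurements: list[EmbryoMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "embryo_id": [m.embryo_id for m in measurements],
            "group": [m.group for m in measurements],
            "stage": [m.stage for m in measurements],
            "roi_area": [m.roi_area for m in measurements],
            "mean_gfp": [m.mean_gfp for m in measurements],
            "mean_rfp": [m.mean_rfp for m in measurements],
            "bg_gfp": [m.bg_gfp for m in measurements],
            "bg_rfp": [m.bg_rfp for m in measurements],
            "ratio": [m.ratio for m in measurements],
            "flagged": [m.flagged for m in measurements],
        }
    )


def compare_groups(measurements: list[EmbryoMeasurement]) -> dict:
    """Two-way ANOVA (group, stage, interaction) plus per-stage contrasts.

    Requires >= 2 groups and >= 2 stages with >= 2 unflagged embryos per
    (group, stage) cell.  Per-stage group contrasts are two-sample t tests
    with Bonferroni adjustment over the number of contrasts; alpha 0.05.
    Returns {"anova": DataFrame, "contrasts": DataFrame}.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = measurements_frame(measurements)
    df = df[~df["flagged"]]
    groups = sorted(df["group"].unique())
    stages = sorted(df["stage"].unique())
    if len(groups) < 2 or len(stages) < 2:
        raise ValidationError("need >= 2 groups and >= 2 stages")
    for g in groups:
        for s in stages:
            n = len(df[(df["group"] == g) & (df["stage"] == s)])
            if n < 2:
                raise ValidationError(
                    f"cell (group={g!r}, stage={s!r}) has {n} embryos; need >= 2"
                )
    model = ols("ratio ~ C(group) * C(stage)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    anova = anova.rename(
        index={
            "C(group)": "group",
            "C(stage)": "stage",
            "C(group):C(stage)": "group:stage",
            "Residual": "residual",
        }
    )
    contrasts = []
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    n_tests = len(stages) * len(pairs)
    for s in stages:
        for a, b in pairs:
            xa = df[(df["group"] == a) & (df["stage"] == s)]["ratio"]
            xb = df[(df["group"] == b) & (df["stage"] == s)]["ratio"]
            t, p = sps.ttest_ind(xa, xb)
            contrasts.append(
                {
                    "stage": s,
                    "group_a": a,
                    "group_b": b,
                    "t": float(t),
                    "p_raw": float(p),
                    "p_bonferroni": float(min(1.0, p * n_tests)),
                    "significant": bool(min(1.0, p * n_tests) < ALPHA),
                }
            )
    return {"anova": anova, "contrasts": pd.DataFrame(contrasts)}
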