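"""Cohort statistics and slope-based classification of myocardial tissue.

Depolarization in turbid tissue grows with path length, so the measured DOLP
of a myocardial sample confounds disease state with tissue thickness.  The
slope-based analysis removes the confound: DOLP is regressed on thickness
separately for the control and diseased groups, each group is summarized by
the slope of its ordinary-least-squares line (mm⁻¹), and a cut-off line with
a slope strictly between the two group slopes discriminates individual
samples.  A sample is called diseased when the slope of the line joining it
to the cut-off anchor point is steeper (more negative) than the cut-off
slope.

The scikit-learn estimator :class:`SlopeCutoffClassifier` packages the whole
procedure (two group fits → cut-off selection → per-sample rule); the
module-level functions expose the individual steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "TissueSample",
    "GroupSummary",
    "GroupFit",
    "CutoffLine",
    "ConfusionMetrics",
    "group_summary",
    "fit_group",
    "select_cutoff",
    "classify",
    "confusion_metrics",
    "SlopeCutoffClassifier",
]

GROUPS = ("control", "RHD", "MV")
VENTRICLES = ("LV", "RV")

#: two samples closer than this in thickness are treated as coincident (mm)
ANCHOR_THICKNESS_TOL_MM = 1e-9


@dataclass(frozen=True)
class TissueSample:
    """One ventricular tissue specimen: the unit of classification.

    ``group`` is the clinical diagnosis: healthy control, rheumatic heart
    disease (RHD) or myxomatous valve (MV) disease.  ``thickness_mm`` may be
    None for records transcribed from published per-subject DOLP tables that
    print no thickness; such records support summaries but not fits.
    """

    subject_id: str
    group: str
    ventricle: str
    thickness_mm: float | None
    dolp: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.ventricle not in VENTRICLES:
            raise ValueError(
                f"unknown ventricle {self.ventricle!r}; expected one of {VENTRICLES}"
            )
        if self.thickness_mm is not None and not self.thickness_mm > 0:
            raise ValueError(f"thickness_mm must be > 0, got {self.thickness_mm}")
        if not (0.0 <= self.dolp <= 1.0):
            raise ValueError(f"dolp must be in [0, 1], got {self.dolp}")


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± SEM of DOLP over one (group, ventricle) cell."""

    group: str
    ventricle: str
    n: int
    mean_dolp: float
    sem_dolp: float


@dataclass(frozen=True)
class GroupFit:
    """OLS line dolp = slope·thickness + intercept for one group."""

    group: str
    slope: float
    intercept: float
    n: int
    r2: float

    def predict(self, thickness_mm: float) -> float:
        return self.slope * thickness_mm + self.intercept


@dataclass(frozen=True)
class CutoffLine:
    """The discriminating line: a slope through an anchor point."""

    slope: float
    anchor_thickness_mm: float
    anchor_dolp: float
    strategy: str = "fixed"


@dataclass(frozen=True)
class ConfusionMetrics:
    """Binary diagnostic counts and the derived proportions."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float


def group_summary(
    samples: Iterable[TissueSample], group: str, ventricle: str
) -> GroupSummary:
    """Mean and standard error of DOLP over one (group, ventricle) subset.

    SEM uses the (n−1)-denominator sample SD divided by sqrt(n); a single
    sample has SEM 0 by convention.
    """
    vals = [s.dolp for s in samples if s.group == group and s.ventricle == ventricle]
    if not vals:
        raise ValueError(f"no samples for group={group!r}, ventricle={ventricle!r}")
    arr = np.asarray(vals, dtype=float)
    sem = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return GroupSummary(group, ventricle, len(arr), float(arr.mean()), sem)


def _ols_line(t: np.ndarray, d: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, intercept and R² of d on t."""
    design = np.column_stack([t, np.ones_like(t)])
    (slope, intercept), *_ = np.linalg.lstsq(design, d, rcond=None)
    resid = d - (slope * t + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((d - d.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


def fit_group(samples: Sequence[TissueSample]) -> GroupFit:
    """OLS fit of DOLP against thickness for one group, ventricles pooled.

    Requires at least two samples with distinct thicknesses; every sample
    must carry a thickness.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("fit_group requires at least 2 samples")
    groups = {s.group for s in samples}
    if len(groups) != 1:
        raise ValueError(f"fit_group expects a single group, got {sorted(groups)}")
    missing = [s.subject_id for s in samples if s.thickness_mm is None]
    if missing:
        raise ValueError(f"samples lack thickness: {missing}")
    t = np.array([s.thickness_mm for s in samples], dtype=float)
    d = np.array([s.dolp for s in samples], dtype=float)
    if len(t) < 2 or np.ptp(t) == 0.0:
        raise ValueError("degenerate predictor: need >= 2 distinct thicknesses")
    slope, intercept, r2 = _ols_line(t, d)
    return GroupFit(groups.pop(), slope, intercept, len(samples), r2)


def _anchor_point(
    control_fit: GroupFit, diseased_fit: GroupFit, anchor: str
) -> tuple[float, float]:
    if anchor == "intersection":
        t = (diseased_fit.intercept - control_fit.intercept) / (
            control_fit.slope - diseased_fit.slope
        )
        return t, control_fit.predict(t)
    if anchor == "intercept-mean":
        return 0.0, 0.5 * (control_fit.intercept + diseased_fit.intercept)
    raise ValueError(f"unknown anchor strategy {anchor!r}")


def select_cutoff(
    control_fit: GroupFit,
    diseased_fit: GroupFit,
    samples: Sequence[TissueSample] | None = None,
    strategy: Literal["fixed", "max-accuracy"] = "max-accuracy",
    *,
    fixed_slope: float | None = None,
    anchor: Literal["intersection", "intercept-mean"] = "intersection",
    diseased_groups: Sequence[str] = ("RHD", "MV"),
    n_grid: int = 201,
) -> CutoffLine:
    """Choose the discriminating cut-off line between two group fits.

    ``strategy="fixed"`` takes the user-supplied slope (to replicate a
    published cut-off).  ``strategy="max-accuracy"`` grid-searches ``n_grid``
    candidate slopes strictly between the two group slopes and returns the
    one maximizing classification accuracy on ``samples``; ties are broken
    toward the midpoint of the two group slopes.

    The line's anchor point is the intersection of the two group fit lines
    by default, or (0, mean of the two intercepts) with
    ``anchor="intercept-mean"``.
    """
    if control_fit.slope == diseased_fit.slope:
        raise ValueError("groups not separable by slope: fitted slopes are equal")
    at, ad = _anchor_point(control_fit, diseased_fit, anchor)
    if strategy == "fixed":
        if fixed_slope is None:
            raise ValueError("fixed strategy requires fixed_slope")
        return CutoffLine(float(fixed_slope), at, ad, strategy="fixed")
    if strategy != "max-accuracy":
        raise ValueError(f"unknown cutoff strategy {strategy!r}")
    if not samples:
        raise ValueError("max-accuracy strategy requires samples")
    lo, hi = sorted((control_fit.slope, diseased_fit.slope))
    # n_grid candidates strictly inside the open interval (lo, hi)
    candidates = np.linspace(lo, hi, n_grid + 2)[1:-1]
    mid = 0.5 * (lo + hi)
    best: tuple[float, float, float] | None = None  # (accuracy, -|slope-mid|, slope)
    for cand in candidates:
        line = CutoffLine(float(cand), at, ad, strategy="max-accuracy")
        _, metrics = classify(samples, line, diseased_groups=diseased_groups)
        key = (metrics.accuracy, -abs(cand - mid), float(cand))
        if best is None or key > best:
            best = key
    return CutoffLine(best[2], at, ad, strategy="max-accuracy")


def _diseased_mask(
    thickness: np.ndarray,
    dolp_vals: np.ndarray,
    cutoff: CutoffLine,
    diseased_side: str,
) -> np.ndarray:
    dt = thickness - cutoff.anchor_thickness_mm
    at_anchor = np.abs(dt) < ANCHOR_THICKNESS_TOL_MM
    safe_dt = np.where(at_anchor, 1.0, dt)
    slopes = (dolp_vals - cutoff.anchor_dolp) / safe_dt
    if diseased_side == "steeper":
        mask = slopes < cutoff.slope
        mask[at_anchor] = dolp_vals[at_anchor] > cutoff.anchor_dolp
    elif diseased_side == "shallower":
        mask = slopes > cutoff.slope
        mask[at_anchor] = dolp_vals[at_anchor] < cutoff.anchor_dolp
    else:
        raise ValueError(f"unknown diseased_side {diseased_side!r}")
    return mask


def classify(
    samples: Sequence[TissueSample],
    cutoff: CutoffLine,
    *,
    diseased_groups: Sequence[str] = ("RHD", "MV"),
    diseased_side: Literal["steeper", "shallower"] = "steeper",
) -> tuple[list[str], ConfusionMetrics]:
    """Label each sample control/diseased and score against the true groups.

    The per-sample statistic is the slope of the line joining the sample to
    the cut-off anchor; a sample is diseased when that slope is strictly
    steeper (more negative) than the cut-off slope, so a sample exactly on
    the cut-off line is labelled control.  A sample at the anchor thickness
    (where the slope is undefined) is labelled diseased when its DOLP lies
    strictly on the diseased side of the anchor DOLP.
    """
    samples = list(samples)
    missing = [s.subject_id for s in samples if s.thickness_mm is None]
    if missing:
        raise ValueError(f"samples lack thickness: {missing}")
    t = np.array([s.thickness_mm for s in samples], dtype=float)
    d = np.array([s.dolp for s in samples], dtype=float)
    mask = _diseased_mask(t, d, cutoff, diseased_side)
    labels = ["diseased" if m else "control" for m in mask]
    truth = np.array([s.group in tuple(diseased_groups) for s in samples])
    tp = int(np.sum(mask & truth))
    fp = int(np.sum(mask & ~truth))
    tn = int(np.sum(~mask & ~truth))
    fn = int(np.sum(~mask & truth))
    return labels, confusion_metrics(tp, fp, tn, fn)


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> ConfusionMetrics:
    """Sensitivity tp/(tp+fn), specificity tn/(tn+fp) and overall accuracy."""
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if not isinstance(v, (int, np.integer)) or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if tp + fn == 0:
        raise ValueError("sensitivity undefined: no positive (diseased) samples")
    if tn + fp == 0:
        raise ValueError("specificity undefined: no negative (control) samples")
    return ConfusionMetrics(
        tp=int(tp),
        fp=int(fp),
        tn=int(tn),
        fn=int(fn),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        accuracy=(tp + tn) / (tp + tn + fp + fn),
    )


class SlopeCutoffClassifier(ClassifierMixin, BaseEstimator):
    """Slope-based two-group classifier of (thickness, DOLP) measurements.

    ``fit`` takes ``X`` with two columns, thickness (mm) and DOLP, and binary
    labels ``y``; it regresses DOLP on thickness within each class, selects a
    cut-off slope between the two fitted slopes and anchors the cut-off line.
    ``predict`` labels a sample by comparing the slope from the anchor to the
    sample against the cut-off slope.

    Parameters
    ----------
    cutoff_strategy : {"max-accuracy", "fixed"}
        How the cut-off slope is chosen: maximize training accuracy over a
        grid between the two group slopes, or use ``fixed_slope``.
    fixed_slope : float, optional
        Cut-off slope in mm⁻¹; required iff ``cutoff_strategy="fixed"``.
    anchor : {"intersection", "intercept-mean"}
        Anchor point of the cut-off line: the intersection of the two group
        fit lines, or thickness 0 at the mean of the two intercepts.
    control_class : object
        The label in ``y`` to treat as the control (non-diseased) class.
    n_grid : int
        Number of candidate slopes for the max-accuracy search.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
    control_fit_, diseased_fit_ : GroupFit-like (slope, intercept, n, r2)
    cutoff_ : CutoffLine
    """

    def __init__(
        self,
        cutoff_strategy: str = "max-accuracy",
        fixed_slope: float | None = None,
        anchor: str = "intersection",
        control_class="control",
        n_grid: int = 201,
    ):
        self.cutoff_strategy = cutoff_strategy
        self.fixed_slope = fixed_slope
        self.anchor = anchor
        self.control_class = control_class
        self.n_grid = n_grid

    def fit(self, X, y) -> "SlopeCutoffClassifier":
        X, y = check_X_y(X, y, ensure_2d=True)
        if X.shape[1] != 2:
            raise ValueError(
                f"X must have 2 columns (thickness_mm, dolp), got {X.shape[1]}"
            )
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"need exactly 2 classes, got {self.classes_!r}")
        if self.control_class not in self.classes_:
            raise ValueError(
                f"control_class {self.control_class!r} not among classes "
                f"{self.classes_!r}"
            )
        ctrl = y == self.control_class
        fits = {}
        for name, m in (("control", ctrl), ("diseased", ~ctrl)):
            t, d = X[m, 0], X[m, 1]
            if len(t) < 2 or np.ptp(t) == 0.0:
                raise ValueError(
                    f"degenerate predictor in {name} class: "
                    "need >= 2 distinct thicknesses"
                )
            slope, intercept, r2 = _ols_line(t, d)
            fits[name] = GroupFit(name, slope, intercept, int(m.sum()), r2)
        self.control_fit_ = fits["control"]
        self.diseased_fit_ = fits["diseased"]
        if self.control_fit_.slope == self.diseased_fit_.slope:
            raise ValueError("groups not separable by slope: fitted slopes are equal")
        at, ad = _anchor_point(self.control_fit_, self.diseased_fit_, self.anchor)
        if self.cutoff_strategy == "fixed":
            if self.fixed_slope is None:
                raise ValueError("cutoff_strategy='fixed' requires fixed_slope")
            self.cutoff_ = CutoffLine(float(self.fixed_slope), at, ad, "fixed")
        elif self.cutoff_strategy == "max-accuracy":
            lo, hi = sorted((self.control_fit_.slope, self.diseased_fit_.slope))
            candidates = np.linspace(lo, hi, self.n_grid + 2)[1:-1]
            mid = 0.5 * (lo + hi)
            truth = ~ctrl
            best = None
            for cand in candidates:
                line = CutoffLine(float(cand), at, ad, "max-accuracy")
                mask = _diseased_mask(X[:, 0], X[:, 1], line, "steeper")
                acc = float(np.mean(mask == truth))
                key = (acc, -abs(cand - mid), float(cand))
                if best is None or key > best:
                    best = key
            self.cutoff_ = CutoffLine(best[2], at, ad, "max-accuracy")
        else:
            raise ValueError(f"unknown cutoff_strategy {self.cutoff_strategy!r}")
        self.n_features_in_ = 2
        return self

    def predict(self, X):
        check_is_fitted(self, "cutoff_")
        X = check_array(X, ensure_2d=True)
        if X.shape[1] != 2:
            raise ValueError(
                f"X must have 2 columns (thickness_mm, dolp), got {X.shape[1]}"
            )
        mask = _diseased_mask(X[:, 0], X[:, 1], self.cutoff_, "steeper")
        diseased_class = self.classes_[self.classes_ != self.control_class][0]
        return np.where(mask, diseased_class, self.control_class)
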