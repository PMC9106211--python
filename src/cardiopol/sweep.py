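"""Reduction of rotating-polarizer voltage sweeps to Stokes parameters.

The instrument rotates its input polarizer from 0° to 180° in 10° steps and
records the photodiode voltage behind a fixed analyzer at each position.  For
any combination of linear polarization elements the detected intensity is
band-limited to the single 2θ harmonic,

    V(θ) = c0 + c1·cos 2θ + c2·sin 2θ,

so ordinary least squares on the basis {1, cos 2θ, sin 2θ} recovers the
coefficients exactly from a noiseless sweep (the 19-point grid heavily
oversamples one harmonic).  The linear Stokes parameters of the beam entering
the analyzer follow as (s1, s2, s3) = (2c0, 2c1, 2c2) in detector units and

    DOLP = sqrt(c1² + c2²) / c0.

Constant detector gain cancels in the ratio, so reductions are unit-invariant.
The circular component s4 is structurally zero here: a rotating linear
polarizer measures only the linear part of the state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .stokes import StokesVector

__all__ = ["AngularSweep", "SweepReduction", "reduce_sweep", "SweepReducer"]

#: default polarizer rotation grid (degrees)
DEFAULT_ANGLES_DEG = tuple(float(a) for a in range(0, 181, 10))

#: relative tolerance on modulation amplitude exceeding the mean level
OVERMODULATION_RTOL = 1e-6


@dataclass(frozen=True)
class AngularSweep:
    """One sample's detected voltage versus polarizer rotation angle.

    Angles are degrees in [0, 180], strictly increasing; voltages are mV and
    non-negative.  At least 5 points are required for a stable reduction.
    Both 0° and 180° may be present — they describe the same polarizer state
    and simply tighten the fit.
    """

    angles_deg: tuple[float, ...]
    voltages_mv: tuple[float, ...]
    sample_id: str = ""

    def __post_init__(self) -> None:
        ang = tuple(float(a) for a in self.angles_deg)
        vol = tuple(float(v) for v in self.voltages_mv)
        object.__setattr__(self, "angles_deg", ang)
        object.__setattr__(self, "voltages_mv", vol)
        if len(ang) != len(vol):
            raise ValueError(
                f"angle/voltage length mismatch: {len(ang)} vs {len(vol)}"
            )
        if len(ang) < 5:
            raise ValueError(f"sweep needs >= 5 points, got {len(ang)}")
        if any(b <= a for a, b in zip(ang, ang[1:])):
            raise ValueError("angles must be strictly increasing")
        if ang[0] < 0.0 or ang[-1] > 180.0:
            raise ValueError("angles must lie within [0, 180] degrees")
        if any(not math.isfinite(v) or v < 0 for v in vol):
            raise ValueError("voltages must be finite and >= 0")


@dataclass(frozen=True)
class SweepReduction:
    """Result of reducing one angular sweep: Stokes estimate + diagnostics."""

    stokes: StokesVector
    dolp: float
    r2: float
    residual_rms: float
    coefficients: tuple[float, float, float] = field(repr=False, default=(0.0, 0.0, 0.0))


def reduce_sweep(sweep: AngularSweep) -> SweepReduction:
    """Least-squares Fourier reduction of a rotating-polarizer sweep.

    Fits V(θ) = c0 + c1·cos2θ + c2·sin2θ and returns the linear Stokes
    estimate (2c0, 2c1, 2c2, 0) with fit diagnostics (R², residual RMS).

    Raises
    ------
    ValueError
        If the fitted mean level c0 is non-positive ("non-physical sweep")
        or the modulation amplitude exceeds c0 beyond tolerance
        ("over-modulated sweep"): both indicate data no linear optical train
        can produce.
    """
    theta = np.radians(np.asarray(sweep.angles_deg, dtype=float))
    v = np.asarray(sweep.voltages_mv, dtype=float)
    design = np.column_stack([np.ones_like(theta), np.cos(2 * theta), np.sin(2 * theta)])
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    c0, c1, c2 = (float(c) for c in coef)
    if c0 <= 0.0:
        raise ValueError(f"non-physical sweep: fitted mean level {c0:.6g} <= 0")
    amp = math.hypot(c1, c2)
    if amp > c0 * (1.0 + OVERMODULATION_RTOL):
        raise ValueError(
            f"over-modulated sweep: modulation {amp:.6g} exceeds mean level {c0:.6g}"
        )
    if amp > c0:  # within tolerance: clamp onto the physical boundary
        scale = c0 / amp
        c1, c2 = c1 * scale, c2 * scale
        amp = c0
    resid = v - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    if ss_tot > 0.0:
        r2 = 1.0 - ss_res / ss_tot
    else:  # constant signal: the fit is exact iff residuals vanish
        r2 = 1.0 if ss_res <= 1e-12 * max(1.0, float(v @ v)) else 0.0
    rms = math.sqrt(ss_res / len(v))
    stokes = StokesVector(2 * c0, 2 * c1, 2 * c2, 0.0, s4_measured=False)
    return SweepReduction(
        stokes=stokes,
        dolp=amp / c0,
        r2=r2,
        residual_rms=rms,
        coefficients=(c0, c1, c2),
    )


class SweepReducer(TransformerMixin, BaseEstimator):
    """Transformer turning voltage sweeps into Stokes parameters and DOLP.

    A stateless transformer (``fit`` only validates the angle grid) so the
    reduction can sit inside scikit-learn pipelines.  ``transform`` accepts
    either a sequence of :class:`AngularSweep` objects or an
    ``(n_sweeps, n_angles)`` voltage array sampled on ``angles_deg``.

    Parameters
    ----------
    angles_deg : sequence of float, default 0,10,…,180
        Rotation grid used when transforming plain arrays.

    Examples
    --------
    >>> import numpy as np
    >>> theta = np.radians(np.arange(0, 181, 10))
    >>> v = 10 * (1 + 0.4 * np.cos(2 * theta))
    >>> SweepReducer().transform([v])["dolp"].round(9).tolist()
    [0.4]
    """

    def __init__(self, angles_deg: tuple[float, ...] = DEFAULT_ANGLES_DEG):
        self.angles_deg = angles_deg

    def fit(self, X=None, y=None) -> "SweepReducer":
        grid = tuple(float(a) for a in self.angles_deg)
        AngularSweep(grid, (0.0,) * len(grid))  # validates the grid
        self.n_angles_ = len(grid)
        return self

    def transform(self, X):
        """Reduce each sweep; returns a DataFrame of Stokes/DOLP/diagnostics."""
        import pandas as pd

        if not hasattr(self, "n_angles_"):
            self.fit()
        rows = []
        for i, item in enumerate(X):
            if isinstance(item, AngularSweep):
                sweep = item
            else:
                sweep = AngularSweep(
                    tuple(float(a) for a in self.angles_deg),
                    tuple(float(v) for v in np.asarray(item, dtype=float)),
                    sample_id=str(i),
                )
            red = reduce_sweep(sweep)
            rows.append(
                {
                    "sample_id": sweep.sample_id or str(i),
                    "s1": red.stokes.s1,
                    "s2": red.stokes.s2,
                    "s3": red.stokes.s3,
                    "dolp": red.dolp,
                    "r2": red.r2,
                    "residual_rms": red.residual_rms,
                }
            )
        return pd.DataFrame(rows)
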