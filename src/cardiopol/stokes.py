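"""Stokes-vector algebra and the degree of linear polarization.

The polarization state of a light beam is described by four Stokes
parameters.  This package follows the 1-based numbering used in tissue
polarimetry instrumentation papers: ``s1`` is the total intensity (elsewhere
often written S0), ``s2`` the horizontal-minus-vertical linear component,
``s3`` the +45°-minus-−45° linear component and ``s4`` the right-minus-left
circular component.

The degree of linear polarization (DOLP) of a beam is

    DOLP = sqrt(s2² + s3²) / s1,

the fraction of the intensity that remains linearly polarized after the beam
has traversed a turbid medium such as myocardial tissue; 0 means fully
depolarized, 1 fully linearly polarized.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "StokesVector",
    "AnalyzerIntensities",
    "stokes_from_analyzer_intensities",
    "dolp",
]

#: relative tolerance for physicality and clamping checks
PHYSICALITY_RTOL = 1e-9


@dataclass(frozen=True)
class StokesVector:
    """A four-component polarization state in linear detector units.

    Parameters
    ----------
    s1 : float
        Total intensity; must be non-negative.
    s2 : float
        Horizontal minus vertical linearly polarized intensity.
    s3 : float
        +45° minus −45° linearly polarized intensity.
    s4 : float
        Right minus left circularly polarized intensity.
    s4_measured : bool
        False when the instrument had no circular analyzer and ``s4`` is a
        structural zero rather than a measurement.
    """

    s1: float
    s2: float = 0.0
    s3: float = 0.0
    s4: float = 0.0
    s4_measured: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        if not math.isfinite(self.s1) or self.s1 < 0:
            raise ValueError(f"s1 must be finite and >= 0, got {self.s1}")
        pol2 = self.s2**2 + self.s3**2 + self.s4**2
        lim = self.s1**2 * (1.0 + PHYSICALITY_RTOL) + PHYSICALITY_RTOL
        if pol2 > lim:
            raise ValueError(
                "unphysical Stokes vector: s2^2+s3^2+s4^2 = "
                f"{pol2:.6g} exceeds s1^2 = {self.s1**2:.6g}"
            )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.s1, self.s2, self.s3, self.s4)

    @property
    def dop(self) -> float:
        """Total degree of polarization sqrt(s2²+s3²+s4²)/s1."""
        if self.s1 <= 0:
            raise ValueError("degenerate intensity: s1 <= 0")
        return _clamped_ratio(math.sqrt(self.s2**2 + self.s3**2 + self.s4**2), self.s1)

    @property
    def dolp(self) -> float:
        """Degree of linear polarization sqrt(s2²+s3²)/s1."""
        return dolp(self)


@dataclass(frozen=True)
class AnalyzerIntensities:
    """Flux measurements behind the six standard polarization analyzers.

    ``i_hla``/``i_vla`` are the intensities behind horizontal and vertical
    linear analyzers, ``i_p45``/``i_m45`` behind ±45° linear analyzers and
    ``i_rca``/``i_lca`` behind right/left circular analyzers.  The circular
    pair is optional: the rotating-polarizer instrument modelled here carries
    no circular analyzer.
    """

    i_hla: float
    i_vla: float
    i_p45: float
    i_m45: float
    i_rca: float | None = None
    i_lca: float | None = None

    def __post_init__(self) -> None:
        for name in ("i_hla", "i_vla", "i_p45", "i_m45", "i_rca", "i_lca"):
            v = getattr(self, name)
            if v is None:
                continue
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"intensity {name} must be finite and >= 0, got {v}")
        if (self.i_rca is None) != (self.i_lca is None):
            raise ValueError("circular analyzer intensities must be given as a pair")

    @property
    def has_circular(self) -> bool:
        return self.i_rca is not None


def stokes_from_analyzer_intensities(
    ai: AnalyzerIntensities, *, consistency_rtol: float = 1e-6
) -> StokesVector:
    """Build a Stokes vector from the analyzer flux measurements.

    s1 = I_HLA + I_VLA, s2 = I_HLA − I_VLA, s3 = I_+45 − I_−45 and
    s4 = I_RCA − I_LCA; when the circular pair is absent s4 is set to 0 and
    flagged unmeasured.  The pairwise sums I_HLA+I_VLA and I_+45+I_−45 both
    estimate the total intensity; a mismatch beyond ``consistency_rtol``
    raises a warning (the measurement is noisy, not invalid).
    """
    s1 = ai.i_hla + ai.i_vla
    s2 = ai.i_hla - ai.i_vla
    s3 = ai.i_p45 - ai.i_m45
    sum45 = ai.i_p45 + ai.i_m45
    if abs(s1 - sum45) > consistency_rtol * max(s1, sum45, 1e-300):
        warnings.warn(
            f"analyzer pair sums disagree: HLA+VLA = {s1:.6g} vs "
            f"+45+(-45) = {sum45:.6g}",
            stacklevel=2,
        )
    if ai.has_circular:
        return StokesVector(s1, s2, s3, ai.i_rca - ai.i_lca, s4_measured=True)
    return StokesVector(s1, s2, s3, 0.0, s4_measured=False)


def _clamped_ratio(num: float, den: float) -> float:
    r = num / den
    if r > 1.0:
        if r > 1.0 + PHYSICALITY_RTOL:
            raise ValueError(f"polarization fraction {r:.12g} exceeds 1 beyond tolerance")
        return 1.0
    return r


def dolp(s: StokesVector) -> float:
    """Degree of linear polarization of a physical Stokes vector.

    Returns sqrt(s2²+s3²)/s1, clamped to 1 only when the overshoot is within
    the numerical physicality tolerance; larger overshoots and non-positive
    intensities are errors.
    """
    if s.s1 <= 0:
        raise ValueError("degenerate intensity: s1 <= 0")
    return _clamped_ratio(math.hypot(s.s2, s.s3), s.s1)
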