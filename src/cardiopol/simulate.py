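"""Forward simulator of the rotating-polarizer instrument and study cohorts.

The physical instrument is an unpolarized 850 nm LED, a rotating linear
polarizer stepped 0°–180° in 10° increments, the tissue sample, a fixed
linear analyzer and a photodiode read out in mV.  The simulator realizes this
train in Mueller calculus: at each grid angle θ the source Stokes vector
(I₀, 0, 0, 0) is propagated through

    polarizer(θ) → [retarder] → depolarizer(d) → analyzer(0°),

the emerging intensity is converted to mV by a detector gain and additive
Gaussian noise is applied.  Without birefringence the detected voltage has
the closed form V(θ) = (I₀·gain/4)·(1 + d·cos 2θ), so the sweep reduction
recovers DOLP = d exactly on noiseless data.

Tissue is summarized by a group-level line DOLP = intercept + slope·thickness:
depolarization accumulates with path length, and fibrotic remodelling of the
myocardium changes the rate.  The cohort generator draws per-sample
thicknesses from truncated normals, evaluates the group line plus Gaussian
scatter to obtain each sample's depolarization factor, simulates the sweep
and reduces it — so synthetic cohorts exercise the entire measurement chain,
not just the final regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import truncnorm

from .cohort import TissueSample
from .mueller import (
    chain,
    mueller_depolarizer,
    mueller_linear_polarizer,
    mueller_linear_retarder,
)
from .stokes import StokesVector
from .sweep import DEFAULT_ANGLES_DEG, AngularSweep, reduce_sweep

__all__ = [
    "InstrumentConfig",
    "TissueModel",
    "simulate_sweep",
    "simulate_cohort",
    "study_tissue_models",
]

#: minimum physical tissue thickness (mm); thickness draws truncate here
MIN_THICKNESS_MM = 0.1

#: published group slopes of the DOLP-vs-thickness lines (mm^-1)
STUDY_SLOPES = {"control": -0.0422, "RHD": -0.0808, "MV": -0.1699}

#: published thickness mean ± SD per (group, ventricle), in mm
STUDY_THICKNESS_MM = {
    ("control", "LV"): (1.657, 0.135),
    ("control", "RV"): (1.821, 0.145),
    ("RHD", "LV"): (1.396, 0.082),
    ("RHD", "RV"): (1.493, 0.142),
    ("MV", "LV"): (0.867, 0.142),
    ("MV", "RV"): (0.857, 0.098),
}

#: published group-mean DOLP per (group, ventricle)
STUDY_MEAN_DOLP = {
    ("control", "LV"): 0.088,
    ("control", "RV"): 0.059,
    ("RHD", "LV"): 0.089,
    ("RHD", "RV"): 0.077,
    ("MV", "LV"): 0.097,
    ("MV", "RV"): 0.121,
}


@dataclass(frozen=True)
class InstrumentConfig:
    """Instrument parameters of the forward model.

    ``source_intensity`` is in arbitrary source units; with the default gain
    of 1 mV per unit the noiseless detected voltage spans roughly
    250·(1 ± d) mV, comparable to a photodiode amplifier output.
    ``noise_sd_mv`` is the SD of additive Gaussian detector noise per
    reading; 1 mV is a few tenths of a percent of the mean level, a
    realistic figure for a modulated, ambient-light-rejecting readout.
    """

    source_intensity: float = 1000.0
    analyzer_angle_deg: float = 0.0
    angle_grid_deg: tuple[float, ...] = DEFAULT_ANGLES_DEG
    noise_sd_mv: float = 1.0
    gain_mv_per_unit: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.source_intensity <= 0:
            raise ValueError("source_intensity must be > 0")
        if self.noise_sd_mv < 0:
            raise ValueError("noise_sd_mv must be >= 0")
        if self.gain_mv_per_unit <= 0:
            raise ValueError("gain_mv_per_unit must be > 0")
        grid = tuple(float(a) for a in self.angle_grid_deg)
        object.__setattr__(self, "angle_grid_deg", grid)
        AngularSweep(grid, (0.0,) * len(grid))  # validates grid shape/order


@dataclass(frozen=True)
class TissueModel:
    """Group-level statistical model of tissue optical behaviour.

    The per-sample depolarization factor is
    d = clamp(dolp_at_zero_thickness + slope_per_mm · thickness, 0, 1); the
    optional retardance models myocardial fiber birefringence.
    """

    dolp_at_zero_thickness: float
    slope_per_mm: float
    thickness_mean_mm: float
    thickness_sd_mm: float
    retardance_deg: float = 0.0
    retarder_axis_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.thickness_mean_mm <= MIN_THICKNESS_MM:
            raise ValueError(
                f"thickness_mean_mm must exceed {MIN_THICKNESS_MM} mm"
            )
        if self.thickness_sd_mm < 0:
            raise ValueError("thickness_sd_mm must be >= 0")

    def depolarization_at(self, thickness_mm: float) -> float:
        return float(
            np.clip(
                self.dolp_at_zero_thickness + self.slope_per_mm * thickness_mm,
                0.0,
                1.0,
            )
        )


def study_tissue_models() -> dict[str, dict[str, TissueModel]]:
    """Tissue models parameterized at the published study conditions.

    Returns one model per (group, ventricle).  Slopes and thickness
    statistics are the published values; the line intercepts (not published)
    are anchored so each group's line passes through its pooled mean
    (thickness, DOLP) point.
    """
    models: dict[str, dict[str, TissueModel]] = {}
    for group, slope in STUDY_SLOPES.items():
        t_mean = np.mean([STUDY_THICKNESS_MM[group, v][0] for v in ("LV", "RV")])
        d_mean = np.mean([STUDY_MEAN_DOLP[group, v] for v in ("LV", "RV")])
        intercept = float(d_mean - slope * t_mean)
        models[group] = {
            v: TissueModel(
                dolp_at_zero_thickness=intercept,
                slope_per_mm=slope,
                thickness_mean_mm=STUDY_THICKNESS_MM[group, v][0],
                thickness_sd_mm=STUDY_THICKNESS_MM[group, v][1],
            )
            for v in ("LV", "RV")
        }
    return models


def simulate_sweep(
    tissue_d: float,
    instrument: InstrumentConfig | None = None,
    *,
    retardance_deg: float = 0.0,
    retarder_axis_deg: float = 0.0,
    rng: np.random.Generator | None = None,
    sample_id: str = "",
) -> AngularSweep:
    """Simulate one rotating-polarizer voltage sweep through a tissue model.

    ``tissue_d`` is the fraction of polarization the tissue retains.  Noise
    is drawn from ``rng`` when given, else from the instrument's seed; a
    noise SD of zero yields the exact closed-form sweep.  Voltages are
    clipped at 0 (a photodiode cannot report negative flux).
    """
    if not (0.0 <= tissue_d <= 1.0):
        raise ValueError(f"tissue_d must be in [0, 1], got {tissue_d}")
    instrument = instrument or InstrumentConfig()
    if rng is None:
        rng = np.random.default_rng(instrument.seed)
    source = StokesVector(instrument.source_intensity, s4_measured=False)
    tissue_elements = []
    if retardance_deg != 0.0:
        tissue_elements.append(
            mueller_linear_retarder(retardance_deg, retarder_axis_deg)
        )
    tissue_elements.append(mueller_depolarizer(tissue_d))
    analyzer = mueller_linear_polarizer(instrument.analyzer_angle_deg)
    voltages = []
    for theta in instrument.angle_grid_deg:
        train = chain([mueller_linear_polarizer(theta), *tissue_elements, analyzer])
        intensity = train.apply(source).s1
        v = intensity * instrument.gain_mv_per_unit
        if instrument.noise_sd_mv > 0:
            v += rng.normal(0.0, instrument.noise_sd_mv)
        voltages.append(max(v, 0.0))
    return AngularSweep(instrument.angle_grid_deg, tuple(voltages), sample_id)


def _as_per_ventricle(model) -> dict[str, TissueModel]:
    if isinstance(model, TissueModel):
        return {"LV": model, "RV": model}
    return dict(model)


def simulate_cohort(
    group_models: dict[str, TissueModel | dict[str, TissueModel]] | None = None,
    n_per_group: int | dict[str, int] = 7,
    instrument: InstrumentConfig | None = None,
    *,
    dolp_noise_sd: float = 0.02,
    seed: int | None = None,
    return_sweeps: bool = False,
):
    """Generate a synthetic cohort through the full measurement chain.

    For each subject and ventricle: draw a thickness from the group's
    truncated normal, evaluate the group DOLP line plus Gaussian scatter
    (``dolp_noise_sd``, the biological spread about the line), simulate the
    voltage sweep and reduce it to the measured DOLP.  Identical seeds
    produce bit-identical cohorts.

    Parameters
    ----------
    group_models : mapping group name → TissueModel or {ventricle: TissueModel}
        Defaults to :func:`study_tissue_models`.
    n_per_group : int or mapping group → int
        Subjects per group; each subject contributes one LV and one RV sample.

    Returns
    -------
    list[TissueSample], or (samples, sweeps) when ``return_sweeps``.
    """
    if group_models is None:
        group_models = study_tissue_models()
    instrument = instrument or InstrumentConfig()
    if dolp_noise_sd < 0:
        raise ValueError("dolp_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    samples: list[TissueSample] = []
    sweeps: list[AngularSweep] = []
    for group in group_models:
        per_vent = _as_per_ventricle(group_models[group])
        n = n_per_group[group] if isinstance(n_per_group, dict) else n_per_group
        if n < 2:
            raise ValueError(f"need >= 2 subjects per group, got {n} for {group}")
        for i in range(1, n + 1):
            subject = f"{group}-{i:02d}"
            for ventricle in ("LV", "RV"):
                model = per_vent[ventricle]
                if model.thickness_sd_mm > 0:
                    a = (MIN_THICKNESS_MM - model.thickness_mean_mm) / model.thickness_sd_mm
                    t = float(
                        truncnorm.rvs(
                            a,
                            np.inf,
                            loc=model.thickness_mean_mm,
                            scale=model.thickness_sd_mm,
                            random_state=rng,
                        )
                    )
                else:
                    t = model.thickness_mean_mm
                d = model.depolarization_at(t)
                if dolp_noise_sd > 0:
                    d = float(np.clip(d + rng.normal(0.0, dolp_noise_sd), 0.0, 1.0))
                sweep = simulate_sweep(
                    d,
                    instrument,
                    retardance_deg=model.retardance_deg,
                    retarder_axis_deg=model.retarder_axis_deg,
                    rng=rng,
                    sample_id=f"{subject}-{ventricle}",
                )
                measured = reduce_sweep(sweep).dolp
                samples.append(
                    TissueSample(subject, group, ventricle, t, measured)
                )
                if return_sweeps:
                    sweeps.append(sweep)
    if return_sweeps:
        return samples, sweeps
    return samples
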