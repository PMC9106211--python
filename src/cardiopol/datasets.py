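"""Packaged reference data.

The study cohort's per-subject DOLP values — 7 control, 7 rheumatic heart
disease (RHD) and 3 myxomatous valve (MV) disease subjects, one left- and one
right-ventricle specimen each — ship as a small CSV so the group summary
statistics can be recomputed without the instrument.  Per-sample thicknesses
were not published, so the ``thickness_mm`` field is empty and these records
support summaries only, not slope fits.
"""

from __future__ import annotations

from importlib.resources import files

from .cohort import TissueSample
from .io import read_samples

__all__ = ["load_study_dolp", "study_dolp_path"]


def study_dolp_path():
    """Path to the packaged per-subject DOLP table."""
    return files("cardiopol.data").joinpath("study_cohort_dolp.csv")


def load_study_dolp(group: str | None = None) -> list[TissueSample]:
    """Load the study cohort's per-subject DOLP records.

    Parameters
    ----------
    group : {"control", "RHD", "MV"}, optional
        Restrict to one clinical group; default returns all 34 records.
    """
    samples = read_samples(study_dolp_path())
    if group is not None:
        samples = [s for s in samples if s.group == group]
        if not samples:
            raise ValueError(f"unknown group {group!r}")
    return samples
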