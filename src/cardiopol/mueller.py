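"""Mueller calculus for the polarizer–tissue–analyzer optical train.

A Mueller matrix is the 4×4 real transfer matrix of an optical element acting
on Stokes vectors; element chains compose by matrix multiplication in
propagation order.  Three idealized elements suffice to model the instrument:

* a linear polarizer at transmission axis θ (the rotating input polarizer and
  the fixed analyzer),
* a pure depolarizer diag(1, d, d, d), modelling the scattering loss of
  polarization in turbid tissue — d is the fraction of polarization retained,
* a linear retarder, modelling the intrinsic birefringence of ordered
  myocardial fibers.

All angles are degrees externally; rotations use the 2θ convention of Stokes
space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .stokes import StokesVector

__all__ = [
    "MuellerMatrix",
    "mueller_linear_polarizer",
    "mueller_depolarizer",
    "mueller_linear_retarder",
    "chain",
]


@dataclass(frozen=True)
class MuellerMatrix:
    """4×4 real transfer matrix with rows/columns ordered (s1, s2, s3, s4)."""

    m: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.m, dtype=float)
        if arr.shape != (4, 4):
            raise ValueError(f"Mueller matrix must be 4x4, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("Mueller matrix entries must be finite")
        object.__setattr__(self, "m", arr)

    def apply(self, s: StokesVector | Sequence[float]) -> StokesVector:
        """Propagate a Stokes vector through this element."""
        vec = s.as_tuple() if isinstance(s, StokesVector) else tuple(s)
        out = self.m @ np.asarray(vec, dtype=float)
        # matmul round-off may leave a tiny negative intensity on extinction
        s1 = out[0] if out[0] > 0 else 0.0
        measured = s.s4_measured if isinstance(s, StokesVector) else True
        return StokesVector(s1, out[1], out[2], out[3], s4_measured=measured)

    def __matmul__(self, other: "MuellerMatrix") -> "MuellerMatrix":
        return MuellerMatrix(self.m @ other.m)

    @classmethod
    def identity(cls) -> "MuellerMatrix":
        return cls(np.eye(4))


def mueller_linear_polarizer(theta_deg: float) -> MuellerMatrix:
    """Ideal linear polarizer with transmission axis at ``theta_deg``.

    The angle is reduced mod 180° (a polarizer axis is a direction, not a
    vector).  m[0,0] = 0.5: an ideal polarizer passes half of unpolarized
    light.
    """
    t = math.radians(theta_deg % 180.0)
    c, s = math.cos(2 * t), math.sin(2 * t)
    m = 0.5 * np.array(
        [
            [1.0, c, s, 0.0],
            [c, c * c, c * s, 0.0],
            [s, c * s, s * s, 0.0],
            [0.0, 0.0, 0.0, 0.0],
        ]
    )
    return MuellerMatrix(m)


def mueller_depolarizer(d: float) -> MuellerMatrix:
    """Isotropic partial depolarizer diag(1, d, d, d).

    ``d`` is the fraction of polarization retained: d=1 leaves the state
    untouched, d=0 fully depolarizes.
    """
    if not (0.0 <= d <= 1.0):
        raise ValueError(f"depolarization factor must be in [0, 1], got {d}")
    return MuellerMatrix(np.diag([1.0, d, d, d]))


def mueller_linear_retarder(delta_deg: float, axis_deg: float = 0.0) -> MuellerMatrix:
    """Linear retarder with retardance ``delta_deg`` and fast axis ``axis_deg``.

    Leaves the total intensity unchanged and rotates the polarized part of
    the Stokes vector (determinant 1), so the total degree of polarization is
    preserved.
    """
    delta = math.radians(delta_deg)
    c, s = math.cos(2 * math.radians(axis_deg)), math.sin(2 * math.radians(axis_deg))
    cd, sd = math.cos(delta), math.sin(delta)
    m = np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, c * c + s * s * cd, c * s * (1 - cd), -s * sd],
            [0.0, c * s * (1 - cd), s * s + c * c * cd, c * sd],
            [0.0, s * sd, -c * sd, cd],
        ]
    )
    return MuellerMatrix(m)


def chain(elements: Iterable[MuellerMatrix]) -> MuellerMatrix:
    """Compose an ordered element list, first element applied first.

    ``chain([A, B, C])`` returns the matrix C·B·A so that applying the result
    equals applying A, then B, then C.
    """
    elems = list(elements)
    if not elems:
        raise ValueError("chain requires at least one element")
    m = elems[0].m
    for e in elems[1:]:
        m = e.m @ m
    return MuellerMatrix(m)
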