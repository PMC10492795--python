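"""Nonlinear concentration -> phenotype linking functions.

Three monotone-increasing shapes through (0, 0) and (1, 1) with a single
curvature parameter m >= 0:

* concave:    y = (exp(-m (x-1)) - exp(m)) / (1 - exp(m))
* convex:     y = (exp( m (x-1)) - exp(-m)) / (1 - exp(-m))
* sigmoidal:  y = (e^m + 1)/(e^m - 1) * (1/(1 + e^{-2m(x-0.5)}) - 1/(1 + e^m))

Larger m means larger curvature; at m = 0 every shape degenerates to the
identity (the printed formulas are 0/0 there, so small m is evaluated as the
identity to avoid catastrophic cancellation).  All shapes have analytic
inverses, used for phenotype -> concentration inversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["LINK_KINDS", "LinkingSpec", "apply_linking", "invert_linking"]

LINK_KINDS = ("linear", "concave", "convex", "sigmoidal")

#: below this curvature the formulas are evaluated as the identity
_M_IDENTITY = 1e-6


@dataclass(frozen=True)
class LinkingSpec:
    """Shape and curvature of the concentration-phenotype relationship."""

    kind: str = "linear"
    m: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in LINK_KINDS:
            raise ValueError(f"kind must be one of {LINK_KINDS}, got {self.kind!r}")
        if not (math.isfinite(self.m) and self.m >= 0):
            raise ValueError(f"m must be finite and >= 0, got {self.m}")

    @property
    def is_identity(self) -> bool:
        return self.kind == "linear" or self.m < _M_IDENTITY


def apply_linking(x, spec: LinkingSpec):
    """Transform a concentration-scale phenotype through the linking curve.

    Accepts scalars or arrays.  The working domain extends slightly above 1
    (grids run to 1.02 AU); the (0,0)/(1,1) anchoring holds exactly.
    """
    x = np.asarray(x, dtype=float)
    if spec.is_identity:
        out = x.copy()
    else:
        m = spec.m
        em = math.exp(m)
        if spec.kind == "concave":
            out = (np.exp(-m * (x - 1.0)) - em) / (1.0 - em)
        elif spec.kind == "convex":
            emn = math.exp(-m)
            out = (np.exp(m * (x - 1.0)) - emn) / (1.0 - emn)
        elif spec.kind == "sigmoidal":
            out = (em + 1.0) / (em - 1.0) * (
                1.0 / (1.0 + np.exp(-2.0 * m * (x - 0.5))) - 1.0 / (1.0 + em)
            )
        else:  # pragma: no cover - guarded by LinkingSpec
            raise ValueError(f"unknown linking kind {spec.kind!r}")
    return float(out) if out.ndim == 0 else out


def invert_linking(y, spec: LinkingSpec):
    """Map a transformed phenotype back to the concentration scale.

    Uses the closed-form inverse of each shape.  Values outside the image of
    the curve raise a ValueError reporting the attainable bounds.
    """
    y = np.asarray(y, dtype=float)
    if spec.is_identity:
        out = y.copy()
    else:
        m = spec.m
        em = math.exp(m)
        if spec.kind == "concave":
            # x = 1 - ln(y (1 - e^m) + e^m) / m ; argument must stay positive
            arg = y * (1.0 - em) + em
            _check_image(arg > 0.0, y, upper=em / (em - 1.0), lower=-math.inf)
            out = 1.0 - np.log(arg) / m
        elif spec.kind == "convex":
            emn = math.exp(-m)
            arg = y * (1.0 - emn) + emn
            _check_image(arg > 0.0, y, upper=math.inf, lower=-emn / (1.0 - emn))
            out = 1.0 + np.log(arg) / m
        elif spec.kind == "sigmoidal":
            z = y * (em - 1.0) / (em + 1.0) + 1.0 / (1.0 + em)
            _check_image(
                (z > 0.0) & (z < 1.0),
                y,
                upper=(1.0 - 1.0 / (1.0 + em)) * (em + 1.0) / (em - 1.0),
                lower=-1.0 / (em - 1.0),
            )
            out = 0.5 - np.log(1.0 / z - 1.0) / (2.0 * m)
        else:  # pragma: no cover
            raise ValueError(f"unknown linking kind {spec.kind!r}")
    return float(out) if out.ndim == 0 else out


def _check_image(ok, y, *, upper: float, lower: float) -> None:
    if not np.all(ok):
        bad = np.asarray(y)[~np.asarray(ok)]
        raise ValueError(
            f"value(s) {bad!r} outside the image of the linking curve "
            f"(attainable open interval ({lower:g}, {upper:g}))"
        )
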