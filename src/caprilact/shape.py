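"""Curve-shape summaries: peak and persistency of a fitted lactation curve.

For the Ali–Schaeffer model the peak is read as the level parameter b0 and
persistency as the pair (b1, b2) governing the late-lactation decline.  For
the parabolic yield-density model y = 1/(b0 + b1 t + b2 t^2) the peak is
-b1/(2 b2) (the stationary point of the denominator) and persistency the
scalar 2*b0*days + b1, with ``days`` defaulting to the 210-day horizon.
Both read-ins are isolated here so an alternative interpretation is a
one-line change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import DomainError

#: Default "Days" constant in the parabolic yield-density persistency.
DEFAULT_DAYS = 210.0


@dataclass(frozen=True)
class CurveShape:
    """Peak/persistency summary of one fitted curve."""

    trait: str
    model_id: str
    peak: float
    persistency_b1: Optional[float] = None
    persistency_b2: Optional[float] = None
    persistency_scalar: Optional[float] = None


def shape_ali_schaeffer(b, trait: str = "") -> CurveShape:
    """Peak = b0; persistency = (b1, b2).  Ignores b3, b4."""
    b = np.asarray(b, dtype=float)
    return CurveShape(
        trait=trait,
        model_id="ali_schaeffer",
        peak=float(b[0]),
        persistency_b1=float(b[1]),
        persistency_b2=float(b[2]),
    )


def shape_pyd(b, days: float = DEFAULT_DAYS, trait: str = "") -> CurveShape:
    """Peak = -b1/(2 b2); persistency = 2*b0*days + b1.

    Undefined when b2 = 0 (no stationary point).
    """
    b = np.asarray(b, dtype=float)
    if b[2] == 0.0:
        raise DomainError("peak undefined for b2 = 0")
    return CurveShape(
        trait=trait,
        model_id="parabolic_yield_density",
        peak=float(-b[1] / (2.0 * b[2])),
        persistency_scalar=float(2.0 * b[0] * days + b[1]),
    )
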