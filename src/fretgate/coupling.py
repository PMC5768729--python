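"""Thermodynamic coupling bound between two conformational gates.

For two binary conformational coordinates with marginal occupancies p(x) and
p(y), the thermodynamic coupling function

    ddA(x, y) = -kT * log( p(x, y) / (p(x) * p(y)) )

measures the free-energy cost of co-occupancy relative to independence
(positive = the joint state is destabilized).  When only the marginals are
known, the joint probability is bounded below by the Fréchet-type limit

    p'(x, y) = min(p(x), p(y)) - (1 - max(p(x), p(y)))

(floored at 0), which yields the *maximum* possible destabilization of the
joint state consistent with the observed marginals.  Applied to the low-FRET
(open) occupancies measured on the intracellular and extracellular faces of
a transporter, this bounds how strongly one gate's opening can disfavor the
other's.  Energies are in units of kT (kT = 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass


@dataclass(frozen=True)
class GateMarginals:
    """Low-FRET (open-state) occupancy of each face."""

    p_low_ic: float
    p_low_ec: float

    def __post_init__(self) -> None:
        for p in (self.p_low_ic, self.p_low_ec):
            if not 0.0 <= p <= 1.0:
                raise ValueError("occupancies must be in [0, 1]")


@dataclass(frozen=True)
class TcfResult:
    """Coupling-bound estimate from marginal occupancies."""

    joint_estimate: float       # minimal joint probability p'
    independence_joint: float   # p(x) * p(y)
    delta_delta_a: float        # kT; +inf when p' = 0


def tcf(p_x: float, p_y: float, p_xy: float) -> float:
    """Thermodynamic coupling free energy -log(p_xy / (p_x p_y)) in kT."""
    if not (0.0 < p_x <= 1.0 and 0.0 < p_y <= 1.0):
        raise ValueError("marginal probabilities must be in (0, 1]")
    if not 0.0 <= p_xy <= 1.0:
        raise ValueError("joint probability must be in [0, 1]")
    if p_xy == 0.0:
        return math.inf
    return -math.log(p_xy / (p_x * p_y))


def min_joint(p_x: float, p_y: float) -> float:
    """Smallest joint probability consistent with the marginals, floored at 0:
    ``min(p_x, p_y) - (1 - max(p_x, p_y))``."""
    if not (0.0 <= p_x <= 1.0 and 0.0 <= p_y <= 1.0):
        raise ValueError("probabilities must be in [0, 1]")
    return max(0.0, min(p_x, p_y) - (1.0 - max(p_x, p_y)))


def estimate_max_destabilization(marginals: GateMarginals) -> TcfResult:
    """Upper bound on the allosteric destabilization of the doubly open state.

    Composes the minimal-joint bound with the coupling function.  Meaningful
    when both marginals exceed 0.5 (otherwise the bound degenerates to a zero
    joint probability and an infinite coupling sentinel, with a warning).
    """
    p_x, p_y = marginals.p_low_ic, marginals.p_low_ec
    p_min = min_joint(p_x, p_y)
    if p_min == 0.0:
        warnings.warn(
            "both marginals must exceed 0.5 for a finite bound; "
            "minimal joint probability is 0 and the coupling bound is infinite",
            RuntimeWarning,
        )
        return TcfResult(0.0, p_x * p_y, math.inf)
    return TcfResult(p_min, p_x * p_y, tcf(p_x, p_y, p_min))
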