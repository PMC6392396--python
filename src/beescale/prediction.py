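"""Prediction results and registry-equation evaluation.

Every prediction in this package -- from a fitted hierarchical model or
from a registered literature equation -- is reported the same way: a
point estimate in the response's units, a standard error, and a 90%
interval.  For equations the interval comes from the equation's ln-scale
residual SD (lognormal error); equations published without one yield a
point-only result that says so.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy import stats

from .registry import AllometricEquation, find_equations

__all__ = ["PredictionResult", "predict_from_equation", "derived_trait", "TRAIT_RESPONSES"]


@dataclass(frozen=True)
class PredictionResult:
    """A point prediction with uncertainty on the response scale.

    ``scale_note`` records how the back-transform was done (posterior
    median of exponentiated draws, lognormal quantiles, or point-only).
    """

    point: float
    se: float
    ci_low: float
    ci_high: float
    scale_note: str
    level: float = 0.90

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError(
                f"interval ({self.ci_low}, {self.ci_high}) does not bracket point {self.point}"
            )
        if self.point <= 0:
            raise ValueError("predictions on a positive response must be positive")

    @property
    def ci90(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)


def predict_from_equation(
    eq: AllometricEquation,
    x: float,
    level: float = 0.90,
    smearing: bool = False,
) -> PredictionResult:
    """Evaluate a registered power law at x with lognormal uncertainty.

    The point estimate is the conditional median exp(alpha + beta*ln x);
    with ``smearing`` the mean correction exp(sigma^2/2) is applied
    instead (off by default).  When the equation has no residual SD the
    result is point-only with zero-width interval and a flagging note.
    """
    if not (x > 0):
        raise ValueError(f"predictor value must be positive, got {x!r}")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    m = eq.alpha + eq.beta * math.log(x)
    if eq.sigma_resid is None:
        point = math.exp(m)
        return PredictionResult(point, 0.0, point, point,
                                scale_note="point-only (no residual SD registered)",
                                level=level)
    s = eq.sigma_resid
    z = stats.norm.ppf(0.5 + level / 2)
    point = math.exp(m + (s * s / 2 if smearing else 0.0))
    sd = math.sqrt((math.exp(s * s) - 1.0) * math.exp(2 * m + s * s))
    note = "lognormal quantiles" + (", smearing mean" if smearing else ", median")
    return PredictionResult(point, sd, math.exp(m - z * s), math.exp(m + z * s),
                            scale_note=note, level=level)


#: derived trait name -> registry response label
TRAIT_RESPONSES = {
    "foraging_distance": "foraging_distance_km",
    "tongue_length": "tongue_length_mm",
    "wing_loading": "wing_loading",
    "nectar_load": "nectar_load_mg",
}


def derived_trait(
    registry: Sequence[AllometricEquation],
    trait_name: str,
    x: float,
    scope: Mapping[str, str] | None = None,
    predictor: str = "itd_mm",
    level: float = 0.90,
) -> PredictionResult:
    """Convert a body-size proxy into a derived trait via the registry.

    Looks up the most specific registered equation for the trait whose
    scope covers the query (e.g. ``{"taxon": "Apidae"}`` for tongue
    length) and evaluates it at ``x``.  Raises KeyError naming the gap
    when no equation covers the requested scope.
    """
    if trait_name not in TRAIT_RESPONSES:
        raise ValueError(
            f"unknown trait {trait_name!r}; expected one of {sorted(TRAIT_RESPONSES)}"
        )
    response = TRAIT_RESPONSES[trait_name]
    hits = find_equations(registry, response, predictor=predictor, scope=scope)
    if not hits:
        raise KeyError(
            f"no registered {trait_name} equation for predictor {predictor!r} "
            f"and scope {dict(scope or {})!r}"
        )
    return predict_from_equation(hits[0], x, level=level)
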