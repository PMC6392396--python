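"""Registry of published allometric power-law equations.

Every registered equation is stored in one canonical form,

    ln(y) = alpha + beta * ln(x)

where ``alpha`` is the ln-scale intercept ln(a) of the power law
``y = a * x^beta``.  Equations published on other scales (base-10 logs,
untransformed power laws) are converted to this form when transcribed.
Each equation carries its response and predictor trait, an applicability
scope (taxon / sex / region), optional ln-scale residual SD, and a source
citation.

The packaged registry (``data/registry.json``) mixes one transcribed
literature equation (Cane 1987, bee dry weight from ITD) with
synthetic-labelled example equations that exercise every trait class;
the synthetic entries carry illustrative coefficients, not published
values, and say so in their ``source`` field.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "RESPONSES",
    "PREDICTORS",
    "AllometricEquation",
    "load_registry",
    "load_packaged_registry",
    "registry_from_csv",
    "find_equations",
    "evaluate_equation",
]

RESPONSES = (
    "dry_weight_mg",
    "foraging_distance_km",
    "tongue_length_mm",
    "wing_loading",
    "nectar_load_mg",
)
PREDICTORS = ("itd_mm", "body_length_mm", "head_width_mm", "body_length_x_width")


@dataclass(frozen=True)
class AllometricEquation:
    """One registered power-law conversion, ln(y) = alpha + beta*ln(x).

    ``scope`` holds the applicability constraints actually published with
    the equation; keys are any of ``taxon`` (order / family / genus label),
    ``sex`` and ``region``.  An absent key means "not restricted".
    ``sigma_resid`` is the ln-scale residual SD when the source reports
    one; predictions from equations without it are point-only.
    """

    eq_id: str
    response: str
    predictor: str
    alpha: float
    beta: float
    scope: Mapping[str, str] = dc_field(default_factory=dict)
    sigma_resid: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(f"{self.eq_id}: unknown response {self.response!r}")
        if self.predictor not in PREDICTORS:
            raise ValueError(f"{self.eq_id}: unknown predictor {self.predictor!r}")
        if not (math.isfinite(self.alpha) and math.isfinite(self.beta)):
            raise ValueError(f"{self.eq_id}: alpha/beta must be finite")
        if not self.scope:
            raise ValueError(f"{self.eq_id}: scope must be non-empty")
        if self.sigma_resid is not None and self.sigma_resid < 0:
            raise ValueError(f"{self.eq_id}: sigma_resid must be >= 0")


def _build(entries: Iterable[Mapping]) -> list[AllometricEquation]:
    eqs: list[AllometricEquation] = []
    seen: set[str] = set()
    for entry in entries:
        eq = AllometricEquation(
            eq_id=entry["eq_id"],
            response=entry["response"],
            predictor=entry["predictor"],
            alpha=float(entry["alpha"]),
            beta=float(entry["beta"]),
            scope=dict(entry.get("scope") or {}),
            sigma_resid=(None if entry.get("sigma_resid") in (None, "")
                         else float(entry["sigma_resid"])),
            source=entry.get("source", ""),
        )
        if eq.eq_id in seen:
            raise ValueError(f"duplicate eq_id {eq.eq_id!r} in registry")
        seen.add(eq.eq_id)
        eqs.append(eq)
    return eqs


def load_registry(path: str | Path) -> list[AllometricEquation]:
    """Load a JSON registry (a list of equation objects)."""
    with Path(path).open(encoding="utf-8") as fh:
        return _build(json.load(fh))


def load_packaged_registry() -> list[AllometricEquation]:
    """Load the registry shipped with the package."""
    text = resources.files("beescale").joinpath("data/registry.json").read_text("utf-8")
    return _build(json.loads(text))


def registry_from_csv(path: str | Path) -> list[AllometricEquation]:
    """CSV import path: columns eq_id,response,predictor,alpha,beta,
    sigma_resid,taxon,sex,region,source (scope columns may be blank)."""
    entries = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            scope = {k: row[k].strip() for k in ("taxon", "sex", "region")
                     if row.get(k, "").strip()}
            entries.append({**row, "scope": scope})
    return _build(entries)


def find_equations(
    registry: Sequence[AllometricEquation],
    response: str,
    predictor: str | None = None,
    scope: Mapping[str, str] | None = None,
) -> list[AllometricEquation]:
    """All equations whose scope covers the query, most specific first.

    An equation matches when its response (and predictor, if queried)
    agree and every scope key it declares is either absent from the query
    (unconstrained query accepts any value) or equal to the query's
    value.  "Most specific first" = more declared-and-matched scope keys
    sort earlier.
    """
    scope = dict(scope or {})
    hits: list[tuple[int, AllometricEquation]] = []
    for eq in registry:
        if eq.response != response:
            continue
        if predictor is not None and eq.predictor != predictor:
            continue
        specificity = 0
        ok = True
        for key, value in eq.scope.items():
            if key in scope:
                if scope[key] != value:
                    ok = False
                    break
                specificity += 1
        if ok:
            hits.append((specificity, eq))
    hits.sort(key=lambda t: (-t[0], t[1].eq_id))
    return [eq for _, eq in hits]


def evaluate_equation(eq: AllometricEquation, x: float) -> float:
    """Point evaluation y = exp(alpha) * x^beta; x must be positive."""
    if not (x > 0):
        raise ValueError(f"predictor value must be positive, got {x!r}")
    return math.exp(eq.alpha + eq.beta * math.log(x))
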