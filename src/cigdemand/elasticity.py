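"""Price and income elasticity decomposition from fitted two-part models.

The participation elasticity evaluates the standard-normal density at the
fitted mean linear index, scales by the coefficient of the log variable, and
divides by the observed participation rate.  The conditional elasticity is
the log-log coefficient read off directly; the total is their sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .estimation import OLSFit, ProbitFit

__all__ = [
    "ElasticityDecomposition",
    "participation_elasticity",
    "conditional_elasticity",
    "total_elasticity",
    "elasticity_table",
    "overall_elasticity",
]

_VARIABLE_TERMS = {"price": "ln_price", "income": "ln_income"}


@dataclass(frozen=True)
class ElasticityDecomposition:
    quintile: int
    variable: str  # "price" or "income"
    participation: float
    conditional: float
    total: float


def _coef_for(fit, variable: str) -> float:
    try:
        term = _VARIABLE_TERMS[variable]
    except KeyError:
        raise ValueError(
            f"unknown variable {variable!r}; expected one of "
            f"{sorted(_VARIABLE_TERMS)}"
        ) from None
    return float(fit.coefficients[fit.terms.index(term)])


def participation_elasticity(fit: ProbitFit, variable: str) -> float:
    """Elasticity of the participation rate with respect to the variable.

    Computed as ``coef * phi(mean_linear_index) / participation_rate`` where
    ``phi`` is the standard-normal density.
    """
    if not fit.converged:
        raise ValueError("participation elasticity requires a converged probit fit")
    rate = fit.participation_rate
    if not 0.0 < rate < 1.0:
        raise ValueError(
            f"participation rate must be strictly inside (0, 1), got {rate}"
        )
    coef = _coef_for(fit, variable)
    density = math.exp(-0.5 * fit.mean_linear_index**2) / math.sqrt(2.0 * math.pi)
    return coef * density / rate


def conditional_elasticity(fit: OLSFit, variable: str) -> float:
    """Elasticity among smokers: the log-log coefficient itself."""
    return _coef_for(fit, variable)


def total_elasticity(participation: float, conditional: float) -> float:
    """Total elasticity as the exact sum of the two parts."""
    if not (math.isfinite(participation) and math.isfinite(conditional)):
        raise ValueError("elasticity components must be finite")
    return participation + conditional


def elasticity_table(
    fits: Mapping[int, tuple[ProbitFit, OLSFit]],
) -> list[ElasticityDecomposition]:
    """Decomposition for all five quintiles and both variables (10 rows)."""
    missing = [q for q in (1, 2, 3, 4, 5) if q not in fits]
    if missing:
        raise ValueError(f"missing quintiles: {missing}")
    rows = []
    for q in (1, 2, 3, 4, 5):
        probit, ols = fits[q]
        for variable in ("price", "income"):
            part = participation_elasticity(probit, variable)
            cond = conditional_elasticity(ols, variable)
            rows.append(
                ElasticityDecomposition(
                    quintile=q,
                    variable=variable,
                    participation=part,
                    conditional=cond,
                    total=total_elasticity(part, cond),
                )
            )
    return rows


def overall_elasticity(
    rows: Iterable[ElasticityDecomposition],
    variable: str = "price",
    component: str = "total",
) -> float:
    """Unweighted mean of a component across quintiles for one variable."""
    vals = [getattr(r, component) for r in rows if r.variable == variable]
    if len(vals) == 0:
        raise ValueError(f"no rows for variable {variable!r}")
    return sum(vals) / len(vals)
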