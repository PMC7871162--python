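"""Static projection of smokers who quit under price-increase scenarios.

Per stratum and scenario, quitters = smokers × |participation elasticity| ×
price increase, rounded half-away-from-zero to whole persons.  The module is
fully deterministic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PopulationStratum",
    "ScenarioResult",
    "smokers_in_stratum",
    "quitters",
    "run_scenarios",
    "scenario_report",
]


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class PopulationStratum:
    """One population group entering the projection.

    ``participation_elasticity`` is a magnitude (absolute value); ``smokers``
    may be given directly, otherwise it is derived from population ×
    prevalence.
    """

    label: str
    population: int
    prevalence: float
    participation_elasticity: float
    smokers: int | None = None

    def __post_init__(self) -> None:
        if self.population < 0:
            raise ValueError(f"population must be non-negative, got {self.population}")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence must be in [0, 1], got {self.prevalence}")
        if self.participation_elasticity < 0:
            raise ValueError(
                "participation_elasticity enters as a magnitude and must be "
                f"non-negative, got {self.participation_elasticity}"
            )
        if self.smokers is not None and self.smokers > self.population:
            raise ValueError(
                f"smokers ({self.smokers}) exceed population ({self.population})"
            )

    @property
    def smoker_count(self) -> int:
        if self.smokers is not None:
            return int(self.smokers)
        return smokers_in_stratum(self.population, self.prevalence)


@dataclass(frozen=True)
class ScenarioResult:
    labels: tuple[str, ...]
    price_increases: tuple[float, ...]
    smokers: tuple[int, ...]  # per stratum
    quitters: np.ndarray  # strata × scenarios, whole persons
    total_smokers: int
    total_quitters: tuple[int, ...]  # per scenario
    percent_quit: tuple[float, ...]  # per scenario, in percent


def smokers_in_stratum(population: int, prevalence: float) -> int:
    """Smoker head count from population and prevalence, rounded to persons."""
    if population < 0:
        raise ValueError(f"population must be non-negative, got {population}")
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError(f"prevalence must be in [0, 1], got {prevalence}")
    return _round_half_away(population * prevalence)


def quitters(smokers: int, participation_elasticity: float, price_increase: float) -> int:
    """Smokers who quit: smokers × elasticity × price increase, in persons."""
    if smokers < 0 or participation_elasticity < 0 or price_increase < 0:
        raise ValueError("smokers, elasticity and price increase must be non-negative")
    q = smokers * participation_elasticity * price_increase
    if q > smokers:
        warnings.warn(
            f"projected quitters ({q:.0f}) exceed smokers ({smokers}); "
            "capping at the smoker count",
            stacklevel=2,
        )
        return int(smokers)
    return _round_half_away(q)


def run_scenarios(
    strata: Sequence[PopulationStratum], price_increases: Sequence[float]
) -> ScenarioResult:
    """Quitter matrix over strata × price-increase scenarios."""
    if len(strata) == 0:
        raise ValueError("at least one stratum is required")
    if len(price_increases) == 0:
        raise ValueError("at least one price-increase scenario is required")
    smokers = tuple(s.smoker_count for s in strata)
    mat = np.zeros((len(strata), len(price_increases)), dtype=int)
    for i, s in enumerate(strata):
        for j, inc in enumerate(price_increases):
            mat[i, j] = quitters(smokers[i], s.participation_elasticity, inc)
    total_smokers = int(sum(smokers))
    total_quitters = tuple(int(c) for c in mat.sum(axis=0))
    percent = tuple(
        100.0 * tq / total_smokers if total_smokers > 0 else 0.0
        for tq in total_quitters
    )
    return ScenarioResult(
        labels=tuple(s.label for s in strata),
        price_increases=tuple(float(p) for p in price_increases),
        smokers=smokers,
        quitters=mat,
        total_smokers=total_smokers,
        total_quitters=total_quitters,
        percent_quit=percent,
    )


def scenario_report(result: ScenarioResult) -> pd.DataFrame:
    """Projection table: one row per stratum plus a Total row.

    Quitter columns are named ``quit_<pct>pct``; the Total row carries the
    summed counts, and percent-quit shares are exposed in
    ``DataFrame.attrs["percent_quit"]``.
    """
    cols = {f"quit_{int(round(p * 100))}pct": result.quitters[:, j]
            for j, p in enumerate(result.price_increases)}
    df = pd.DataFrame(
        {"stratum": result.labels, "smokers": result.smokers, **cols}
    )
    total = {"stratum": "Total", "smokers": result.total_smokers}
    for j, p in enumerate(result.price_increases):
        total[f"quit_{int(round(p * 100))}pct"] = result.total_quitters[j]
    df = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
    df.attrs["percent_quit"] = {
        f"{int(round(p * 100))}pct": result.percent_quit[j]
        for j, p in enumerate(result.price_increases)
    }
    return df


def format_report(result: ScenarioResult) -> str:
    """Plain-text rendering of :func:`scenario_report` with percent lines."""
    df = scenario_report(result)
    lines = [df.to_string(index=False)]
    for key, pct in df.attrs["percent_quit"].items():
        lines.append(f"percent quit at {key}: {pct:.1f}%")
    return "\n".join(lines)
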