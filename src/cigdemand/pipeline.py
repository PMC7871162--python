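"""Pipeline orchestration: quintile assignment, descriptives, CSV I/O, and
the end-to-end simulate → fit → elasticity → project chain."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .elasticity import ElasticityDecomposition, elasticity_table
from .estimation import OLSFit, ProbitFit, fit_two_part
from .published import DEFAULT_PRICE_INCREASES, IRAN_MALE_STRATA
from .scenarios import PopulationStratum, run_scenarios, scenario_report
from .synthetic import HOUSEHOLD_COLUMNS, generate_survey

__all__ = [
    "PipelineConfig",
    "assign_quintiles",
    "descriptive_stats",
    "run_pipeline",
    "read_households",
    "write_households",
    "read_strata",
    "coefficient_frame",
    "elasticity_frame",
]

logger = logging.getLogger("cigdemand")

_STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _stars(estimate: float, se: float) -> str:
    """Significance stars from a two-sided normal test at 5/1/0.1%."""
    from scipy.special import ndtr

    if not np.isfinite(se) or se <= 0:
        return ""
    p = 2.0 * (1.0 - ndtr(abs(estimate) / se))
    for thr, sym in _STAR_THRESHOLDS:
        if p < thr:
            return sym
    return ""


# ---------------------------------------------------------------------------
# CSV I/O (text-only, UTF-8, comma separated; '#' header comments)


def _header_comment(seed=None, extra: dict | None = None) -> str:
    parts = [f"version={__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    for k, v in (extra or {}).items():
        parts.append(f"{k}={v}")
    return "# " + " ".join(parts) + "\n"


def _write_csv(df: pd.DataFrame, path, seed=None, extra: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header_comment(seed=seed, extra=extra))
        df.to_csv(fh, index=False)


def write_households(df: pd.DataFrame, path, seed=None) -> None:
    """Write a household table; non-smoker consumption becomes empty fields."""
    _write_csv(df, path, seed=seed, extra={"rows": len(df)})


def read_households(path) -> pd.DataFrame:
    """Read a household CSV written by :func:`write_households`."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in HOUSEHOLD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"household table is missing columns: {missing}")
    return df


def read_strata(path) -> list[PopulationStratum]:
    """Read scenario strata from CSV (label, population, prevalence,
    participation_elasticity, optional smokers)."""
    df = pd.read_csv(path, comment="#")
    strata = []
    for _, row in df.iterrows():
        smokers = None
        if "smokers" in df.columns and not pd.isna(row["smokers"]):
            smokers = int(row["smokers"])
        strata.append(
            PopulationStratum(
                label=str(row["label"]),
                population=int(row["population"]),
                prevalence=float(row["prevalence"]),
                participation_elasticity=float(row["participation_elasticity"]),
                smokers=smokers,
            )
        )
    return strata


# ---------------------------------------------------------------------------
# Quintile assignment and descriptives


def assign_quintiles(table: pd.DataFrame) -> pd.DataFrame:
    """Label households 1-5 by ranked expenditure per equivalent adult.

    Ranks use minimum ranking, so tied expenditures always share a quintile
    (an all-equal table collapses into quintile 1, with a warning); distinct
    values cut cleanly at the 20/40/60/80 percentiles.
    """
    if "expenditure_pea" not in table.columns:
        raise ValueError("expenditure_pea column is required")
    n = len(table)
    if n < 5:
        raise ValueError(f"need at least 5 households to form quintiles, got {n}")
    if (table["expenditure_pea"] <= 0).any():
        raise ValueError("expenditure_pea must be positive")
    ranks = table["expenditure_pea"].rank(method="min").to_numpy()
    labels = ((ranks - 1) * 5 // n + 1).astype(int)
    out = table.copy()
    out["quintile"] = labels
    counts = np.bincount(labels, minlength=6)[1:]
    if (counts == 0).any():
        warnings.warn(
            f"tied expenditures left quintile sizes unbalanced: {counts.tolist()}",
            stacklevel=2,
        )
    return out


def descriptive_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Per-quintile descriptive summary of the household table.

    Columns: household count, mean expenditure per equivalent adult, percent
    of households smoking, mean percent of expenditure spent on cigarettes
    among smokers (sticks priced per 20-stick pack), mean sticks per day
    among smokers, and percent of households with any university-educated
    member.  Smoker-conditional cells are NaN where a quintile has no
    smokers.
    """
    if "quintile" not in table.columns:
        raise ValueError("assign quintiles before computing descriptives")
    rows = []
    for q in (1, 2, 3, 4, 5):
        sub = table[table["quintile"] == q]
        row = {"quintile": q, "n_households": len(sub)}
        if len(sub) == 0:
            rows.append(row)
            continue
        row["mean_expenditure_pea"] = float(sub["expenditure_pea"].mean())
        smokers = sub[sub["smoke"] == 1]
        row["smoking_rate_pct"] = 100.0 * len(smokers) / len(sub)
        if len(smokers) > 0:
            row["mean_sticks_per_day"] = float(
                (smokers["sticks_month"] / 30.0).mean()
            )
            if "ln_price" in smokers.columns:
                spend = smokers["sticks_month"] / 20.0 * np.exp(smokers["ln_price"])
                row["cig_budget_share_pct"] = float(
                    (100.0 * spend / smokers["expenditure_pea"]).mean()
                )
        if "share_univ_edu" in sub.columns:
            row["univ_member_pct"] = float(100.0 * (sub["share_univ_edu"] > 0).mean())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end pipeline


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full pipeline run needs."""

    seed: int = 0
    n_per_quintile: int = 10_000
    sigma: float = 0.45
    price_increases: tuple[float, ...] = DEFAULT_PRICE_INCREASES
    strata: tuple[PopulationStratum, ...] = IRAN_MALE_STRATA
    use_fitted_elasticities: bool = False
    outdir: str = "cigdemand_out"
    verbosity: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in (
            "seed",
            "n_per_quintile",
            "sigma",
            "use_fitted_elasticities",
            "outdir",
            "verbosity",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "price_increases" in raw:
            kwargs["price_increases"] = tuple(float(p) for p in raw["price_increases"])
        if "strata" in raw:
            kwargs["strata"] = tuple(
                PopulationStratum(
                    label=str(s["label"]),
                    population=int(s["population"]),
                    prevalence=float(s["prevalence"]),
                    participation_elasticity=float(s["participation_elasticity"]),
                    smokers=int(s["smokers"]) if "smokers" in s else None,
                )
                for s in raw["strata"]
            )
        return cls(**kwargs)

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def coefficient_frame(fits: dict[int, tuple[ProbitFit, OLSFit]]) -> pd.DataFrame:
    """Long-format coefficient table (quintile, part, term, estimate, se,
    stars) mirroring the published layout."""
    rows = []
    for q in sorted(fits):
        probit, ols = fits[q]
        for part, fit in (("participation", probit), ("consumption", ols)):
            for term, est, se in zip(fit.terms, fit.coefficients, fit.standard_errors):
                rows.append(
                    {
                        "quintile": q,
                        "part": part,
                        "term": term,
                        "estimate": est,
                        "se": se,
                        "stars": _stars(est, se),
                        "n": fit.n,
                    }
                )
    return pd.DataFrame(rows)


def elasticity_frame(rows: list[ElasticityDecomposition]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "quintile": r.quintile,
                "variable": r.variable,
                "participation": r.participation,
                "conditional": r.conditional,
                "total": r.total,
            }
            for r in rows
        ]
    )


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """simulate → assign quintiles → fit ×5 → elasticities → scenarios.

    Writes households.csv, coefficients.csv, elasticities.csv, scenarios.csv
    and run.log into ``config.outdir``; any stage failure removes partial
    outputs and re-raises with the stage name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        name: outdir / f"{name}.csv"
        for name in ("households", "coefficients", "elasticities", "scenarios")
    }
    paths["log"] = outdir / "run.log"
    written: list[Path] = []
    log_lines = [
        f"version={__version__} seed={config.seed} config_hash={config.digest()}"
    ]
    stage = "simulate"
    try:
        table = generate_survey(
            n_per_quintile=config.n_per_quintile, seed=config.seed, sigma=config.sigma
        )
        stage = "assign_quintiles"
        table = assign_quintiles(table)
        write_households(table, paths["households"], seed=config.seed)
        written.append(paths["households"])
        log_lines.append(f"simulated {len(table)} households")

        stage = "fit_two_part"
        fits = {}
        for q in (1, 2, 3, 4, 5):
            probit, ols = fit_two_part(table, q)
            fits[q] = (probit, ols)
            log_lines.append(
                f"quintile {q}: n_part1={probit.n} n_part2={ols.n} "
                f"converged={probit.converged} iterations={probit.n_iter}"
            )
        _write_csv(coefficient_frame(fits), paths["coefficients"], seed=config.seed)
        written.append(paths["coefficients"])

        stage = "elasticity_table"
        decomp = elasticity_table(fits)
        _write_csv(elasticity_frame(decomp), paths["elasticities"], seed=config.seed)
        written.append(paths["elasticities"])

        stage = "run_scenarios"
        strata = config.strata
        if config.use_fitted_elasticities:
            fitted = {
                r.quintile: abs(r.participation)
                for r in decomp
                if r.variable == "price"
            }
            strata = tuple(
                dataclasses.replace(s, participation_elasticity=fitted[q])
                for q, s in zip((1, 2, 3, 4, 5), strata)
            )
        result = run_scenarios(strata, config.price_increases)
        report = scenario_report(result)
        _write_csv(report, paths["scenarios"], seed=config.seed)
        written.append(paths["scenarios"])
        for key, pct in report.attrs["percent_quit"].items():
            log_lines.append(f"percent quit at {key}: {pct:.2f}%")
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    paths["log"].write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    logger.info("pipeline complete: %s", outdir)
    return paths
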