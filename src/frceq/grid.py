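"""Parameter-grid sweeps, regression analysis and the validation suite.

The standard grid crosses s = 0.05..0.9 and h = 0.05..0.95 in steps of
0.05. For each cell the engine is solved at the requested C and at the
matched C = 1 baseline; the fold increase omega and the percent increase
100*(omega - 1) are recorded. Everything is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import pandas as pd
from scipy import stats

from . import autosomal, dimorphic, sexlinked
from .closed_forms import breakdown, q_full_frc, q_no_frc
from .params import ModelParams, SolverSettings

logger = logging.getLogger(__name__)

LOCUS_MODES = ("autosomal", "sexlinked", "dimorphic")

_SOLVERS = {
    "autosomal": autosomal.solve_equilibrium,
    "sexlinked": sexlinked.solve_equilibrium_x,
    "dimorphic": dimorphic.solve_equilibrium_dimorphic,
}


def _default_s() -> tuple[float, ...]:
    return tuple(round(0.05 * i, 2) for i in range(1, 19))  # 0.05..0.9


def _default_h() -> tuple[float, ...]:
    return tuple(round(0.05 * i, 2) for i in range(1, 20))  # 0.05..0.95


@dataclass(frozen=True)
class GridSpec:
    """A (h, s, C) sweep at fixed mutation rate for one locus mode."""

    s_values: tuple[float, ...] = field(default_factory=_default_s)
    h_values: tuple[float, ...] = field(default_factory=_default_h)
    C_values: tuple[float, ...] = (1.1, 1.2, 1.5, 2.0)
    mu: float = 1e-5
    locus_mode: str = "autosomal"

    def __post_init__(self) -> None:
        if self.locus_mode not in LOCUS_MODES:
            raise ValueError(f"locus_mode must be one of {LOCUS_MODES}")
        for C in self.C_values:
            if C < 1.0:
                raise ValueError(f"C >= 1 required, got {C}")


@dataclass(frozen=True)
class GridRecord:
    """One grid cell: equilibrium with and without compensation.

    ``q_frc``/``q_baseline`` are adult-census equilibria and
    ``omega = q_frc / q_baseline`` their ratio; under full compensation
    this equals 2 - h*s to leading order. The gametic equilibria (one
    extra round of mutation, used for closed-form comparisons) are kept
    alongside; their ratio is diluted toward 1 by the fresh-mutation
    term common to both censuses.
    """

    h: float
    s: float
    C: float
    mu: float
    q_frc: float
    q_baseline: float
    q_frc_gametic: float
    q_baseline_gametic: float
    omega: float
    percent_increase: float
    converged: bool
    iterations: int


def run_grid(spec: GridSpec, settings: SolverSettings | None = None) -> list[GridRecord]:
    """Solve every (h, s, C) cell against its simulated C = 1 baseline.

    The baseline is solved once per (h, s) and shared across C values.
    Non-converged cells are flagged, not dropped.
    """
    settings = settings or SolverSettings()
    solve = _SOLVERS[spec.locus_mode]
    records: list[GridRecord] = []
    for h in spec.h_values:
        for s in spec.s_values:
            base_params = ModelParams(h=h, s=s, mu=spec.mu, C=1.0)
            base = solve(base_params, settings)
            for C in spec.C_values:
                res = solve(ModelParams(h=h, s=s, mu=spec.mu, C=C), settings)
                om = res.q_adult / base.q_adult
                records.append(
                    GridRecord(
                        h=h,
                        s=s,
                        C=C,
                        mu=spec.mu,
                        q_frc=res.q_adult,
                        q_baseline=base.q_adult,
                        q_frc_gametic=res.q_gametic,
                        q_baseline_gametic=base.q_gametic,
                        omega=om,
                        percent_increase=100.0 * (om - 1.0),
                        converged=res.converged and base.converged,
                        iterations=res.iterations,
                    )
                )
                logger.debug(
                    "%s h=%.2f s=%.2f C=%.2f omega=%.5f (%d iter)",
                    spec.locus_mode, h, s, C, om, res.iterations,
                )
        logger.info("%s grid row h=%.2f done", spec.locus_mode, h)
    return records


def records_to_frame(records: list[GridRecord]) -> pd.DataFrame:
    columns = [f.name for f in fields(GridRecord)]
    return pd.DataFrame([r.__dict__ for r in records], columns=columns)


def linear_fit_percent_increase(records: list[GridRecord], C: float) -> tuple[float, float]:
    """OLS of percent increase on h*s over the linear (full-fRC) portion.

    Only cells with h*s strictly below the breakdown threshold 2*(1-1/C)
    enter the fit; on that portion the expected relation is
    percent = 100*(1 - h*s), i.e. intercept 100 and slope -100.
    """
    threshold = breakdown(C).hs_threshold
    pts = [(r.h * r.s, r.percent_increase) for r in records if r.C == C and r.h * r.s < threshold]
    if len(pts) < 3:
        raise ValueError(f"fewer than 3 grid cells in the linear portion (h*s < {threshold:g})")
    x, y = zip(*pts)
    fit = stats.linregress(x, y)
    return (fit.intercept, fit.slope)


def validate_standard_results(
    mu: float = 1e-7, settings: SolverSettings | None = None
) -> pd.DataFrame:
    """Check the engines recover the classical closed-form equilibria.

    Runs each engine at C = 1 (no compensation) and C = 100 (full
    compensation) against the corresponding closed form. All rows are
    asserted at 1% relative error except the X-linked semidominant
    no-compensation form, whose derivation makes algebraic assumptions
    the full recursion does not share; its deviation is reported only.
    """
    settings = settings or SolverSettings()
    rows = []

    def add(check, locus, h, s, C, census, expected, simulated, asserted):
        rel = abs(simulated - expected) / expected
        rows.append(
            {
                "check": check,
                "locus_mode": locus,
                "h": h,
                "s": s,
                "C": C,
                "census": census,
                "expected": expected,
                "simulated": simulated,
                "rel_error": rel,
                "asserted": asserted,
                "passed": (rel < 0.01) if asserted else True,
            }
        )

    # autosomal, no compensation
    for h, s in ((0.5, 0.2), (0.2, 0.5)):
        res = autosomal.solve_equilibrium(ModelParams(h, s, mu, 1.0), settings)
        add("autosomal semidominant, no fRC: q = mu/(h*s)",
            "autosomal", h, s, 1.0, "gametic", q_no_frc(mu, h, s), res.q_gametic, True)
    res = autosomal.solve_equilibrium(ModelParams(0.0, 0.5, mu, 1.0), settings)
    add("autosomal recessive, no fRC: q = sqrt(mu/s)",
        "autosomal", 0.0, 0.5, 1.0, "gametic", q_no_frc(mu, 0.0, 0.5), res.q_gametic, True)
    # autosomal recessive lethal, full compensation
    res = autosomal.solve_equilibrium(ModelParams(0.0, 1.0, mu, 100.0), settings)
    add("autosomal recessive lethal, full fRC: q = sqrt(3*mu/2)",
        "autosomal", 0.0, 1.0, 100.0, "gametic",
        q_full_frc(mu, 0.0, 1.0), res.q_gametic, True)
    # sex-linked semidominant, no compensation (reported, not asserted)
    res = sexlinked.solve_equilibrium_x(ModelParams(0.5, 0.2, mu, 1.0), settings)
    add("sex-linked semidominant, no fRC: q = 3*mu/(2hs+s) (reported only)",
        "sexlinked", 0.5, 0.2, 1.0, "gametic",
        q_no_frc(mu, 0.5, 0.2, "sexlinked"), res.q_gametic, False)
    # sex-linked recessive lethal, affected-male census
    res = sexlinked.solve_equilibrium_x(ModelParams(0.0, 1.0, mu, 1.0), settings)
    add("sex-linked recessive lethal, no fRC: q_affected = 3*mu",
        "sexlinked", 0.0, 1.0, 1.0, "affected_males",
        q_no_frc(mu, 0.0, 1.0, "sexlinked"),
        sexlinked.affected_male_freq(res.state, mu), True)
    res = sexlinked.solve_equilibrium_x(ModelParams(0.0, 1.0, mu, 100.0), settings)
    add("sex-linked recessive lethal, full fRC: q_affected = 4*mu",
        "sexlinked", 0.0, 1.0, 100.0, "affected_males",
        q_full_frc(mu, 0.0, 1.0, "sexlinked"),
        sexlinked.affected_male_freq(res.state, mu), True)
    return pd.DataFrame(rows)


def export(records: list[GridRecord], path: str, format: str = "csv") -> None:
    """Write grid records as CSV (header + fixed column order) or JSON."""
    df = records_to_frame(records)
    if format == "csv":
        df.to_csv(path, index=False, float_format="%.10g")
    elif format == "json":
        df.to_json(path, orient="records", double_precision=10, indent=1)
    else:
        raise ValueError(f"unknown format {format!r}")
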