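"""X-linked model with strictly within-sex compensation.

For species so sexually dimorphic that a dead male can only be replaced
by a brother (and a dead female by a sister), compensation acts on each
sex's half of the brood independently: with the sexes produced 50:50,
each sub-brood has pre-selection size 0.5, post-selection size Z_sex,
and post-compensation size B_sex = min(Z_sex * C, 0.5) -- full
restoration means restoring that sex's half-share, never borrowing from
the other sex. Everything else (mating types, mutation, selection,
per-sex normalization, censuses) is identical to
:mod:`frceq.sexlinked`, and at C = 1 the two models coincide exactly.
"""

from __future__ import annotations

from ._solve import dual_start_solve
from .brood import (
    FEMALE_GENOTYPES,
    MALE_GENOTYPES,
    apply_brood_mutation,
    mendelian_brood,
    selection_numerators,
)
from .params import EquilibriumResult, ModelParams, SexLinkedState, SolverSettings
from .sexlinked import MATING_PAIRS, adult_mutant_freq_x, affected_male_freq, solve_equilibrium_x

_GENOS = MALE_GENOTYPES + FEMALE_GENOTYPES


def _contribution_table(params: ModelParams) -> list[tuple[float, ...]]:
    """B_sex * P(g | sex sub-brood) per mating type.

    Each sex's numerators are compensated against that sex's half-share
    cap of 0.5; an extinct sub-brood (Z_sex = 0) contributes nothing for
    that sex.
    """
    table = []
    for pair in MATING_PAIRS:
        dist = apply_brood_mutation(mendelian_brood(pair, "sexlinked"), params.mu)
        numer = selection_numerators(dist, params)
        Zm = sum(numer.get(g, 0.0) for g in MALE_GENOTYPES)
        Zf = sum(numer.get(g, 0.0) for g in FEMALE_GENOTYPES)
        scale_m = min(Zm * params.C, 0.5) / Zm if Zm > 0.0 else 0.0
        scale_f = min(Zf * params.C, 0.5) / Zf if Zf > 0.0 else 0.0
        row = tuple(
            numer.get(g, 0.0) * (scale_m if g in MALE_GENOTYPES else scale_f) for g in _GENOS
        )
        table.append(row)
    return table


def _step(M: tuple[float, ...], table: list[tuple[float, ...]]) -> tuple[float, ...]:
    n = [0.0] * 5
    for m, row in zip(M, table):
        for k in range(5):
            n[k] += m * row[k]
    Nm = n[0] + n[1]
    Nf = n[2] + n[3] + n[4]
    if Nm <= 0.0 or Nf <= 0.0:
        raise RuntimeError("population extinct: one sex has no survivors")
    return (n[0] / Nm, n[1] / Nm, n[2] / Nf, n[3] / Nf, n[4] / Nf)


def next_generation_dimorphic(state: SexLinkedState, params: ModelParams) -> SexLinkedState:
    """One generation with compensation confined within each sex."""
    if not state.is_normalized:
        raise ValueError("input state is not normalized")
    males = state.male_tuple()
    females = state.female_tuple()
    M = tuple(m * f for m in males for f in females)
    return SexLinkedState(*_step(M, _contribution_table(params)))


def solve_equilibrium_dimorphic(
    params: ModelParams, settings: SolverSettings | None = None
) -> EquilibriumResult:
    """Mutation/selection balance under within-sex compensation."""
    settings = settings or SolverSettings()
    table = _contribution_table(params)

    def step(t: tuple[float, ...]) -> tuple[float, ...]:
        M = tuple(m * f for m in t[:2] for f in t[2:])
        return _step(M, table)

    def census(t: tuple[float, ...]) -> float:
        return t[1] / 3.0 + 2.0 * (0.5 * t[3] + t[4]) / 3.0

    def make_state(q0: float) -> tuple[float, ...]:
        p = 1.0 - q0
        return (p, q0, p * p, 2.0 * p * q0, q0 * q0)

    result = dual_start_solve(step, census, make_state, params.mu, settings)
    return EquilibriumResult(
        q_adult=result.q_adult,
        q_gametic=result.q_gametic,
        iterations=result.iterations,
        converged=result.converged,
        state=SexLinkedState(*result.state),
        start_agreement=result.start_agreement,
    )


def omega_dimorphic(
    params: ModelParams,
    settings: SolverSettings | None = None,
    census: str = "adult",
) -> float:
    """Fold increase vs the simulated C = 1 baseline (within-sex fRC)."""
    res = solve_equilibrium_dimorphic(params, settings)
    base = solve_equilibrium_dimorphic(params.baseline(), settings)
    if census == "gametic":
        return res.q_gametic / base.q_gametic
    if census == "adult":
        return res.q_adult / base.q_adult
    if census == "affected_males":
        return affected_male_freq(res.state, params.mu) / affected_male_freq(base.state, params.mu)
    raise ValueError(f"unknown census {census!r}")
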