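"""X-linked (male-heterogametic) recursion and equilibrium solver.

Males are hemizygous (+Y or mY, the latter with fitness 1 - s); females
carry two X copies with the autosomal fitness scheme. The six mating
types are male genotype x female genotype with frequency
M_i = f_male * f_female. Compensation pools the whole brood: a dead son
can be replaced by a surviving sister (contrast
:mod:`frceq.dimorphic`). Next-generation male and female genotype
frequencies are normalized separately.

Two thirds of X copies reside in females, so the adult census is
q_a = f_male(mY)/3 + 2*(0.5*f_fem(+m) + f_fem(mm))/3. For lethal checks
the classical affected-male census q = f_fem(+m)/2 + mu is also provided.
"""

from __future__ import annotations

from ._solve import dual_start_solve
from .brood import (
    FEMALE_GENOTYPES,
    MALE_GENOTYPES,
    apply_brood_mutation,
    brood_size_after_frc,
    mendelian_brood,
    selection_numerators,
)
from .params import EquilibriumResult, ModelParams, SexLinkedState, SolverSettings

#: male x female genotype pairs, wildtype fathers first
MATING_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (m, f) for m in MALE_GENOTYPES for f in FEMALE_GENOTYPES
)

_GENOS = MALE_GENOTYPES + FEMALE_GENOTYPES  # +Y mY ++ +m mm


def mating_frequencies(state: SexLinkedState) -> tuple[float, ...]:
    """M_i = f_male(g_m) * f_female(g_f) over the six pairs."""
    males = state.male_tuple()
    females = state.female_tuple()
    return tuple(m * f for m in males for f in females)


def _contribution_table(params: ModelParams) -> list[tuple[float, ...]]:
    """B_i * P(g)_i per mating type, pooled-brood compensation.

    Z is the whole brood's post-selection size; B = min(Z*C, 1) is shared
    by both sexes (a death in either sex releases resources to all sibs).
    """
    table = []
    for pair in MATING_PAIRS:
        dist = apply_brood_mutation(mendelian_brood(pair, "sexlinked"), params.mu)
        numer = selection_numerators(dist, params)
        Z = sum(numer.values())
        if Z <= 0.0:
            table.append((0.0,) * 5)
            continue
        scale = brood_size_after_frc(Z, params.C) / Z
        table.append(tuple(numer.get(g, 0.0) * scale for g in _GENOS))
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


def next_generation_x(state: SexLinkedState, params: ModelParams) -> SexLinkedState:
    """Advance the sex-linked adult frequencies by one generation."""
    if not state.is_normalized:
        raise ValueError("input state is not normalized")
    return SexLinkedState(*_step(mating_frequencies(state), _contribution_table(params)))


def adult_mutant_freq_x(state: SexLinkedState) -> float:
    """Population X-allele mutant frequency (2/3 of X copies in females)."""
    return state.m_mY / 3.0 + 2.0 * (0.5 * state.w_pm + state.w_mm) / 3.0


def affected_male_freq(state: SexLinkedState, mu: float) -> float:
    """Classical affected-male census for male-lethal mutations.

    Mutant alleles then transmit only through females, so the frequency
    of affected male births is half the female heterozygote frequency
    plus new mutation: f_fem(+m)/2 + mu.
    """
    return 0.5 * state.w_pm + mu


def _make_solver(params: ModelParams, table: list[tuple[float, ...]]):
    def step(t: tuple[float, ...]) -> tuple[float, ...]:
        males = t[:2]
        females = t[2:]
        M = tuple(m * f for m in males for f in females)
        return _step(M, table)

    def census(t: tuple[float, ...]) -> float:
        return t[1] / 3.0 + 2.0 * (0.5 * t[3] + t[4]) / 3.0

    def make_state(q0: float) -> tuple[float, ...]:
        p = 1.0 - q0
        return (p, q0, p * p, 2.0 * p * q0, q0 * q0)

    return step, census, make_state


def solve_equilibrium_x(params: ModelParams, settings: SolverSettings | None = None) -> EquilibriumResult:
    """Mutation/selection balance for an X-linked locus (pooled fRC)."""
    settings = settings or SolverSettings()
    step, census, make_state = _make_solver(params, _contribution_table(params))
    result = dual_start_solve(step, census, make_state, params.mu, settings)
    return EquilibriumResult(
        q_adult=result.q_adult,
        q_gametic=result.q_gametic,
        iterations=result.iterations,
        converged=result.converged,
        state=SexLinkedState(*result.state),
        start_agreement=result.start_agreement,
    )


def omega_x(
    params: ModelParams,
    settings: SolverSettings | None = None,
    census: str = "adult",
) -> float:
    """Fold increase vs the simulated C = 1 baseline.

    ``census`` selects the frequency compared: ``'adult'`` (default;
    see :func:`frceq.autosomal.omega` for why), ``'gametic'``, or
    ``'affected_males'`` (the lethal-check census).
    """
    res = solve_equilibrium_x(params, settings)
    base = solve_equilibrium_x(params.baseline(), settings)
    if census == "gametic":
        return res.q_gametic / base.q_gametic
    if census == "adult":
        return res.q_adult / base.q_adult
    if census == "affected_males":
        return affected_male_freq(res.state, params.mu) / affected_male_freq(base.state, params.mu)
    raise ValueError(f"unknown census {census!r}")
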