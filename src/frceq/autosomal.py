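"""One-generation recursion and equilibrium solver for autosomal loci.

Adults mate at random, giving six mating types with frequencies M_i
(squared terms for like x like, doubled cross-products otherwise). Each
mating type's brood passes through segregation, mutation, selection and
compensation (see :mod:`frceq.brood`); next-generation adult genotype
frequencies are proportional to sum_i M_i * B_i * P(g)_i, normalized
over the three genotypes.
"""

from __future__ import annotations

from scipy.optimize import brentq

from ._solve import dual_start_solve
from .brood import AUTOSOMAL_GENOTYPES, brood_size_after_frc, mendelian_brood, apply_brood_mutation, selection_numerators
from .params import AutosomalState, EquilibriumResult, ModelParams, SolverSettings

#: mating types in the conventional order (like x like squared,
#: unlike pairs doubled)
MATING_PAIRS: tuple[tuple[str, str], ...] = (
    ("++", "++"),
    ("++", "+m"),
    ("++", "mm"),
    ("+m", "+m"),
    ("+m", "mm"),
    ("mm", "mm"),
)


def mating_frequencies(state: AutosomalState) -> tuple[float, ...]:
    """Frequencies M_1..M_6 of the six mating types under random mating."""
    pp, pm, mm = state.as_tuple()
    return (pp * pp, 2.0 * pp * pm, 2.0 * pp * mm, pm * pm, 2.0 * pm * mm, mm * mm)


def _contribution_table(params: ModelParams) -> list[tuple[float, float, float]]:
    """Per mating type, the factor B_i * P(g)_i for g in (++, +m, mm).

    These depend only on the parameters (brood composition is fixed per
    mating type), so the solver computes them once. Extinct broods
    (Z = 0, only possible at s = 1) contribute zero.
    """
    table = []
    for pair in MATING_PAIRS:
        dist = apply_brood_mutation(mendelian_brood(pair, "autosomal"), params.mu)
        numer = selection_numerators(dist, params)
        Z = sum(numer.values())
        if Z <= 0.0:
            table.append((0.0, 0.0, 0.0))
            continue
        B = brood_size_after_frc(Z, params.C)
        scale = B / Z
        table.append(tuple(numer.get(g, 0.0) * scale for g in AUTOSOMAL_GENOTYPES))
    return table


def _step(M: tuple[float, ...], table: list[tuple[float, float, float]]) -> tuple[float, float, float]:
    n_pp = n_pm = n_mm = 0.0
    for m, (c_pp, c_pm, c_mm) in zip(M, table):
        n_pp += m * c_pp
        n_pm += m * c_pm
        n_mm += m * c_mm
    N = n_pp + n_pm + n_mm
    if N <= 0.0:
        raise RuntimeError("population extinct: every brood has Z = 0")
    return (n_pp / N, n_pm / N, n_mm / N)


def next_generation(state: AutosomalState, params: ModelParams) -> AutosomalState:
    """Advance the adult genotype frequencies by one generation."""
    if not state.is_normalized:
        raise ValueError("input state is not normalized")
    new = _step(mating_frequencies(state), _contribution_table(params))
    return AutosomalState(*new)


def adult_mutant_freq(state: AutosomalState) -> float:
    """Mutant allele frequency among adults: 0.5*f(+m) + f(mm)."""
    return 0.5 * state.f_pm + state.f_mm


def gametic_freq(q_adult: float, mu: float) -> float:
    """Gamete-stage census: one extra round of mutation before fertilization."""
    return q_adult + (1.0 - q_adult) * mu


def solve_equilibrium(params: ModelParams, settings: SolverSettings | None = None) -> EquilibriumResult:
    """Mutation/selection balance by fixed-point iteration.

    Starts from Hardy-Weinberg states at the low (and, with dual_start,
    high) starting frequencies and iterates the full genotype-frequency
    recursion until the adult mutant frequency stabilizes.
    """
    settings = settings or SolverSettings()
    table = _contribution_table(params)

    def step(t: tuple[float, float, float]) -> tuple[float, float, float]:
        pp, pm, mm = t
        M = (pp * pp, 2.0 * pp * pm, 2.0 * pp * mm, pm * pm, 2.0 * pm * mm, mm * mm)
        return _step(M, table)

    def census(t: tuple[float, float, float]) -> float:
        return 0.5 * t[1] + t[2]

    def make_state(q0: float) -> tuple[float, float, float]:
        p = 1.0 - q0
        return (p * p, 2.0 * p * q0, q0 * q0)

    result = dual_start_solve(step, census, make_state, params.mu, settings)
    return EquilibriumResult(
        q_adult=result.q_adult,
        q_gametic=result.q_gametic,
        iterations=result.iterations,
        converged=result.converged,
        state=AutosomalState(*result.state),
        start_agreement=result.start_agreement,
    )


def solve_equilibrium_1d(params: ModelParams, settings: SolverSettings | None = None) -> float:
    """Cross-check: root of q -> q_a(next_generation(HW(q))) - q.

    A one-dimensional root-find on the adult mutant frequency with the
    state embedded at Hardy-Weinberg. Because the true equilibrium state
    deviates slightly from Hardy-Weinberg under selection, this agrees
    with :func:`solve_equilibrium` only approximately; it is provided as
    an independent sanity check, not as the canonical solver.
    """
    settings = settings or SolverSettings()
    table = _contribution_table(params)

    def g(q: float) -> float:
        p = 1.0 - q
        M = (
            p * p * p * p,
            2.0 * p * p * 2.0 * p * q,
            2.0 * p * p * q * q,
            (2.0 * p * q) ** 2,
            2.0 * 2.0 * p * q * q * q,
            q * q * q * q,
        )
        new = _step(M, table)
        return 0.5 * new[1] + new[2] - q

    return brentq(g, settings.start_low, settings.start_high, xtol=1e-15, rtol=8.9e-16)


def omega(params: ModelParams, settings: SolverSettings | None = None, census: str = "adult") -> float:
    """Fold increase in equilibrium mutant frequency due to compensation.

    The ratio of the equilibrium at the given C to the simulated C = 1
    baseline (not a closed form), keeping the comparison internally
    consistent for every locus mode.

    By default the adult census is compared: the fold increase of the
    adult frequency equals 2 - h*s under full compensation (to leading
    order in mu), which is the headline result. The gametic census adds
    the same fresh-mutation term mu to both equilibria, which dilutes
    the ratio toward 1 by a factor that grows with h*s (the relative
    weight of new mutations, h*s/[(1-h*s)(2-h*s)], is not small when
    selection is strong), so it does not reproduce the linear
    percent-increase relation.
    """
    res = solve_equilibrium(params, settings)
    base = solve_equilibrium(params.baseline(), settings)
    if census == "adult":
        return res.q_adult / base.q_adult
    if census == "gametic":
        return res.q_gametic / base.q_gametic
    raise ValueError(f"unknown census {census!r}")
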