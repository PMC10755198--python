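"""Generic dual-start fixed-point driver shared by the three engines."""

from __future__ import annotations

from typing import Callable

from .params import EquilibriumResult, SolverSettings

_TINY = 1e-300


def iterate_to_equilibrium(
    step: Callable[[object], object],
    census: Callable[[object], float],
    state0: object,
    settings: SolverSettings,
) -> tuple[object, int, bool]:
    """Iterate ``step`` until the census frequency stabilizes.

    The recursion contracts geometrically near its stable equilibrium, so
    the remaining distance to the limit is estimated from consecutive
    changes (a geometric-tail / Aitken estimate): with delta_t the change
    at generation t and lam = delta_t / delta_{t-1} the estimated
    contraction factor, the tail is |delta_t| * lam / (1 - lam).
    Convergence requires both the per-generation relative change and the
    estimated relative tail to fall below ``rel_tol``; this is strictly
    tighter than the consecutive-change criterion alone, and it refuses
    to stop on slow transits (e.g. escape from the unstable all-mutant
    boundary, where the changes grow, lam >= 1). Returns (state,
    iterations, converged); hitting ``max_iter`` flags ``converged=False``
    rather than raising.
    """
    state = state0
    q_prev = census(state)
    delta_prev: float | None = None
    for it in range(1, settings.max_iter + 1):
        state = step(state)
        q = census(state)
        delta = q - q_prev
        rel_change = abs(delta) / max(abs(q_prev), _TINY)
        if rel_change < settings.rel_tol:
            if delta == 0.0:
                return state, it, True  # exact fixed point
            if delta_prev:  # contraction estimate needs a previous change
                lam = abs(delta) / abs(delta_prev)
                if lam < 1.0:
                    tail = abs(delta) * lam / (1.0 - lam)
                    if tail / max(abs(q), _TINY) < settings.rel_tol:
                        return state, it, True
        q_prev = q
        delta_prev = delta
    return state, settings.max_iter, False


def dual_start_solve(
    step: Callable[[object], object],
    census: Callable[[object], float],
    make_state: Callable[[float], object],
    mu: float,
    settings: SolverSettings,
) -> EquilibriumResult:
    """Run the iteration from a low and (optionally) a high start.

    The low-start solution is canonical. With ``dual_start`` the two
    solutions must agree within ``10 * rel_tol`` (relative) or the
    result is flagged unconverged.
    """
    state_lo, it_lo, ok_lo = iterate_to_equilibrium(step, census, make_state(settings.start_low), settings)
    q_lo = census(state_lo)
    if not settings.dual_start:
        return EquilibriumResult(
            q_adult=q_lo,
            q_gametic=q_lo + (1.0 - q_lo) * mu,
            iterations=it_lo,
            converged=ok_lo,
            state=state_lo,
        )
    state_hi, it_hi, ok_hi = iterate_to_equilibrium(step, census, make_state(settings.start_high), settings)
    q_hi = census(state_hi)
    agreement = abs(q_lo - q_hi) / max(q_lo, q_hi, _TINY)
    converged = ok_lo and ok_hi and agreement < 10.0 * settings.rel_tol
    return EquilibriumResult(
        q_adult=q_lo,
        q_gametic=q_lo + (1.0 - q_lo) * mu,
        iterations=it_lo + it_hi,
        converged=converged,
        state=state_lo,
        start_agreement=agreement,
    )
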