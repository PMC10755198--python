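"""Classical closed-form equilibria and compensation formulas.

These are the standard mutation/selection-balance results the numerical
engines are validated against, plus the analytic description of when
full compensation is possible.

Autosomal, no compensation:
    semidominant (h > 0): q = mu / (h*s)
    recessive (h = 0):    q = sqrt(mu / s)
Autosomal, full compensation:
    semidominant: q = mu * (2 - h*s) / (h*s)   (fold increase 2 - h*s)
    recessive lethal: q = sqrt(3*mu / 2)       (fold increase sqrt(3/2) = 1.22)
X-linked, no compensation:
    semidominant: q = 3*mu / (2*h*s + s)
    recessive lethal (affected-male census): q = 3*mu
X-linked recessive lethal, full compensation: q = 4*mu.

The recessive results are sometimes quoted without the square root
(i.e. as mu/s and 3*mu/2); those renderings are dimensionally
inconsistent with the 1.22-fold lethal result and with the classical
literature, but are retained behind ``as_printed=True`` for
transparency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import ModelParams


@dataclass(frozen=True)
class BreakdownInfo:
    """Where full compensation fails.

    ``F = 1 - 1/C`` is the largest brood fraction whose loss competitive
    release can fully replace. In a predominantly ++ x +m world, brood
    mortality is 0.5*h*s, so linear behaviour of the fold increase in
    h*s breaks down once ``h*s > 2F``.
    """

    F: float
    hs_threshold: float


def breakdown(C: float) -> BreakdownInfo:
    """Critical replaceable brood fraction and the h*s breakdown threshold."""
    if C < 1.0:
        raise ValueError(f"C >= 1 required, got {C}")
    F = 1.0 - 1.0 / C
    return BreakdownInfo(F=F, hs_threshold=2.0 * F)


def q_no_frc(mu: float, h: float, s: float, locus_mode: str = "autosomal", as_printed: bool = False) -> float:
    """Equilibrium mutant frequency without compensation (C = 1)."""
    if s <= 0.0:
        raise ValueError("closed forms require s > 0")
    if locus_mode == "autosomal":
        if h > 0.0:
            return mu / (h * s)
        return mu / s if as_printed else math.sqrt(mu / s)
    if locus_mode == "sexlinked":
        if h > 0.0:
            return 3.0 * mu / (2.0 * h * s + s)
        if s == 1.0:
            return 3.0 * mu  # affected-male census
        raise ValueError("no printed sex-linked closed form for recessive, nonlethal mutations")
    raise ValueError(f"unknown locus_mode {locus_mode!r}")


def q_full_frc(mu: float, h: float, s: float, locus_mode: str = "autosomal", as_printed: bool = False) -> float:
    """Equilibrium mutant frequency under full compensation (C large)."""
    if s <= 0.0:
        raise ValueError("closed forms require s > 0")
    if locus_mode == "autosomal":
        if h > 0.0:
            return mu * (2.0 - h * s) / (h * s)
        if s == 1.0:
            return 1.5 * mu if as_printed else math.sqrt(1.5 * mu)
        raise ValueError("no printed full-compensation form for recessive, nonlethal autosomal mutations")
    if locus_mode == "sexlinked":
        if h == 0.0 and s == 1.0:
            return 4.0 * mu  # affected-male census
        raise ValueError("the only printed sex-linked full-compensation form is the recessive lethal")
    raise ValueError(f"unknown locus_mode {locus_mode!r}")


def omega_formula(h: float, s: float) -> float:
    """Autosomal fold increase under full compensation: 2 - h*s."""
    if not 0.0 <= h * s <= 1.0:
        raise ValueError("h*s must be in [0, 1]")
    return 2.0 - h * s


def heterozygote_fitness_under_frc(h: float, s: float) -> float:
    """Effective heterozygote fitness when compensation is full.

    In a ++ x +m brood the h*s dead heterozygotes are replaced half by
    ++ and half by +m sibs, giving w = 1 - h*s / (2 - h*s); the implied
    effective selection pressure h*s/(2-h*s) reproduces the
    full-compensation equilibrium mu*(2-h*s)/(h*s).
    """
    if not 0.0 <= h * s < 1.0:
        raise ValueError("h*s must be in [0, 1)")
    return 1.0 - h * s / (2.0 - h * s)
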