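"""Parameter and state containers shared by all engines.

The model tracks adult genotype frequencies at a single biallelic locus
(wildtype ``+``, deleterious mutant ``m``) under mutation, viability
selection within broods, and sibling reproductive compensation
("competitive release"). Fitnesses are 1 for ``++`` (and ``+Y`` males),
``1 - h*s`` for heterozygotes and ``1 - s`` for ``mm`` homozygotes and
hemizygous ``mY`` males.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace


class ParameterError(ValueError):
    """A model parameter is outside its admissible range."""


class DegenerateModelWarning(UserWarning):
    """Parameters are admissible but the equilibrium is degenerate."""


@dataclass(frozen=True)
class ModelParams:
    """The four model parameters.

    Parameters
    ----------
    h : float
        Dominance coefficient in [0, 1]; the heterozygote fitness is
        ``1 - h*s``. ``h = 0`` is fully recessive, ``h = 1`` dominant.
    s : float
        Selection coefficient in [0, 1] against the mutant homozygote
        (and hemizygous mutant males at sex-linked loci).
    mu : float
        Per-allele wildtype-to-mutant mutation rate per generation,
        in (0, 0.01]. Back mutation is zero.
    C : float
        Competitive release coefficient, >= 1. Brood size after
        compensation is ``min(Z*C, 1)``; ``C = 1`` means compensation
        is absent.
    """

    h: float
    s: float
    mu: float
    C: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h <= 1.0:
            raise ParameterError(f"dominance h must be in [0, 1], got {self.h}")
        if not 0.0 <= self.s <= 1.0:
            raise ParameterError(f"selection coefficient s must be in [0, 1], got {self.s}")
        if not 0.0 < self.mu <= 0.01:
            raise ParameterError(f"mutation rate mu must be in (0, 0.01], got {self.mu}")
        if self.C < 1.0:
            raise ParameterError(f"competitive release coefficient C >= 1 required, got {self.C}")
        if self.s == 0.0 and self.C > 1.0:
            warnings.warn(
                "s = 0: selection is absent, so mutation pressure drives the "
                "mutant frequency toward 1 and no mutation/selection balance exists",
                DegenerateModelWarning,
                stacklevel=2,
            )

    @property
    def hs(self) -> float:
        """Heterozygous selection pressure h*s."""
        return self.h * self.s

    def with_C(self, C: float) -> "ModelParams":
        """Same parameters with a different compensation coefficient."""
        return replace(self, C=C)

    def baseline(self) -> "ModelParams":
        """The matched no-compensation parameter set (C = 1)."""
        return replace(self, C=1.0)


def validate_params(params: ModelParams) -> ModelParams:
    """Validate a parameter set, returning it unchanged.

    Validation happens at construction; this re-runs it so that
    parameter sets built by other means (e.g. ``dataclasses.replace``
    on a subclass) pass through the same checks.
    """
    return ModelParams(params.h, params.s, params.mu, params.C)


@dataclass(frozen=True)
class SolverSettings:
    """Fixed-point solver configuration.

    Equilibrium is declared when the population mutant frequency changes
    by less than a factor of ``rel_tol`` between consecutive generations.
    With ``dual_start`` the iteration is run from both a near-zero and a
    near-one mutant frequency and the two solutions must agree.
    """

    rel_tol: float = 1e-7
    max_iter: int = 10_000_000
    start_low: float = 1e-9
    start_high: float = 1.0 - 1e-9
    dual_start: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.rel_tol < 1.0:
            raise ParameterError(f"rel_tol must be in (0, 1), got {self.rel_tol}")
        if not 0.0 < self.start_low < self.start_high < 1.0:
            raise ParameterError(
                f"require 0 < start_low < start_high < 1, got "
                f"({self.start_low}, {self.start_high})"
            )
        if self.max_iter < 1:
            raise ParameterError("max_iter must be positive")


_NORM_TOL = 1e-9


@dataclass(frozen=True)
class AutosomalState:
    """Adult genotype frequencies (++, +m, mm) at an autosomal locus."""

    f_pp: float
    f_pm: float
    f_mm: float

    def __post_init__(self) -> None:
        for name, v in (("f_pp", self.f_pp), ("f_pm", self.f_pm), ("f_mm", self.f_mm)):
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")

    @property
    def is_normalized(self) -> bool:
        return math.isclose(self.f_pp + self.f_pm + self.f_mm, 1.0, abs_tol=_NORM_TOL)

    @classmethod
    def from_allele_freq(cls, q: float) -> "AutosomalState":
        """Hardy-Weinberg state at mutant allele frequency q."""
        p = 1.0 - q
        return cls(p * p, 2.0 * p * q, q * q)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.f_pp, self.f_pm, self.f_mm)


@dataclass(frozen=True)
class SexLinkedState:
    """Adult genotype frequencies at an X-linked locus (XY males).

    Males carry one X (+Y or mY); females are ++, +m or mm. The two
    sexes are normalized separately.
    """

    m_pY: float
    m_mY: float
    w_pp: float
    w_pm: float
    w_mm: float

    def __post_init__(self) -> None:
        for name, v in (
            ("m_pY", self.m_pY),
            ("m_mY", self.m_mY),
            ("w_pp", self.w_pp),
            ("w_pm", self.w_pm),
            ("w_mm", self.w_mm),
        ):
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")

    @property
    def is_normalized(self) -> bool:
        return math.isclose(self.m_pY + self.m_mY, 1.0, abs_tol=_NORM_TOL) and math.isclose(
            self.w_pp + self.w_pm + self.w_mm, 1.0, abs_tol=_NORM_TOL
        )

    @classmethod
    def from_allele_freq(cls, q: float) -> "SexLinkedState":
        """Males at allele frequency q; females at Hardy-Weinberg."""
        p = 1.0 - q
        return cls(p, q, p * p, 2.0 * p * q, q * q)

    def male_tuple(self) -> tuple[float, float]:
        return (self.m_pY, self.m_mY)

    def female_tuple(self) -> tuple[float, float, float]:
        return (self.w_pp, self.w_pm, self.w_mm)


@dataclass(frozen=True)
class BroodOutcome:
    """One mating type's brood after mutation, selection and compensation.

    ``proportions`` are the surviving genotype proportions P(g) (summing
    to 1 over genotypes present); ``Z`` is the relative brood size after
    selection (an all-wildtype brood has size 1) and ``B = min(Z*C, 1)``
    the relative size after compensation.
    """

    proportions: dict[str, float]
    Z: float
    B: float


@dataclass(frozen=True)
class EquilibriumResult:
    """Converged mutation/selection balance.

    ``q_adult`` is the mutant allele frequency among breeding adults,
    ``q_gametic = q_adult + (1 - q_adult)*mu`` the gamete-stage census
    used for comparison with classical results. ``start_agreement`` is
    the relative difference between the low- and high-start solutions
    (nan when only one start was run).
    """

    q_adult: float
    q_gametic: float
    iterations: int
    converged: bool
    state: object
    start_agreement: float = float("nan")
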