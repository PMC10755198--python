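"""Within-brood genetics: Mendelian segregation, mutation, selection, compensation.

A brood is the offspring of one mating type, represented as a genotype
distribution. The pipeline is

    Mendelian proportions -> gamete-stage mutation -> viability selection
    -> competitive release (compensation),

and every mating type goes through the same generic code path; the
per-type numerators are therefore a consequence of the pipeline, not
hard-coded tables. Mutation moves mass ``++ -> +m`` at rate 2*mu,
``+m -> mm`` at mu and ``+Y -> mY`` at mu (no back mutation). Selection
weights each genotype by its viability; compensation rescales the
surviving brood by C, capped at the size of an all-wildtype brood (1).
"""

from __future__ import annotations

from .params import BroodOutcome, ModelParams

AUTOSOMAL_GENOTYPES = ("++", "+m", "mm")
MALE_GENOTYPES = ("+Y", "mY")
FEMALE_GENOTYPES = ("++", "+m", "mm")
SEXLINKED_GENOTYPES = MALE_GENOTYPES + FEMALE_GENOTYPES

# gamete distributions of diploid (female/autosomal) genotypes
_GAMETES = {"++": (("+", 1.0),), "+m": (("+", 0.5), ("m", 0.5)), "mm": (("m", 1.0),)}


class BroodExtinctError(ValueError):
    """Every member of the brood was removed by selection (Z = 0)."""


class InvalidMatingError(ValueError):
    """The parental pair is not valid for the requested locus mode."""


def mendelian_brood(parent_pair: tuple[str, str], locus_mode: str = "autosomal") -> dict[str, float]:
    """Pre-mutation offspring genotype distribution of one mating.

    For ``locus_mode='autosomal'`` the pair is two diploid genotypes
    (order irrelevant). For ``'sexlinked'`` the pair is
    (male genotype, female genotype); sons receive the mother's X and the
    Y, daughters the father's X and one maternal X, and the sexes are
    produced 50:50.
    """
    a, b = parent_pair
    if locus_mode == "autosomal":
        if a not in _GAMETES or b not in _GAMETES:
            raise InvalidMatingError(f"invalid autosomal pair {parent_pair!r}")
        dist: dict[str, float] = {}
        for ga, pa in _GAMETES[a]:
            for gb, pb in _GAMETES[b]:
                g = "".join(sorted(ga + gb))  # '+m' not 'm+'
                dist[g] = dist.get(g, 0.0) + pa * pb
        return dist
    if locus_mode == "sexlinked":
        if a not in MALE_GENOTYPES or b not in _GAMETES:
            raise InvalidMatingError(
                f"sex-linked pair must be (male, female) genotype, got {parent_pair!r}"
            )
        paternal_x = a[0]  # '+' or 'm'
        dist = {}
        for gm, pm in _GAMETES[b]:
            # sons: maternal X + Y
            son = gm + "Y"
            dist[son] = dist.get(son, 0.0) + 0.5 * pm
            # daughters: paternal X + maternal X
            daughter = "".join(sorted(paternal_x + gm))
            dist[daughter] = dist.get(daughter, 0.0) + 0.5 * pm
        return dist
    raise ValueError(f"unknown locus_mode {locus_mode!r}")


def apply_brood_mutation(dist: dict[str, float], mu: float) -> dict[str, float]:
    """Move mutational mass within a brood genotype distribution.

    ``++`` genotypes become ``+m`` at rate 2*mu (two wildtype alleles),
    ``+m`` become ``mm`` at mu, and hemizygous ``+Y`` become ``mY`` at mu.
    Total mass is conserved exactly.
    """
    out = {g: 0.0 for g in dist}
    for g, f in dist.items():
        if g == "++":
            out["++"] += f * (1.0 - 2.0 * mu)
            out["+m"] = out.get("+m", 0.0) + f * 2.0 * mu
        elif g == "+m":
            out["+m"] += f * (1.0 - mu)
            out["mm"] = out.get("mm", 0.0) + f * mu
        elif g == "+Y":
            out["+Y"] += f * (1.0 - mu)
            out["mY"] = out.get("mY", 0.0) + f * mu
        else:  # mm, mY: fully mutant already
            out[g] += f
    return out


def genotype_fitness(genotype: str, params: ModelParams) -> float:
    """Viability of a brood genotype (wildtype classes have fitness 1)."""
    if genotype in ("++", "+Y"):
        return 1.0
    if genotype == "+m":
        return 1.0 - params.h * params.s
    if genotype in ("mm", "mY"):
        return 1.0 - params.s
    raise ValueError(f"unknown genotype {genotype!r}")


def selection_numerators(dist: dict[str, float], params: ModelParams) -> dict[str, float]:
    """Fitness-weighted (unnormalized) surviving-genotype masses."""
    return {g: f * genotype_fitness(g, params) for g, f in dist.items()}


def apply_selection(dist: dict[str, float], params: ModelParams) -> BroodOutcome:
    """Viability selection within a brood; compensation not yet applied.

    Returns a :class:`BroodOutcome` whose ``Z`` is the sum of the
    fitness-weighted masses (relative brood size after selection) and
    whose proportions are those masses normalized. ``B`` is filled in
    with ``Z`` (i.e. the C = 1 value); see :func:`brood_size_after_frc`.
    """
    numer = selection_numerators(dist, params)
    Z = sum(numer.values())
    if Z <= 0.0:
        raise BroodExtinctError("brood extinct: selection removed every offspring (Z = 0)")
    return BroodOutcome(proportions={g: v / Z for g, v in numer.items()}, Z=Z, B=Z)


def brood_size_after_frc(Z: float, C: float) -> float:
    """Relative brood size after competitive release: min(Z*C, 1)."""
    return min(Z * C, 1.0)


def brood_outcome(
    parent_pair: tuple[str, str], params: ModelParams, locus_mode: str = "autosomal"
) -> BroodOutcome:
    """Full pipeline for one mating type (raises if the brood is extinct)."""
    dist = mendelian_brood(parent_pair, locus_mode)
    dist = apply_brood_mutation(dist, params.mu)
    out = apply_selection(dist, params)
    return BroodOutcome(proportions=out.proportions, Z=out.Z, B=brood_size_after_frc(out.Z, params.C))
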