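"""Brood pipeline checked term-by-term against the hand-written
per-mating-type numerators (all six autosomal and six X-linked types),
plus conservation and monotonicity properties.

The expected numerators below are written out independently, one
expression per genotype, with the mutation factor in the first bracket
and the selection weight outside it; the generic pipeline
(segregation -> mutation -> selection) must reproduce every term.
"""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frceq import ModelParams, apply_brood_mutation, apply_selection, brood_outcome, brood_size_after_frc, mendelian_brood
from frceq.brood import BroodExtinctError, InvalidMatingError, selection_numerators


def expected_autosomal_numerators(pair, h, s, mu):
    w_het, w_hom = 1.0 - h * s, 1.0 - s
    return {
        ("++", "++"): {"++": 1.0 - 2 * mu, "+m": 2 * mu * w_het, "mm": 0.0},
        ("++", "+m"): {
            "++": 0.5 * (1 - 2 * mu),
            "+m": (0.5 * (1 - mu) + 0.5 * 2 * mu) * w_het,
            "mm": 0.5 * mu * w_hom,
        },
        ("++", "mm"): {"++": 0.0, "+m": (1 - mu) * w_het, "mm": mu * w_hom},
        ("+m", "+m"): {
            "++": 0.25 * (1 - 2 * mu),
            "+m": (0.5 * (1 - mu) + 0.25 * 2 * mu) * w_het,
            "mm": (0.25 + 0.5 * mu) * w_hom,
        },
        ("+m", "mm"): {"++": 0.0, "+m": 0.5 * (1 - mu) * w_het, "mm": (0.5 + 0.5 * mu) * w_hom},
        ("mm", "mm"): {"++": 0.0, "+m": 0.0, "mm": w_hom},
    }[pair]


def expected_sexlinked_numerators(pair, h, s, mu):
    w_het, w_hom = 1.0 - h * s, 1.0 - s
    return {
        ("+Y", "++"): {
            "+Y": 0.5 * (1 - mu), "mY": 0.5 * mu * w_hom,
            "++": 0.5 * (1 - 2 * mu), "+m": 0.5 * 2 * mu * w_het, "mm": 0.0,
        },
        ("+Y", "+m"): {
            "+Y": 0.25 * (1 - mu), "mY": (0.25 + 0.25 * mu) * w_hom,
            "++": 0.25 * (1 - 2 * mu),
            "+m": (0.25 * (1 - mu) + 0.25 * 2 * mu) * w_het,
            "mm": 0.25 * mu * w_hom,
        },
        ("+Y", "mm"): {
            "+Y": 0.0, "mY": 0.5 * w_hom,
            "++": 0.0, "+m": 0.5 * (1 - mu) * w_het, "mm": 0.5 * mu * w_hom,
        },
        ("mY", "++"): {
            "+Y": 0.5 * (1 - mu), "mY": 0.5 * mu * w_hom,
            "++": 0.0, "+m": 0.5 * (1 - mu) * w_het, "mm": 0.5 * mu * w_hom,
        },
        ("mY", "+m"): {
            "+Y": 0.25 * (1 - mu), "mY": (0.25 + 0.25 * mu) * w_hom,
            "++": 0.0, "+m": 0.25 * (1 - mu) * w_het, "mm": (0.25 + 0.25 * mu) * w_hom,
        },
        ("mY", "mm"): {"+Y": 0.0, "mY": 0.5 * w_hom, "++": 0.0, "+m": 0.0, "mm": 0.5 * w_hom},
    }[pair]


SEXLINKED_PAIRS = [("+Y", "++"), ("+Y", "+m"), ("+Y", "mm"), ("mY", "++"), ("mY", "+m"), ("mY", "mm")]


class TestMendelianBroods:
    @pytest.mark.parametrize(
        "pair, expected",
        [
            (("+m", "+m"), {"++": 0.25, "+m": 0.5, "mm": 0.25}),
            (("++", "++"), {"++": 1.0}),
            (("++", "mm"), {"+m": 1.0}),
        ],
    )
    def test_autosomal_segregation(self, pair, expected):
        assert mendelian_brood(pair, "autosomal") == pytest.approx(expected)

    def test_sexlinked_segregation_is_half_each_sex(self):
        brood = mendelian_brood(("mY", "+m"), "sexlinked")
        assert brood == pytest.approx({"+Y": 0.25, "mY": 0.25, "+m": 0.25, "mm": 0.25})

    def test_invalid_pairs_rejected(self):
        with pytest.raises(InvalidMatingError):
            mendelian_brood(("+Y", "mY"), "sexlinked")  # two males
        with pytest.raises(InvalidMatingError):
            mendelian_brood(("+Y", "++"), "autosomal")


class TestMutation:
    def test_mass_moves_at_the_per_allele_rates(self):
        mu = 1e-3
        out = apply_brood_mutation({"++": 0.5, "+m": 0.5}, mu)
        assert out["++"] == pytest.approx(0.5 * (1 - 2 * mu))
        assert out["+m"] == pytest.approx(0.5 * (1 - mu) + 0.5 * 2 * mu)
        assert out["mm"] == pytest.approx(0.5 * mu)

    def test_all_mutant_brood_is_invariant(self):
        assert apply_brood_mutation({"mm": 1.0}, 1e-3) == {"mm": 1.0}

    def test_zero_rate_is_identity(self):
        dist = {"++": 0.3, "+m": 0.5, "mm": 0.2}
        assert apply_brood_mutation(dist, 0.0) == pytest.approx(dist)

    @settings(max_examples=100, derandomize=True)
    @given(
        f=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=5, max_size=5),
        mu=st.floats(min_value=0.0, max_value=0.01),
    )
    def test_conserves_mass_exactly(self, f, mu):
        total = sum(f)
        dist = dict(zip(("++", "+m", "mm", "+Y", "mY"), f))
        out = apply_brood_mutation(dist, mu)
        assert math.isclose(sum(out.values()), total, rel_tol=1e-12, abs_tol=1e-15)


@pytest.mark.parametrize("pair", [("++", "++"), ("++", "+m"), ("++", "mm"), ("+m", "+m"), ("+m", "mm"), ("mm", "mm")])
def test_autosomal_numerators_match_per_type_listings(pair):
    h, s, mu = 0.3, 0.7, 1e-3
    params = ModelParams(h=h, s=s, mu=mu)
    dist = apply_brood_mutation(mendelian_brood(pair, "autosomal"), mu)
    numer = selection_numerators(dist, params)
    expected = expected_autosomal_numerators(pair, h, s, mu)
    for g, v in expected.items():
        assert numer.get(g, 0.0) == pytest.approx(v, abs=1e-15), (pair, g)
    # pre-selection mass is conserved: the bracketed mutation terms sum to 1
    assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("pair", SEXLINKED_PAIRS)
def test_sexlinked_numerators_match_per_type_listings(pair):
    h, s, mu = 0.3, 0.7, 1e-3
    params = ModelParams(h=h, s=s, mu=mu)
    dist = apply_brood_mutation(mendelian_brood(pair, "sexlinked"), mu)
    numer = selection_numerators(dist, params)
    expected = expected_sexlinked_numerators(pair, h, s, mu)
    for g, v in expected.items():
        assert numer.get(g, 0.0) == pytest.approx(v, abs=1e-15), (pair, g)
    assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)


class TestSelectionAndCompensation:
    def test_proportions_normalized_and_Z_is_numerator_sum(self):
        params = ModelParams(h=0.5, s=0.4, mu=1e-5)
        dist = apply_brood_mutation(mendelian_brood(("+m", "+m"), "autosomal"), params.mu)
        out = apply_selection(dist, params)
        assert sum(out.proportions.values()) == pytest.approx(1.0, abs=1e-12)
        assert out.Z == pytest.approx(sum(selection_numerators(dist, params).values()))

    def test_no_selection_leaves_distribution_unchanged(self):
        params = ModelParams(h=0.0, s=0.0, mu=1e-5)
        dist = apply_brood_mutation(mendelian_brood(("+m", "+m"), "autosomal"), params.mu)
        out = apply_selection(dist, params)
        assert out.Z == pytest.approx(1.0, abs=1e-12)
        assert out.proportions == pytest.approx(dist)

    def test_all_mutant_brood_size_is_one_minus_s(self):
        params = ModelParams(h=0.5, s=0.4, mu=1e-5)
        out = brood_outcome(("mm", "mm"), params, "autosomal")
        assert out.Z == pytest.approx(1.0 - params.s)

    def test_lethal_all_mutant_brood_is_extinct(self):
        params = ModelParams(h=0.0, s=1.0, mu=1e-7)
        dist = apply_brood_mutation(mendelian_brood(("mm", "mm"), "autosomal"), params.mu)
        with pytest.raises(BroodExtinctError):
            apply_selection(dist, params)

    @pytest.mark.parametrize(
        "Z, C, expected",
        [(0.70, 1.5, 1.0), (0.5, 1.5, 0.75), (0.9, 1.0, 0.9)],
    )
    def test_compensated_size(self, Z, C, expected):
        assert brood_size_after_frc(Z, C) == pytest.approx(expected)

    @settings(max_examples=100, derandomize=True)
    @given(
        Z1=st.floats(min_value=0.0, max_value=1.0),
        Z2=st.floats(min_value=0.0, max_value=1.0),
        C1=st.floats(min_value=1.0, max_value=100.0),
        C2=st.floats(min_value=1.0, max_value=100.0),
    )
    def test_compensation_monotone_and_capped(self, Z1, Z2, C1, C2):
        assert brood_size_after_frc(Z1, C1) <= 1.0
        if Z1 <= Z2:
            assert brood_size_after_frc(Z1, C1) <= brood_size_after_frc(Z2, C1)
        if C1 <= C2:
            assert brood_size_after_frc(Z1, C1) <= brood_size_after_frc(Z1, C2)
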