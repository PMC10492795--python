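"""Unit and property tests for the equilibrium thermodynamics core."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from diplothermo import (
    Allele,
    EnergyParams,
    Genotype,
    SystemConfig,
    folded_fraction,
    kd_from_energy,
    model1_phenotype,
    model2_equilibrium,
    model2_phenotype,
)


def closed_single_het(ddg: float, p: EnergyParams) -> float:
    """Printed closed form for a heterozygous single folding mutant."""
    rt = p.RT
    a = math.exp(p.dG_folding_wt / rt)
    x = math.exp((p.dG_folding_wt + ddg) / rt)
    return (2 + a + x) / (2 * (1 + x))


def closed_between(ddg_a: float, ddg_b: float, p: EnergyParams) -> float:
    """Printed closed form for one folding mutation on each allele."""
    rt = p.RT
    a = math.exp(p.dG_folding_wt / rt)
    xa = math.exp((p.dG_folding_wt + ddg_a) / rt)
    xb = math.exp((p.dG_folding_wt + ddg_b) / rt)
    return (1 + a) * (2 + xa + xb) / (2 * (1 + xa) * (1 + xb))


def closed_homozygote(ddg: float, p: EnergyParams) -> float:
    rt = p.RT
    return (1 + math.exp(p.dG_folding_wt / rt)) / (
        1 + math.exp((p.dG_folding_wt + ddg) / rt)
    )


class TestFoldedFraction:
    @pytest.mark.parametrize(
        "dG, expected, tol",
        [
            (0.0, 0.5, 0.0),  # symmetric two-state system
            (-1000.0, 1.0, 1e-12),  # fully stabilised limit
            (1000.0, 0.0, 1e-12),  # fully destabilised limit
            # frozen from extended-precision evaluation of the Boltzmann form
            (-2.0, 0.9629172107355422, 1e-12),
        ],
    )
    def test_examples(self, params, dG, expected, tol):
        assert folded_fraction(dG, params) == pytest.approx(expected, abs=tol)

    @pytest.mark.parametrize("bad", [math.nan, math.inf, -math.inf])
    def test_nonfinite_rejected(self, params, bad):
        with pytest.raises(ValueError):
            folded_fraction(bad, params)

    def test_no_overflow_at_extreme_energies(self, params):
        # |dG/RT| ~ 650 exceeds the exp clip; must stay finite and saturated
        assert folded_fraction(-400.0, params) == pytest.approx(1.0, abs=1e-12)
        assert folded_fraction(400.0, params) == pytest.approx(0.0, abs=1e-12)

    @given(
        # fractions saturate to exactly 0/1 beyond |dG/RT| ~ 36; strict
        # monotonicity only holds where the fraction is representable
        st.floats(-20.0, 20.0),
        st.floats(1e-3, 10.0),
    )
    def test_strictly_decreasing(self, params, dG, delta):
        assert folded_fraction(dG, params) > folded_fraction(dG + delta, params)

    @given(st.floats(-1e4, 1e4), st.floats(0.0, 100.0))
    def test_bounded_and_nonincreasing_everywhere(self, params, dG, delta):
        f1, f2 = folded_fraction(dG, params), folded_fraction(dG + delta, params)
        assert 0.0 <= f2 <= f1 <= 1.0

    def test_vectorized(self, params):
        grid = np.linspace(-10, 10, 101)
        f = folded_fraction(grid, params)
        assert f.shape == grid.shape
        assert np.all(np.diff(f) < 0)


class TestKd:
    def test_reference_energy_gives_unit_kd(self, params):
        assert kd_from_energy(0.0, params) == 1.0

    def test_closed_form(self, params):
        assert kd_from_energy(-params.RT * math.log(2.0), params) == pytest.approx(0.5)

    def test_moderate_affinity_significand(self, params):
        kd = kd_from_energy(-5.0, params)
        significand = kd / 10 ** math.floor(math.log10(kd))
        assert significand == pytest.approx(2.91, abs=0.005)


class TestModel1:
    def test_wildtype_is_exactly_one(self, params):
        assert model1_phenotype(Genotype.wildtype(), params) == 1.0

    def test_null_over_wt_is_half(self, params):
        # one of two equal expression units absent
        assert model1_phenotype(Genotype.hemizygote(), params) == 0.5

    @pytest.mark.parametrize("ddg", [-2.0, -0.5, 0.0, 2.0, 5.0, 13.0])
    def test_single_het_matches_printed_closed_form(self, params, ddg):
        W = model1_phenotype(Genotype.single_het(ddg), params)
        assert W == pytest.approx(closed_single_het(ddg, params), abs=1e-12)

    def test_single_het_frozen_example(self, params):
        # ddG = +2 cancels dG_wt = -2: frozen oracle value
        W = model1_phenotype(Genotype.single_het(2.0), params)
        assert W == pytest.approx(0.7596277200290489, abs=1e-12)

    @pytest.mark.parametrize("ddg_a", [-2.0, 0.0, 3.0, 8.0])
    @pytest.mark.parametrize("ddg_b", [-1.0, 0.0, 4.0, 13.0])
    def test_all_genotype_shapes_match_closed_forms(self, params, ddg_a, ddg_b):
        between = model1_phenotype(Genotype.between_allele(ddg_a, ddg_b), params)
        within = model1_phenotype(Genotype.within_allele(ddg_a, ddg_b), params)
        homo = model1_phenotype(Genotype.homozygote(ddg_a), params)
        assert between == pytest.approx(closed_between(ddg_a, ddg_b, params), abs=1e-12)
        assert within == pytest.approx(
            closed_single_het(ddg_a + ddg_b, params), abs=1e-12
        )
        assert homo == pytest.approx(closed_homozygote(ddg_a, params), abs=1e-12)

    @given(st.floats(-2.0, 13.0), st.floats(0.01, 5.0))
    def test_monotone_in_ddg(self, params, ddg, delta):
        for make in (Genotype.single_het, Genotype.homozygote):
            assert model1_phenotype(make(ddg), params) >= model1_phenotype(
                make(ddg + delta), params
            )

    def test_between_allele_additivity_identity(self, params):
        # additive expectation coincides with the observed between-allele double
        for a in (-2.0, 0.0, 2.0, 7.0):
            for b in (-1.0, 1.0, 13.0):
                W_ab = model1_phenotype(Genotype.between_allele(a, b), params)
                W_a = model1_phenotype(Genotype.single_het(a), params)
                W_b = model1_phenotype(Genotype.single_het(b), params)
                assert W_ab == pytest.approx(W_a + W_b - 1.0, abs=1e-12)


class TestModel2Equilibrium:
    def test_no_ligand(self, params):
        c = SystemConfig(ligand_ratio=0.0)
        s = model2_equilibrium(Genotype.wildtype(), params, c)
        assert s.free_ligand == 0.0
        assert s.total_bound == 0.0
        # protein still partitions between unfolded and folded states
        assert sum(s.folded) + sum(s.unfolded) == pytest.approx(1.0, rel=1e-12)

    def test_binding_abolished(self, params):
        c = SystemConfig(ligand_ratio=1.0)
        g = Genotype(Allele(ddG_binding=1000.0), Allele(ddG_binding=1000.0))
        s = model2_equilibrium(g, params, c)
        assert abs(s.free_ligand - c.L_T) <= 1e-9

    @pytest.mark.parametrize("ratio", [0.8, 1.0, 2.0, 10.0])
    @pytest.mark.parametrize(
        "genotype",
        [
            Genotype.wildtype(),
            Genotype.hemizygote(),
            Genotype.between_allele(3.0, -1.0),
            Genotype(Allele(2.0, 1.0), Allele(0.0, 4.0)),
        ],
    )
    def test_conservation_invariants(self, params, ratio, genotype):
        c = SystemConfig(ligand_ratio=ratio)
        s = model2_equilibrium(genotype, params, c)
        assert abs(s.free_ligand + s.total_bound - c.L_T) / c.L_T <= 1e-10
        for allele, u, f, b in zip(genotype.alleles, s.unfolded, s.folded, s.bound):
            if allele.expressed:
                assert u + f + b == pytest.approx(0.5 * c.X_T, rel=1e-10)
            else:
                assert (u, f, b) == (0.0, 0.0, 0.0)

    def test_dense_scan_oracle_excess_ligand(self, params):
        # independent root bracketing of the monotone conservation map
        c = SystemConfig(ligand_ratio=10.0)
        g = Genotype.wildtype()
        s = model2_equilibrium(g, params, c)
        rt = params.RT
        scale = math.exp(params.dG_binding_wt / rt) * (
            1 + math.exp(params.dG_folding_wt / rt)
        )
        L = np.linspace(0.0, c.L_T, 10_000_001)
        resid = L + 2 * (0.5 * c.X_T * L / (L + scale)) - c.L_T
        i = np.searchsorted(resid > 0, True)
        lo, hi = L[i - 1], L[i]
        assert lo <= s.free_ligand <= hi
        # in ligand excess nearly all folded protein is complexed
        assert s.total_bound == pytest.approx(
            s.total_bound + s.total_folded, rel=1e-3
        )
        assert s.free_ligand == pytest.approx(c.L_T - s.total_bound, rel=1e-12)


class TestModel2Phenotype:
    def test_wildtype_is_exactly_one(self, params, ratio1):
        assert model2_phenotype(Genotype.wildtype(), params, ratio1) == 1.0

    def test_hemizygote_under_ligand_limitation(self, params):
        # one null allele at ratio 0.8: 0.5 bound out of 0.8 -> 62.5% of WT
        c = SystemConfig(ligand_ratio=0.8)
        W = model2_phenotype(Genotype.hemizygote(), params, c)
        assert W == pytest.approx(0.625, abs=1e-3)

    def test_hemizygote_in_ligand_excess(self, params):
        c = SystemConfig(ligand_ratio=10.0)
        W = model2_phenotype(Genotype.hemizygote(), params, c)
        assert W == pytest.approx(0.5, abs=1e-4)

    def test_no_ligand_reference_rejected(self, params):
        with pytest.raises(ValueError):
            model2_phenotype(
                Genotype.wildtype(), params, SystemConfig(ligand_ratio=0.0)
            )

    @given(st.floats(-2.0, 13.0), st.floats(0.01, 5.0))
    def test_monotone_in_each_energy(self, params, ratio1, ddg, delta):
        for kw in ({"ddG_folding": ddg}, {"ddG_binding": ddg}):
            kw2 = {k: v + delta for k, v in kw.items()}
            W1 = model2_phenotype(Genotype.single_het(**kw), params, ratio1)
            W2 = model2_phenotype(Genotype.single_het(**kw2), params, ratio1)
            assert W2 <= W1 + 1e-12

    def test_decoupling_limit_with_increasing_ligand(self, params):
        """Between-allele additivity residual vanishes as ligand saturates.

        The residual scales roughly as 1/ratio (alleles compete for a finite
        ligand pool); by ratio 1e5 it is below 1e-6.
        """
        ddgs = np.arange(-2.0, 13.1, 1.5)
        worst = []
        for ratio in (1e3, 1e4, 1e5):
            c = SystemConfig(ligand_ratio=ratio)
            het = {d: model2_phenotype(Genotype.single_het(d), params, c) for d in ddgs}
            worst.append(
                max(
                    abs(
                        model2_phenotype(Genotype.between_allele(a, b), params, c)
                        - (het[a] + het[b] - 1.0)
                    )
                    for a in ddgs
                    for b in ddgs
                )
            )
        assert worst[0] > worst[1] > worst[2]
        assert worst[2] <= 1e-6
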