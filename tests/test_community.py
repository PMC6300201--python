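"""Carbon biomass conversions, Shannon diversity and bioturbation potential."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from benthoflux.community import (
    ProkaryoteCensus,
    SizeClassStocks,
    TaxonRecord,
    afdw_to_carbon,
    bpc,
    laternula_biomass,
    prokaryote_biomass,
    shannon,
    stock_fractions,
)
from benthoflux.errors import DomainError, InconsistentRecordError


def taxon(density=100.0, biomass=50.0, m=3, r=4, name="t"):
    return TaxonRecord(name, density, biomass, m, r)


class TestAfdw:
    def test_half_of_afdw_is_carbon(self):
        assert afdw_to_carbon(10.0) == 5.0
        assert afdw_to_carbon(0.0) == 0.0

    def test_chained_with_ash_subtraction(self):
        dry, ash = 12.0, 2.0
        assert afdw_to_carbon(dry - ash) == 5.0

    @given(x=st.floats(0, 1e4))
    def test_homogeneous(self, x):
        assert afdw_to_carbon(2 * x) == pytest.approx(2 * afdw_to_carbon(x))

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            afdw_to_carbon(-0.1)


class TestProkaryotes:
    def test_site_like_volumetric_biomass(self):
        out = prokaryote_biomass(ProkaryoteCensus(6.1e9, 0.142))
        assert out["volumetric"] == pytest.approx(0.26, abs=0.005)  # mg C cm^-3

    def test_areal_integration_over_five_cm(self):
        # 0.26 mg C cm^-3 over 5 cm -> 13 g C m^-2
        out = prokaryote_biomass(ProkaryoteCensus(6.1e9, 0.142, integration_depth=5.0))
        assert out["areal"] == pytest.approx(13.0, rel=0.01)

    def test_zero_density(self):
        assert prokaryote_biomass(ProkaryoteCensus(0.0, 0.142))["areal"] == 0.0


class TestLaternula:
    def test_zero_density_zero_biomass(self):
        out = laternula_biomass([], density=0.0, slope=0.5)
        assert out["biomass"] == 0.0

    def test_site_like_population(self):
        # widths chosen so mean individual carbon is 0.39 g C
        widths = [1.56]
        out = laternula_biomass(widths, density=93.0, slope=0.5)
        assert out["individual"] == pytest.approx(0.39, abs=1e-9)
        assert out["biomass"] == pytest.approx(36.3, abs=0.1)

    def test_doubling_widths_doubles_biomass_with_zero_intercept(self):
        a = laternula_biomass([1.0, 2.0], 50.0, slope=0.4)
        b = laternula_biomass([2.0, 4.0], 50.0, slope=0.4)
        assert b["biomass"] == pytest.approx(2 * a["biomass"])

    def test_missing_widths_with_nonzero_density_rejected(self):
        with pytest.raises(DomainError):
            laternula_biomass([], density=10.0, slope=0.5)


def brute_force_bpc(records, variant):
    """Oracle: direct summation of the defining formula, term by term."""
    total = 0.0
    for rec in records:
        if rec.density == 0:
            continue
        per_capita = rec.biomass / rec.density
        if variant == "sqrt":
            per_capita = math.sqrt(per_capita)
        total += per_capita * rec.density * rec.mobility * rec.reworking
    return total


class TestBPc:
    def test_empty_community_is_zero(self):
        assert bpc([]) == 0.0

    def test_single_taxon_both_variants_by_hand(self):
        rec = taxon(density=100, biomass=50, m=3, r=4)
        assert bpc([rec], "as_printed") == pytest.approx(600.0)
        assert bpc([rec], "sqrt") == pytest.approx(math.sqrt(0.5) * 100 * 12)

    @pytest.mark.parametrize("variant", ["as_printed", "sqrt"])
    def test_matches_brute_force_on_random_communities(self, variant, rng):
        for _ in range(20):
            n = rng.integers(1, 51)
            records = [
                taxon(
                    density=float(rng.uniform(0.1, 1e4)),
                    biomass=float(rng.uniform(0, 100)),
                    m=int(rng.integers(1, 5)),
                    r=int(rng.integers(1, 6)),
                    name=f"t{i}",
                )
                for i in range(n)
            ]
            assert bpc(records, variant) == pytest.approx(
                brute_force_bpc(records, variant), rel=1e-12
            )

    def test_additive_over_disjoint_communities(self):
        a = [taxon(name="a")]
        b = [taxon(density=20, biomass=5, m=1, r=2, name="b")]
        assert bpc(a + b) == pytest.approx(bpc(a) + bpc(b))

    @given(scale=st.floats(0.1, 100))
    def test_homogeneous_in_biomass_as_printed(self, scale):
        base = [taxon(biomass=10.0), taxon(density=30, biomass=3, m=2, r=5, name="u")]
        scaled = [
            TaxonRecord(r.taxon, r.density, r.biomass * scale, r.mobility, r.reworking)
            for r in base
        ]
        assert bpc(scaled) == pytest.approx(scale * bpc(base), rel=1e-9)

    def test_biomass_without_abundance_rejected(self):
        with pytest.raises(InconsistentRecordError):
            bpc([taxon(density=0.0, biomass=5.0)])

    def test_invalid_trait_scores_rejected(self):
        with pytest.raises(DomainError):
            taxon(m=5)
        with pytest.raises(DomainError):
            taxon(r=0)


class TestShannon:
    def test_single_taxon_zero_diversity(self):
        assert shannon([taxon()]) == 0.0

    def test_two_equal_taxa(self):
        recs = [taxon(name="a"), taxon(name="b")]
        assert shannon(recs) == pytest.approx(math.log(2))

    @pytest.mark.parametrize("s", [3, 7, 20])
    def test_uniform_community_attains_log_s(self, s):
        recs = [taxon(name=f"t{i}") for i in range(s)]
        assert shannon(recs) == pytest.approx(math.log(s))

    @given(scale=st.floats(0.01, 1000))
    def test_invariant_to_density_rescaling(self, scale):
        recs = [taxon(density=10, name="a"), taxon(density=30, name="b")]
        scaled = [TaxonRecord(r.taxon, r.density * scale, r.biomass, r.mobility, r.reworking)
                  for r in recs]
        assert shannon(scaled) == pytest.approx(shannon(recs), rel=1e-9)

    def test_zero_density_taxa_excluded(self):
        recs = [taxon(name="a"), taxon(density=0.0, biomass=0.0, name="b")]
        assert shannon(recs) == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(DomainError):
            shannon([taxon(density=0.0, biomass=0.0)])


class TestStockFractions:
    @pytest.mark.parametrize(
        "laternula,macro,expected",
        [(36.0, 56.0, 39.0), (54.0, 75.0, 42.0), (81.0, 37.0, 69.0)],
    )
    def test_laternula_share_of_macrofauna(self, laternula, macro, expected):
        stocks = SizeClassStocks(prokaryote=10.0, meiofauna=1.0,
                                 macrofauna_excl_le=macro, laternula=laternula)
        out = stock_fractions(stocks)
        assert round(out["laternula_share_of_macrofauna"]) == expected

    def test_all_macrofauna_gives_full_fraction(self):
        stocks = SizeClassStocks(0.0, 0.0, 10.0, 5.0)
        assert stock_fractions(stocks)["macrofauna_fraction"] == pytest.approx(100.0)

    def test_shares_are_complementary(self):
        stocks = SizeClassStocks(2.0, 1.0, 30.0, 70.0)
        out = stock_fractions(stocks)
        assert out["macrofauna_fraction"] <= 100.0
        le = out["laternula_share_of_macrofauna"]
        assert le + (100.0 - le) == pytest.approx(100.0)

    def test_zero_total_rejected(self):
        with pytest.raises(DomainError):
            stock_fractions(SizeClassStocks(0, 0, 0, 0))
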