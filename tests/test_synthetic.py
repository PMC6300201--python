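"""Generator contracts: determinism, truth self-consistency, realism envelopes."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from benthoflux.community import TaxonRecord, bpc, shannon
from benthoflux.chamber import ChamberGeometry, IncubationSeries, total_flux
from benthoflux.errors import DomainError
from benthoflux.synthetic import (
    PRESETS,
    ScenarioConfig,
    flux_recovery_experiment,
    gen_community,
    gen_incubation,
    gen_layers,
    gen_microprofile_arrays,
    gen_porewater,
    microprofile_truth,
    opd_at_threshold,
    simulate_scenario,
)
from benthoflux.sediment import GravimetricSample, porosity


def file_hashes(directory):
    return {
        f.name: hashlib.sha256(f.read_bytes()).hexdigest()
        for f in sorted(Path(directory).iterdir())
    }


def test_scenario_files_byte_identical_for_fixed_seed(tmp_path):
    cfg = ScenarioConfig.from_preset("creek_like", seed=77)
    simulate_scenario(cfg, tmp_path / "a")
    simulate_scenario(cfg, tmp_path / "b")
    assert file_hashes(tmp_path / "a") == file_hashes(tmp_path / "b")


def test_different_seeds_differ(tmp_path):
    simulate_scenario(ScenarioConfig.from_preset("creek_like", seed=1), tmp_path / "a")
    simulate_scenario(ScenarioConfig.from_preset("creek_like", seed=2), tmp_path / "b")
    assert file_hashes(tmp_path / "a") != file_hashes(tmp_path / "b")


class TestIncubationGenerator:
    def test_noiseless_two_point_recovers_flux_exactly(self, faro):
        geom = ChamberGeometry(19.0, (18.0,))
        true_flux = faro.total_fluxes["O2"]
        rate = geom.area_m2 / geom.volume_l * 1000.0 / 24.0
        concs = (300.0, 300.0 + true_flux * rate * 21.0)
        series = IncubationSeries("O2", (0.0, 21.0), concs, geom, detection_limit=0.0)
        assert total_flux(series).value == pytest.approx(true_flux, rel=1e-12)

    def test_emitted_table_round_trips_through_estimator(self, faro):
        cfg = ScenarioConfig(seed=3, site=faro, n_chambers=2)
        inc, geom_df, truth = gen_incubation(cfg)
        cid = inc["chamber_id"].iloc[0]
        g = geom_df[geom_df.chamber_id == cid]
        geom = ChamberGeometry(float(g.diameter_cm.iloc[0]), tuple(g.height_cm))
        o2 = inc[(inc.chamber_id == cid) & (inc.analyte == "O2")].sort_values("time_h")
        series = IncubationSeries("O2", tuple(o2.time_h), tuple(o2.conc_umol_L), geom)
        res = total_flux(series)
        assert res.value == pytest.approx(truth["total_fluxes"]["O2"], rel=0.05)

    def test_light_and_dark_chambers_emitted(self, faro):
        inc, _, _ = gen_incubation(ScenarioConfig(seed=3, site=faro))
        assert set(inc["light"]) == {"transparent", "black"}


class TestMicroprofileGenerator:
    def test_preset_penetration_depths_inside_observed_envelope(self):
        for preset in PRESETS.values():
            assert 3.0 <= preset.opd_mm <= 8.0
            assert 3.0 <= opd_at_threshold(preset) <= 8.0

    def test_preset_dou_inside_observed_envelope(self):
        for preset in PRESETS.values():
            assert 1.5 <= preset.dou <= 2.4

    def test_zero_consumption_flat_below_swi(self, faro):
        import dataclasses

        site = dataclasses.replace(faro, dou=1e-12, opd_mm=8.0, o2_rel_noise=0.0)
        cfg = ScenarioConfig(seed=0, site=site)
        profile, _ = gen_microprofile_arrays(cfg, np.random.default_rng(0))
        below = np.asarray(profile.depths_mm) > 0
        o2 = np.asarray(profile.o2_umol_l)
        assert np.ptp(o2[below][np.asarray(profile.depths_mm)[below] < 8.0]) < 1e-6

    def test_profile_continuous_at_interface(self, faro):
        truth = microprofile_truth(faro)
        import dataclasses

        site = dataclasses.replace(faro, o2_rel_noise=0.0)
        profile, _ = gen_microprofile_arrays(
            ScenarioConfig(seed=0, site=site), np.random.default_rng(0)
        )
        z = np.asarray(profile.depths_mm)
        o2 = np.asarray(profile.o2_umol_l)
        i0 = int(np.argmin(np.abs(z)))
        assert o2[i0] == pytest.approx(truth["c_swi"], rel=1e-6)

    def test_bad_span_rejected(self, faro):
        with pytest.raises(DomainError):
            gen_microprofile_arrays(
                ScenarioConfig(seed=0, site=faro, profile_zmax_mm=5.0),
                np.random.default_rng(0),
            )


class TestPorewaterGenerator:
    def test_sulfate_flat_at_27_mM(self, faro):
        df, _ = gen_porewater(ScenarioConfig(seed=5, site=faro, n_cores=1))
        so4 = df[df.analyte == "SO4"]["conc_umol_L"]
        assert so4.mean() == pytest.approx(27_000.0, rel=0.01)

    def test_truth_gradients_match_imposed_fluxes(self, faro):
        _, truth = gen_porewater(ScenarioConfig(seed=5, site=faro, n_cores=1))
        for analyte, rec in truth["gradients"].items():
            assert rec["flux"] == pytest.approx(faro.diffusive_fluxes[analyte])

    def test_bottom_water_point_present_once(self, faro):
        df, _ = gen_porewater(ScenarioConfig(seed=5, site=faro, n_cores=2))
        for (_, _), grp in df.groupby(["core_id", "analyte"]):
            assert (grp.depth_cm < 0).sum() == 1


class TestLayerGenerator:
    def test_gravimetric_masses_invert_to_target_porosity(self, faro):
        df, _ = gen_layers(ScenarioConfig(seed=8, site=faro))
        phis = [
            porosity(GravimetricSample.from_psu(r.wet_mass_g, r.dry_mass_g, r.salinity_psu))
            for r in df.itertuples()
        ]
        assert np.mean(phis) == pytest.approx(faro.porosity, abs=0.02)

    def test_organic_carbon_never_exceeds_total(self, faro):
        df, _ = gen_layers(ScenarioConfig(seed=8, site=faro))
        assert (df.toc_ugC_mg <= df.tc_ugC_mg).all()


class TestCommunityGenerator:
    def test_truth_equals_metrics_on_emitted_table(self, faro):
        taxa, _, truth = gen_community(ScenarioConfig(seed=21, site=faro))
        for rep, grp in taxa.groupby("replicate"):
            records = [
                TaxonRecord(r.taxon, r.density_ind_m2, r.biomass_gC_m2, int(r.Mi), int(r.Ri))
                for r in grp.itertuples()
            ]
            assert bpc(records) == pytest.approx(truth["replicates"][rep]["bpc_as_printed"])
            assert shannon(records) == pytest.approx(truth["replicates"][rep]["shannon"])

    def test_dominant_bivalve_share_matches_preset(self):
        for name, preset in PRESETS.items():
            _, census, truth = gen_community(ScenarioConfig(seed=2, site=preset))
            macro_total = preset.macrofauna_excl_le_gC + truth["laternula_biomass_gC_m2"]
            share = truth["laternula_biomass_gC_m2"] / macro_total
            assert share == pytest.approx(preset.laternula_share, abs=1e-9)

    def test_single_taxon_preset_has_zero_diversity(self, faro):
        import dataclasses

        site = dataclasses.replace(faro, n_taxa=1)
        taxa, _, truth = gen_community(ScenarioConfig(seed=2, site=site))
        assert truth["replicates"][1]["shannon"] == 0.0


def test_preset_diffusive_shares_inside_observed_envelope():
    for preset in PRESETS.values():
        for analyte, diff in preset.diffusive_fluxes.items():
            if analyte == "SO4":
                continue
            share = abs(diff) / abs(preset.total_fluxes[analyte])
            assert 0.003 <= share <= 0.13
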