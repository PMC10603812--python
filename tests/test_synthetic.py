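"""Synthetic study generator: determinism, round trips, noiseless closure."""

import numpy as np
import pandas as pd
import pytest

from crowdtherm import (
    GroundTruth,
    fit_chi,
    fit_chi_temperature,
    fit_partial_molar_volume,
    gen_activity_series,
    gen_density_series,
    gen_folding_dataset,
    gen_hbond_tables,
    make_bundle,
)
from crowdtherm.folding import gibbs_helmholtz_deltas
from crowdtherm.hbonds import network_delta
from crowdtherm.synthetic import SyntheticBundle, default_hbond_truth
from crowdtherm import io as ctio


class TestDensityGenerator:
    def test_pure_water_density(self, noiseless_truth):
        df = gen_density_series(noiseless_truth, [0.0, 0.5, 1.0])
        assert df.density_g_cm3.iloc[0] == pytest.approx(18.015 / 18.07, rel=1e-9)

    def test_noiseless_inversion(self, noiseless_truth, tmp_path):
        df = gen_density_series(noiseless_truth, np.linspace(0, 1.5, 8))
        df.to_csv(tmp_path / "density.csv", index=False)
        series = next(iter(ctio.read_density(tmp_path / "density.csv",
                                             m_c=noiseless_truth.m_c).values()))
        fit = fit_partial_molar_volume(series)
        assert fit.vbar_c_ == pytest.approx(noiseless_truth.vbar_c, abs=1e-9)

    def test_seed_determinism(self):
        t = GroundTruth(seed=7)
        a = gen_density_series(t, [0.0, 0.5, 1.0])
        b = gen_density_series(t, [0.0, 0.5, 1.0])
        pd.testing.assert_frame_equal(a, b)

    def test_negative_molality_rejected(self, noiseless_truth):
        with pytest.raises(ValueError):
            gen_density_series(noiseless_truth, [-0.1, 0.0])


class TestActivityGenerator:
    def test_pure_solvent_activity_one(self, noiseless_truth):
        df = gen_activity_series(noiseless_truth, [0.0, 0.5],
                                 [288.0, 298.0, 308.0])
        assert np.allclose(df[df.molality == 0.0].water_activity, 1.0)

    def test_noiseless_chi_recovery_per_temperature(self, noiseless_truth):
        temps = [288.0, 298.0, 308.0, 318.0]
        df = gen_activity_series(noiseless_truth, np.linspace(0, 1.5, 8), temps)
        params = noiseless_truth.cosolute_params()
        for t in temps:
            sub = df[df.T_K == t].sort_values("molality")
            from crowdtherm.binary import ActivitySeries
            s = ActivitySeries(noiseless_truth.cosolute, t,
                               sub.molality.to_numpy(), sub.water_activity.to_numpy())
            fit = fit_chi(s, params.nu, params.vbar_c)
            assert fit.chi_ == pytest.approx(params.chi(t), abs=1e-10)

    def test_temperature_split_recovery_with_noise(self):
        """(a, b) recovered within its reported uncertainty in most replicates."""
        hits = 0
        reps = 100
        for k in range(reps):
            truth = GroundTruth(sigma_activity=1e-4, seed=k)
            temps = [278.0, 288.0, 298.0, 308.0]
            df = gen_activity_series(truth, np.linspace(0, 1.5, 8), temps)
            params = truth.cosolute_params()
            chis, sigs = [], []
            from crowdtherm.binary import ActivitySeries
            for t in temps:
                sub = df[df.T_K == t].sort_values("molality")
                s = ActivitySeries(truth.cosolute, t, sub.molality.to_numpy(),
                                   sub.water_activity.to_numpy())
                f = fit_chi(s, params.nu, params.vbar_c)
                chis.append(f.chi_)
                sigs.append(f.chi_se_)
            tf = fit_chi_temperature(temps, chis, sigs)
            hits += abs(tf.a_ - truth.chi_a) < 2 * tf.a_se_
        assert hits / reps >= 0.80

    def test_needs_three_temperatures(self, noiseless_truth):
        with pytest.raises(ValueError):
            gen_activity_series(noiseless_truth, [0.0, 0.5], [298.0, 308.0])


class TestFoldingGenerator:
    def test_buffer_column_is_vant_hoff_baseline(self, noiseless_truth):
        temps = np.linspace(278, 318, 9)
        df = gen_folding_dataset(noiseless_truth, [0.0, 1.0], temps)
        sub = df[df.molality == 0.0].sort_values("T_K")
        t = sub.T_K.to_numpy()
        expect = (noiseless_truth.dh0_buffer * 1000 - t * noiseless_truth.ds0_buffer
                  + noiseless_truth.dcp_buffer * ((t - 298.0) - t * np.log(t / 298.0))
                  ) / 1000.0
        np.testing.assert_allclose(sub.dG0_kJ_mol.to_numpy(), expect, atol=1e-12)

    def test_isodichroic_construction(self, noiseless_truth):
        _, spectra = gen_folding_dataset(noiseless_truth, [0.0, 0.75, 1.5],
                                         [288.0, 298.0, 308.0], with_spectra=True)
        iso = spectra[spectra.wavelength_nm == noiseless_truth.isodichroic_nm]
        assert iso.mre.std() == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_epsilon_closure(self, noiseless_truth, noiseless_bundle):
        fold = noiseless_bundle.folding
        sub = fold[fold.T_K == 298.0].sort_values("molality")
        ddg = sub.dG0_kJ_mol - sub.dG0_kJ_mol.iloc[0]
        from crowdtherm import fit_epsilon
        res = fit_epsilon(sub.molality.to_numpy()[1:], ddg.to_numpy()[1:],
                          noiseless_truth.cosolute_params(), noiseless_truth.dsasa)
        assert res.estimate == pytest.approx(noiseless_truth.epsilon, abs=1e-6)

    def test_gibbs_helmholtz_surface_route(self, noiseless_bundle, noiseless_truth):
        d = gibbs_helmholtz_deltas(noiseless_bundle.folding)
        assert d[d.molality == 0.0][["ddg0_kj", "ddh0_kj"]].abs().max().max() == 0.0
        np.testing.assert_allclose(d.t_dds0_kj, d.ddh0_kj - d.ddg0_kj, atol=1e-12)


class TestHbondGenerator:
    def test_null_perturbation_zero_downstream(self):
        truth = default_hbond_truth("stabilized")
        null = truth.copy()
        # make the sugar condition identical to water for shared pairs and
        # drop sugar-only pairs
        null = null[~null.pair_id.str.contains("sugar")]
        w = null[null.condition == "water"]
        null.loc[null.condition == "sugar", ["n_mean", "gbar_kJ_mol"]] = \
            w[["n_mean", "gbar_kJ_mol"]].to_numpy()
        rec = gen_hbond_tables(null, seed=0)
        d = network_delta(rec)
        assert d.ddg_native == d.ddg_denatured == d.ddg_fold == 0.0

    def test_configured_perturbation_sign(self):
        stab = network_delta(gen_hbond_tables(default_hbond_truth("stabilized")))
        destab = network_delta(gen_hbond_tables(default_hbond_truth("destabilized")))
        assert stab.ddg_fold < 0 < destab.ddg_fold
        # both states destabilized in both scenarios
        assert stab.ddg_native > 0 and stab.ddg_denatured > 0

    def test_seed_determinism(self):
        t = default_hbond_truth()
        a = gen_hbond_tables(t, sigma_n=0.1, sigma_g=0.05, seed=3)
        b = gen_hbond_tables(t, sigma_n=0.1, sigma_g=0.05, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_mismatched_pairs_need_zero_fill(self):
        t = default_hbond_truth()
        with pytest.raises(ValueError, match="zero_fill"):
            gen_hbond_tables(t, zero_fill=False)


class TestBundle:
    def test_round_trip_through_readers(self, noiseless_bundle, tmp_path):
        noiseless_bundle.to_dir(tmp_path / "b")
        dens = ctio.read_density(tmp_path / "b" / "density.csv",
                                 m_c=noiseless_bundle.truth.m_c)
        acts = ctio.read_activity(tmp_path / "b" / "activity.csv")
        fold = ctio.read_folding(tmp_path / "b" / "folding.csv")
        spec = ctio.read_spectra(tmp_path / "b" / "spectra.csv")
        hb = ctio.read_hbonds(tmp_path / "b" / "hbonds.csv")
        assert len(dens) == 1 and len(acts) == 9
        assert {"dG0_kJ_mol"} <= set(fold.columns)
        assert spec.mre.shape[1] == fold.shape[0]
        assert len(hb) > 0

    def test_provenance_round_trip(self, noiseless_bundle, tmp_path):
        noiseless_bundle.to_dir(tmp_path / "b")
        back = SyntheticBundle.from_dir(tmp_path / "b")
        assert back.truth == noiseless_bundle.truth
        pd.testing.assert_frame_equal(back.folding, noiseless_bundle.folding,
                                      check_exact=False)

    def test_same_seed_identical_bundles(self):
        t = GroundTruth(seed=5)
        a = make_bundle(t, with_spectra=False)
        b = make_bundle(t, with_spectra=False)
        pd.testing.assert_frame_equal(a.density, b.density)
        pd.testing.assert_frame_equal(a.folding, b.folding)
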