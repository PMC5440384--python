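"""Two-level estimation: curve decomposition round trips, shared-shape
profiling, and the potency regression against the packaged design table."""

import numpy as np
import pytest

import hilltau as ht

SYNERGY_PAIR = ("Orox PK", "Anox 20")


def make_curve(tau=8.0, theta=3.45, noise_frac=0.0, seed=0, t_max=None, **kw):
    spec = ht.CurveGenSpec(
        tau=tau, theta=theta, noise_frac=noise_frac, seed=seed,
        t_max=t_max if t_max is not None else 2.5 * tau, **kw,
    )
    return spec, ht.generate_curve(spec)


class TestFitCurve:
    @pytest.mark.parametrize("theta", [1.5, 3.45, 8.0])
    @pytest.mark.parametrize("tau_frac", [0.2, 0.45, 0.7])
    def test_noise_free_round_trip(self, theta, tau_frac):
        t_max = 20.0
        spec, curve = make_curve(
            tau=tau_frac * t_max, theta=theta, t_max=t_max, noise_frac=0.0
        )
        fit = ht.fit_curve(curve, theta="free")
        assert fit.sigma_min == pytest.approx(spec.sigma_min, rel=1e-6)
        assert fit.m == pytest.approx(spec.m, rel=1e-6)
        assert fit.P == pytest.approx(spec.P, rel=1e-6)
        assert fit.tau == pytest.approx(spec.tau, rel=1e-6)
        assert fit.theta == pytest.approx(spec.theta, rel=1e-6)

    def test_fixed_theta_round_trip(self):
        spec, curve = make_curve(noise_frac=0.0)
        fit = ht.fit_curve(curve, theta=3.45)
        assert fit.tau == pytest.approx(spec.tau, rel=1e-8)
        assert fit.theta == 3.45

    def test_noisy_recovery_monte_carlo(self):
        """1% multiplicative noise, 200 points over [0, 3 tau]: the median
        relative error of the recovered tau stays under 1%."""
        errs = []
        for seed in range(100):
            spec, curve = make_curve(
                tau=8.0, t_max=24.0, noise_frac=0.01, seed=seed
            )
            fit = ht.fit_curve(curve, theta="free", seed=seed)
            errs.append(abs(fit.tau - spec.tau) / spec.tau)
        assert np.median(errs) < 0.01

    def test_reported_rss_matches_reconstruction(self):
        _, curve = make_curve(noise_frac=0.02, seed=7)
        fit = ht.fit_curve(curve, theta="free")
        recomputed = float(np.sum((curve.signal - fit.predict(curve.times)) ** 2))
        assert fit.rss == pytest.approx(recomputed, rel=1e-10)
        assert np.isfinite(fit.se_tau) and fit.se_tau > 0

    def test_pure_drift_rejected_as_non_sigmoidal(self):
        t = np.linspace(0.0, 20.0, 100)
        curve = ht.ConductivityCurve(times=t, signal=5.0 + 0.1 * t, label="drift")
        with pytest.raises(ht.FitError, match="sigmoidal"):
            ht.fit_curve(curve)

    def test_too_few_points_rejected(self):
        t = np.linspace(0, 10, 5)
        with pytest.raises(ValueError):
            ht.ConductivityCurve(times=t, signal=np.ones(5))

    def test_non_monotone_times_rejected(self):
        t = np.array([0.0, 1.0, 0.5, 2.0, 3.0, 4.0, 5.0, 6.0])
        with pytest.raises(ValueError):
            ht.ConductivityCurve(times=t, signal=np.zeros(8))


class TestFitSharedTheta:
    def test_noise_free_recovers_shared_shape(self):
        curves = [
            ht.generate_curve(
                ht.CurveGenSpec(tau=tau, t_max=2.5 * tau, noise_frac=0.0,
                                seed=i, label=f"c{i}")
            )
            for i, tau in enumerate(np.linspace(5.0, 14.0, 6))
        ]
        res = ht.fit_shared_theta(curves)
        assert res.theta == pytest.approx(3.45, abs=1e-4)
        for f, tau in zip(res.fits, np.linspace(5.0, 14.0, 6)):
            assert f.tau == pytest.approx(tau, rel=1e-5)

    def test_noisy_estimate_carries_plausible_uncertainty(self):
        curves = [
            ht.generate_curve(
                ht.CurveGenSpec(tau=tau, t_max=2.5 * tau, noise_frac=0.01,
                                seed=40 + i, label=f"c{i}")
            )
            for i, tau in enumerate(np.linspace(5.0, 14.0, 6))
        ]
        res = ht.fit_shared_theta(curves)
        assert abs(res.theta - 3.45) < 3 * res.se_theta + 1e-9
        assert 0 < res.se_theta < 0.2

    def test_single_curve_rejected(self):
        _, curve = make_curve()
        with pytest.raises(ValueError):
            ht.fit_shared_theta([curve])

    def test_failing_curve_is_named(self):
        _, good = make_curve()
        t = np.linspace(0, 20, 50)
        drift = ht.ConductivityCurve(times=t, signal=1.0 + 0.2 * t, label="flatliner")
        with pytest.raises(ht.FitError, match="flatliner"):
            ht.fit_shared_theta([good, drift])


class TestPredictTau:
    def test_empty_composition_is_baseline(self, table1_fit):
        assert ht.predict_tau({}, table1_fit.model) == pytest.approx(
            table1_fit.model.tau_o
        )

    def test_additive_prediction_is_linear_in_dose(self, table1_fit):
        m = table1_fit.model
        base = ht.predict_tau({"Naugard P": 0.1}, m)
        up = ht.predict_tau({"Naugard P": 0.1 + 1e-6}, m)
        slope = (up - base) / 1e-6
        assert slope == pytest.approx(m.potencies["Naugard P"], rel=1e-4)

    def test_unknown_agent_rejected(self, table1_fit):
        with pytest.raises(ValueError):
            ht.predict_tau({"BHT": 0.1}, table1_fit.model)

    def test_synergy_pair_uses_square_root_rule(self, table1_fit):
        m = table1_fit.model
        tA = m.potencies["Orox PK"] * 0.1
        tB = m.potencies["Anox 20"] * 0.1
        expected = m.tau_o + (np.sqrt(tA) + np.sqrt(tB)) ** 2
        got = ht.predict_tau({"Orox PK": 0.1, "Anox 20": 0.1}, m)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got > m.tau_o + tA + tB  # strictly synergistic


class TestPercentDifference:
    @pytest.mark.parametrize(
        "obs, pred, expected, tol",
        [
            (12.42, 12.74, 2.6, 0.05),
            (5.0, 5.0, 0.0, 1e-12),
            (5.82, 6.78, 16.5, 0.05),  # printed 16.4 reflects rounding
        ],
    )
    def test_examples(self, obs, pred, expected, tol):
        assert ht.percent_difference(obs, pred) == pytest.approx(expected, abs=tol)

    def test_requires_positive_observation(self):
        with pytest.raises(ValueError):
            ht.percent_difference(0.0, 1.0)


class TestFitPotency:
    def test_zero_noise_design_recovers_truth_exactly(self):
        truth = ht.study_like_potency_model()
        design = ht.generate_design(
            ht.DesignGenSpec(potency=truth, grid=ht.table1_layout_grid(),
                             noise_sd=0.0, n_rep=1, seed=0)
        )
        for scheme in ("single", "all"):
            fit = ht.fit_potency(design, synergy_pairs=[SYNERGY_PAIR], lam=2.0,
                                 records_used=scheme)
            assert fit.model.tau_o == pytest.approx(truth.tau_o)
            for agent, kappa in truth.potencies.items():
                assert fit.model.potencies[agent] == pytest.approx(kappa, rel=1e-6)
            assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_table1_reproduces_published_fitted_column(self, table1_fit):
        ref = ht.table1_fitted_reference()
        for rec, pred in zip(table1_fit.records, table1_fit.predictions):
            assert abs(pred - ref[rec.label]) / ref[rec.label] < 0.05

    def test_table1_headline_predictions(self, table1_fit):
        by_label = {
            r.label: p for r, p in zip(table1_fit.records, table1_fit.predictions)
        }
        assert by_label["anox20-0.250"] == pytest.approx(12.74, rel=0.05)
        assert by_label["oroxpk0.167-anox0.083"] == pytest.approx(11.41, rel=0.05)
        assert by_label["naugardp0.125-anox0.125"] == pytest.approx(9.31, rel=0.05)

    def test_additive_residuals_orthogonal_to_design(self):
        """Normal-equation check for the simultaneous additive fit: the
        residual vector is orthogonal to every dose column."""
        truth = ht.PotencyModel(tau_o=5.0, potencies={"A": 10.0, "B": 2.0})
        grid = [{"A": 0.0, "B": 0.0}] + [
            {"A": a, "B": b} for a in (0.0, 0.1, 0.2) for b in (0.0, 0.1, 0.2)
        ]
        design = ht.generate_design(
            ht.DesignGenSpec(potency=truth, grid=tuple(grid), noise_sd=0.4,
                             n_rep=3, seed=3)
        )
        fit = ht.fit_potency(design, records_used="all")
        rows = [r for r in fit.records if not r.is_neat]
        preds = {id(r): p for r, p in zip(fit.records, fit.predictions)}
        resid = np.array([preds[id(r)] - r.tau_obs for r in rows])
        for agent in ("A", "B"):
            col = np.array([r.composition[agent] for r in rows])
            assert abs(col @ resid) < 1e-6 * max(1.0, np.abs(resid).sum())

    def test_synergy_model_beats_additive_on_table1(self, table1_records):
        """Replacing the square-root synergy rule by plain additivity must
        worsen the residual sum of squares on the synergistic pair's rows."""
        syn = ht.fit_potency(table1_records, synergy_pairs=[SYNERGY_PAIR], lam=2.0)
        add = ht.fit_potency(table1_records, synergy_pairs=[], lam=2.0)

        def pair_rss(fit):
            out = 0.0
            for r, p in zip(fit.records, fit.predictions):
                if r.composition["Orox PK"] > 0 and r.composition["Anox 20"] > 0:
                    out += (p - r.tau_obs) ** 2
            return out

        assert pair_rss(syn) < pair_rss(add)
        assert syn.rss < add.rss

    def test_missing_neat_record_rejected(self, table1_records):
        with pytest.raises(ValueError, match="neat"):
            ht.fit_potency([r for r in table1_records if not r.is_neat])

    def test_agent_without_single_record_unidentifiable(self):
        recs = [
            ht.CompositionRecord({"A": 0.0, "B": 0.0}, tau_obs=5.0),
            ht.CompositionRecord({"A": 0.1, "B": 0.1}, tau_obs=8.0),
            ht.CompositionRecord({"A": 0.2, "B": 0.0}, tau_obs=7.0),
        ]
        with pytest.raises(ValueError, match="unidentifiable"):
            ht.fit_potency(recs)

    def test_negative_slope_flagged_as_destabilizer(self):
        recs = [
            ht.CompositionRecord({"A": 0.0}, tau_obs=5.0),
            ht.CompositionRecord({"A": 0.1}, tau_obs=4.0),
            ht.CompositionRecord({"A": 0.2}, tau_obs=3.1),
        ]
        with pytest.warns(UserWarning, match="destabilizer"):
            fit = ht.fit_potency(recs)
        assert fit.negative_potency_agents == ("A",)

    def test_unknown_synergy_agent_rejected(self, table1_records):
        with pytest.raises(ValueError):
            ht.fit_potency(table1_records, synergy_pairs=[("Orox PK", "BHT")])
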