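"""Generator tests: log-normal populations, entry traces, rendered frames."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cytovisc as cv
from cytovisc.synthetic import Z_UPPER_QUARTILE, body_radius


class TestLognormalFromQuartiles:
    @pytest.mark.parametrize(
        "q1,med,q3,exp_lm,exp_ls",
        [
            # frozen from direct arithmetic: ln(med), ln(q3/q1)/(2*0.6744897502)
            (16.7, 42.1, 110.3, 3.7400, 1.3995),
            (144.8, 489.8, 1390.7, 6.1944, 1.6770),
        ],
    )
    def test_reported_quartile_fits(self, q1, med, q3, exp_lm, exp_ls):
        spec = cv.fit_lognormal_from_quartiles(q1, med, q3)
        assert spec.log_median == pytest.approx(exp_lm, abs=5e-4)
        assert spec.log_sigma == pytest.approx(exp_ls, abs=5e-4)
        # symmetric-in-log fit: quartile ratio preserved exactly, q1'*q3' = med^2
        q1p, medp, q3p = spec.quartiles()
        assert q3p / q1p == pytest.approx(q3 / q1, rel=1e-12)
        assert q1p * q3p == pytest.approx(med**2, rel=1e-12)

    def test_implied_quartiles_match_numeric_quantile_oracle(self):
        # independent oracle: quantiles of the implied log-normal via scipy
        from scipy.stats import lognorm

        spec = cv.fit_lognormal_from_quartiles(16.7, 42.1, 110.3)
        dist = lognorm(s=spec.log_sigma, scale=np.exp(spec.log_median))
        q1p, medp, q3p = spec.quartiles()
        assert q1p == pytest.approx(dist.ppf(0.25), rel=1e-9)
        assert medp == pytest.approx(dist.ppf(0.5), rel=1e-9)
        assert q3p == pytest.approx(dist.ppf(0.75), rel=1e-9)

    def test_degenerate_point_mass(self):
        spec = cv.fit_lognormal_from_quartiles(42.0, 42.0, 42.0)
        assert spec.log_sigma == 0.0

    @pytest.mark.parametrize(
        "bad", [(-1.0, 2.0, 3.0), (3.0, 2.0, 4.0), (1.0, 2.0, 1.5), (0.0, 1.0, 2.0)]
    )
    def test_invalid_quartiles_rejected_with_message(self, bad):
        with pytest.raises(ValueError):
            cv.fit_lognormal_from_quartiles(*bad)


class TestSamplePopulation:
    def test_zero_spread_gives_constant_viscosity(self):
        spec = cv.PopulationSpec("pt", 5, np.log(42.0), 0.0)
        table = cv.sample_population(spec, seed=0)
        assert np.allclose(table["true_viscosity"], 42.0)

    def test_sample_quartiles_match_cohort_at_reported_n(self):
        # at n = 652 the quartile sampling error is ~7-8% (sd) on Q1/Q3, so
        # the 15% band holds for the typical seed, not every seed: check the
        # seed fraction and the seed-averaged quartiles
        spec = cv.cohort_spec("H1299_10kPa")  # n = 652
        target = np.array([16.7, 42.1, 110.3])
        within = 0
        qs = []
        n_seeds = 20
        for seed in range(n_seeds):
            v = cv.sample_population(spec, seed)["true_viscosity"]
            q = np.quantile(v, [0.25, 0.5, 0.75])
            qs.append(q)
            within += np.all(np.abs(q / target - 1) < 0.15)
        assert within / n_seeds >= 0.8
        assert np.all(np.abs(np.mean(qs, axis=0) / target - 1) < 0.08)

    def test_quartile_round_trip_large_n(self):
        # fit -> sample at n=10^4 reproduces the inputs within 5%
        spec = cv.fit_lognormal_from_quartiles(16.7, 42.1, 110.3, n_cells=10_000)
        v = cv.sample_population(spec, seed=3)["true_viscosity"]
        q = np.quantile(v, [0.25, 0.5, 0.75])
        assert np.all(np.abs(q / np.array([16.7, 42.1, 110.3]) - 1) < 0.05)

    def test_seed_contract(self):
        spec = cv.cohort_spec("H1299_10kPa", 50)
        a = cv.sample_population(spec, 5)
        b = cv.sample_population(spec, 5)
        c = cv.sample_population(spec, 6)
        assert a.equals(b)
        assert not a["true_viscosity"].equals(c["true_viscosity"])

    def test_radii_within_range(self):
        spec = cv.cohort_spec("A549_10kPa", 200)
        r = cv.sample_population(spec, 0)["cell_radius"]
        assert r.min() >= 6.0 and r.max() <= 12.5


class TestSimulateTrace:
    def test_noiseless_pure_viscous_has_constant_increments(self, acq_10kpa):
        # choose mu so that v = 0.4 mm/s exactly: mu = Rp*dP/(6*(1-Rp/Rc)*v)
        v_target = 400.0  # µm/s
        mu = (5e-6 * 1e4) / (6 * 0.5 * v_target * 1e-6)
        spec = cv.TraceSpec(
            true_viscosity=mu, cell_radius=10.0, elastic_jump=0.0,
            elastic_duration=1e-4, noise_sd=0.0,
        )
        tr = cv.simulate_trace(spec, acq_10kpa, T0=0.0)
        dl = np.diff(tr.lengths)
        assert np.allclose(dl, v_target / 800.0, rtol=1e-9)

    def test_rate_matches_arithmetic_oracle(self, acq_10kpa):
        # Rp=5, Rc=10, dP=10 kPa, mu=41.67 -> v = 4.0e-4 m/s
        v = cv.entry_rate(41.67, 10.0, acq_10kpa, T0=0.0)
        assert v == pytest.approx(4.0e-4 * 1e6, rel=1e-3)

    def test_round_trip_recovers_viscosity_noiseless(self, noiseless_trace, acq_10kpa):
        kin = cv.fit_trace_kinetics(noiseless_trace, acq_10kpa)
        mu, _, _ = cv.estimate_viscosity(5.0, 10.0, 1e4, kin.rate)
        assert mu == pytest.approx(41.67, rel=0.02)

    def test_trace_ends_at_full_entry(self, noiseless_trace):
        l_full = cv.full_entry_length(10.0, 5.0)
        assert noiseless_trace.lengths[-1] >= l_full
        assert noiseless_trace.lengths[-2] < l_full

    def test_geometry_precondition(self, acq_10kpa):
        with pytest.raises(ValueError, match="exceed"):
            cv.simulate_trace(
                cv.TraceSpec(true_viscosity=10, cell_radius=4.0), acq_10kpa
            )

    def test_truncation_flagged(self, acq_10kpa):
        spec = cv.TraceSpec(true_viscosity=5000.0, cell_radius=12.0, noise_sd=0.0)
        tr = cv.simulate_trace(spec, acq_10kpa, max_duration=0.5)
        from cytovisc.traces import FLAG_TRUNCATED

        assert tr.meta["truncated"]
        assert tr.flags[-1] & FLAG_TRUNCATED
        assert tr.times[-1] <= 0.5 + 1 / 800

    def test_unsupported_frame_rate_rejected(self):
        with pytest.raises(ValueError, match="frame_rate"):
            cv.TraceSpec(true_viscosity=10, cell_radius=8, frame_rate=10.0)

    def test_section2_slope_equals_model_rate(self, acq_10kpa):
        # least-squares slope of the noiseless viscous section == model rate
        spec = cv.TraceSpec(
            true_viscosity=100.0, cell_radius=9.0, elastic_jump=1.0,
            elastic_duration=0.0025, noise_sd=0.0,
        )
        tr = cv.simulate_trace(spec, acq_10kpa)
        v = tr.meta["true_rate_um_s"]
        sec2 = tr.times >= 0.0025
        slope = np.polyfit(tr.times[sec2], tr.lengths[sec2], 1)[0]
        assert slope == pytest.approx(v, rel=1e-9)


class TestRenderer:
    def test_static_stack_has_empty_difference_mask(self, acq_10kpa, render_spec_noiseless):
        tr = cv.AspirationTrace("s", 8.0, np.arange(3) / 800, np.full(3, 10.0))
        acq = cv.plan_geometry(8.0, acq_10kpa, render_spec_noiseless)
        stack = cv.render_sequence(tr, acq, render_spec_noiseless)
        assert np.array_equal(stack[0], stack[1])
        masks = cv.difference_frames(stack, threshold=0.01)
        assert not masks.any()

    def test_known_circle_radius_recovered(self, acq_10kpa, render_spec_noiseless):
        acq = cv.plan_geometry(8.0, acq_10kpa, render_spec_noiseless)
        frame = cv.synthetic.render_frame(0.0, 8.0, acq, render_spec_noiseless)
        fit = cv.measure_cell_radius(frame, acq)
        assert fit.radius_um == pytest.approx(8.0, rel=0.02)

    def test_seed_determinism(self, acq_10kpa, render_spec, noiseless_trace):
        acq = cv.plan_geometry(10.0, acq_10kpa, render_spec)
        a = cv.render_sequence(noiseless_trace, acq, render_spec, seed=11)
        b = cv.render_sequence(noiseless_trace, acq, render_spec, seed=11)
        assert np.array_equal(a, b)

    def test_geometry_overflow_reports_required_size(self, acq_10kpa):
        small = cv.RenderSpec(image_size=(32, 64))
        with pytest.raises(ValueError, match="need at least"):
            cv.plan_geometry(12.0, acq_10kpa, small)

    def test_volume_conservation_body_shrinks_monotonically(self):
        # volume outside + volume inside is conserved until full entry
        rc, rp = 10.0, 5.0
        l_full = cv.full_entry_length(rc, rp)
        lps = np.linspace(0, l_full, 50)
        radii = np.array([body_radius(rc, rp, lp) for lp in lps])
        assert np.all(np.diff(radii) < 0)
        total = (4 / 3) * np.pi * radii**3 + np.pi * rp**2 * lps
        assert np.allclose(total, (4 / 3) * np.pi * rc**3, rtol=1e-12)
        # cube root amplifies the float residual of Rc^3 - (3/4) Rp^2 L_full
        assert body_radius(rc, rp, l_full) == pytest.approx(0.0, abs=1e-4)

    def test_render_level_invariants_enforced(self):
        with pytest.raises(ValueError, match="photon_noise_sd"):
            cv.RenderSpec(background_level=0.4, cell_level=0.5, photon_noise_sd=0.05)


@settings(max_examples=25, deadline=None)
@given(
    med=st.floats(1.0, 1000.0),
    ratio=st.floats(1.0, 50.0),
)
def test_quartile_fit_ratio_and_product_properties(med, ratio):
    q1 = med / np.sqrt(ratio)
    q3 = med * np.sqrt(ratio)
    spec = cv.fit_lognormal_from_quartiles(q1, med, q3)
    q1p, medp, q3p = spec.quartiles()
    assert medp == pytest.approx(med, rel=1e-9)
    assert q3p / q1p == pytest.approx(ratio, rel=1e-9)
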