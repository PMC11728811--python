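"""Monte Carlo engine: factor sampling, EC/HQ/HI arithmetic, summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

import solventrisk as sr
from solventrisk.distfit import moments_to_spec
from solventrisk.errors import ConfigurationError
from solventrisk.simulation import FactorDraws, scenario_hash

AT = 69_408.0


def point_model(conc=30.0, et=8.0, ed=10.0, ef=250.0, chem="x"):
    pm = lambda v: moments_to_spec("normal", v, 0.0)
    return sr.ExposureFactorModel(
        concentration_specs={chem: pm(conc)}, et_spec=pm(et), ed_spec=pm(ed), ef_spec=pm(ef),
        at_days=AT,
    )


class TestComputeEc:
    def test_hand_arithmetic(self):
        assert sr.compute_ec(30.6, 8, 7.62, 267.2, AT) == pytest.approx(
            0.2992141078838174, rel=1e-12
        )

    def test_zero_exposure_years(self):
        assert sr.compute_ec(30.6, 8, 0.0, 267.2, AT) == 0.0

    def test_continuous_exposure_recovers_concentration(self):
        # 24 h/day, 365 d/yr for the whole averaging time -> EC equals C
        assert sr.compute_ec(5.0, 24.0, AT / 365.0, 365.0, AT) == pytest.approx(5.0, rel=1e-12)

    def test_nonpositive_averaging_time_rejected(self):
        with pytest.raises(ConfigurationError):
            sr.compute_ec(1.0, 8.0, 10.0, 250.0, 0.0)


class TestComputeHqHi:
    def test_threshold_case(self):
        assert sr.compute_hq(0.35, 0.35) == 1.0

    def test_xylene_continuation(self):
        assert sr.compute_hq(0.2992, 0.1) == pytest.approx(2.992, rel=1e-12)

    def test_zero_exposure(self):
        assert sr.compute_hq(0.0, 0.1) == 0.0

    def test_nonpositive_rfc_rejected(self):
        with pytest.raises(ConfigurationError):
            sr.compute_hq(1.0, 0.0)

    def test_hi_direct_sum(self):
        g = sr.ToxicityGrouping("g", ("a", "b"))
        assert sr.compute_hi({"a": 0.5, "b": 0.3}, g) == pytest.approx(0.8)

    def test_hi_singleton_identity(self):
        g = sr.ToxicityGrouping("g", ("a",))
        assert sr.compute_hi({"a": 0.7, "b": 9.0}, g) == 0.7

    def test_hi_nervous_membership(self):
        g = sr.ToxicityGrouping("nervous", ("xylene", "n-butanol", "isobutyl alcohol", "toluene"))
        hq = {"xylene": 2.0, "n-butanol": 1.0, "isobutyl alcohol": 0.5, "toluene": 0.1}
        assert sr.compute_hi(hq, g) == pytest.approx(3.6)

    def test_missing_member_named(self):
        g = sr.ToxicityGrouping("g", ("a", "b"))
        with pytest.raises(ConfigurationError, match="'b'"):
            sr.compute_hi({"a": 0.5}, g)


class TestExceedancePercentile:
    def test_all_above(self):
        assert sr.exceedance_percentile([2.0, 3.0], 1.0) == 0.0

    def test_constructed_ranks(self):
        assert sr.exceedance_percentile(np.arange(1, 101), 50.5) == 50.0

    def test_ties_count_as_non_exceeding(self):
        assert sr.exceedance_percentile(np.ones(10), 1.0) == 100.0

    def test_complement_identity(self):
        x = np.random.default_rng(0).lognormal(0, 1, 999)
        ep = sr.exceedance_percentile(x, 1.0)
        assert ep + 100.0 * np.mean(x > 1.0) == pytest.approx(100.0, abs=1e-9)


class TestSummarizePercentiles:
    def test_constant_vector(self):
        assert set(sr.summarize_percentiles(np.full(7, 3.3)).values()) == {3.3}

    def test_linear_interpolation_hand_example(self):
        got = sr.summarize_percentiles(np.arange(1.0, 100.0), (25, 50, 75))
        assert got[25.0] == pytest.approx(25.5)
        assert got[50.0] == pytest.approx(50.0)
        assert got[75.0] == pytest.approx(74.5)

    def test_monotone_in_grid(self, default_result):
        for chem in default_result.hq.columns:
            s = sr.summarize_percentiles(default_result.hq[chem].to_numpy())
            vals = [s[q] for q in sorted(s)]
            assert vals == sorted(vals)


class TestSampleFactors:
    def test_point_mass_model_constant_columns(self):
        d = sr.sample_factors(point_model(), n=50, seed=1)
        assert np.ptp(d.et) == 0 and np.ptp(d.ed) == 0 and np.ptp(d.ef) == 0
        assert np.ptp(d.concentrations["x"]) == 0

    def test_same_seed_bit_identical(self, scenario):
        a = sr.sample_factors(scenario.model, n=500, seed=9)
        b = sr.sample_factors(scenario.model, n=500, seed=9)
        assert np.array_equal(a.et, b.et) and np.array_equal(a.ed, b.ed)
        for name in a.concentrations:
            assert np.array_equal(a.concentrations[name], b.concentrations[name])

    def test_exposure_duration_mean(self, scenario):
        d = sr.sample_factors(scenario.model, n=100_000, seed=2)
        assert d.ed.mean() == pytest.approx(11.0, abs=0.15)  # 3·SE band, SD 11

    def test_all_draws_positive(self, scenario):
        d = sr.sample_factors(scenario.model, n=20_000, seed=3)
        assert (d.et > 0).all() and (d.ed > 0).all() and (d.ef > 0).all()
        assert all((c > 0).all() for c in d.concentrations.values())

    def test_absurd_truncation_rejected(self):
        model = point_model()
        bad = sr.ExposureFactorModel(
            concentration_specs=model.concentration_specs,
            et_spec=moments_to_spec("normal", -5.0, 1.0),  # essentially always negative
            ed_spec=model.ed_spec,
            ef_spec=model.ef_spec,
            at_days=AT,
        )
        with pytest.raises(ConfigurationError, match="50%"):
            sr.sample_factors(bad, n=1000, seed=0)


def nervous_members(scenario):
    return next(g for g in scenario.groupings if g.group_name == "nervous").members


class TestRunSimulation:
    def test_point_mass_scenario_all_iterations_identical(self):
        chem = sr.ChemicalSpec("x", 106.17, rfc_by_toxicity={"nervous": 0.1})
        grouping = sr.ToxicityGrouping("nervous", ("x",))
        res = sr.run_simulation([chem], point_model(chem="x"), [grouping], n=100, seed=0)
        hq = res.hq["x"].to_numpy()
        assert np.ptp(hq) == 0
        expected = (30.0 * 106.17 / 24.45) * 8 * 10 * 250 / (AT * 24) / 0.1
        assert hq[0] == pytest.approx(expected, rel=1e-12)
        summ = res.hq_summary().loc["x"]
        assert summ["p25"] == summ["p95"] == pytest.approx(expected, rel=1e-12)

    def test_determinism(self, scenario):
        kw = dict(n=800, seed=123)
        a = sr.run_simulation(scenario.chemicals, scenario.model, scenario.groupings, **kw)
        b = sr.run_simulation(scenario.chemicals, scenario.model, scenario.groupings, **kw)
        pd.testing.assert_frame_equal(a.hq, b.hq)
        pd.testing.assert_frame_equal(a.hi, b.hi)

    def test_halving_rfc_doubles_hq_bitwise(self, scenario):
        halved = []
        for c in scenario.chemicals:
            halved.append(
                sr.ChemicalSpec(
                    c.name,
                    c.molecular_weight,
                    {k: v / 2 for k, v in c.rfc_by_toxicity.items()},
                    {k: v / 2 for k, v in c.rfd_by_toxicity.items()},
                    c.record_count_default,
                )
            )
        kw = dict(n=1000, seed=77)
        a = sr.run_simulation(scenario.chemicals, scenario.model, scenario.groupings, **kw)
        b = sr.run_simulation(halved, scenario.model, scenario.groupings, **kw)
        for chem in a.hq.columns:
            assert np.array_equal(2.0 * a.hq[chem].to_numpy(), b.hq[chem].to_numpy())

    def test_concentration_scaling_equivariance(self, scenario):
        k = 3.7
        specs = dict(scenario.model.concentration_specs)
        specs["xylene"] = moments_to_spec("lognormal", k * 19.66, k * 51.24)
        scaled_model = sr.ExposureFactorModel(
            concentration_specs=specs,
            et_spec=scenario.model.et_spec,
            ed_spec=scenario.model.ed_spec,
            ef_spec=scenario.model.ef_spec,
            at_days=scenario.model.at_days,
        )
        kw = dict(n=1000, seed=5)
        a = sr.run_simulation(scenario.chemicals, scenario.model, scenario.groupings, **kw)
        b = sr.run_simulation(scenario.chemicals, scaled_model, scenario.groupings, **kw)
        np.testing.assert_allclose(
            b.hq["xylene"].to_numpy(), k * a.hq["xylene"].to_numpy(), rtol=1e-12
        )

    def test_hi_is_row_sum_of_member_hqs(self, default_result, scenario):
        for g in scenario.groupings:
            members = list(g.members)
            expected = default_result.hq[members].sum(axis=1).to_numpy()
            got = default_result.hi[g.group_name].to_numpy()
            np.testing.assert_allclose(got, expected, rtol=1e-12)
            assert (got >= default_result.hq[members].max(axis=1).to_numpy()).all()

    def test_degenerate_worker_factors_percentile_identity(self, scenario):
        # with ET/ED/EF fixed, HQ percentiles are an exact affine image of
        # concentration percentiles (monotone-transform property)
        pm = lambda v: moments_to_spec("normal", v, 0.0)
        model = sr.ExposureFactorModel(
            concentration_specs=dict(scenario.model.concentration_specs),
            et_spec=pm(8.0), ed_spec=pm(10.0), ef_spec=pm(250.0), at_days=AT,
        )
        res = sr.run_simulation(scenario.chemicals, model, scenario.groupings, n=2000, seed=6)
        c = res.draws.concentrations["xylene"]
        const = (106.17 / 24.45) * 8.0 * 10.0 * 250.0 / (AT * 24.0) / 0.1
        for q in (25, 50, 75, 95):
            assert np.percentile(res.hq["xylene"], q) == pytest.approx(
                const * np.percentile(c, q), rel=1e-12
            )

    def test_missing_concentration_spec_rejected(self, scenario):
        model = sr.ExposureFactorModel(
            concentration_specs={"xylene": scenario.model.concentration_specs["xylene"]},
            et_spec=scenario.model.et_spec,
            ed_spec=scenario.model.ed_spec,
            ef_spec=scenario.model.ef_spec,
        )
        with pytest.raises(ConfigurationError, match="no concentration spec"):
            sr.run_simulation(scenario.chemicals, model, scenario.groupings, n=10, seed=0)

    def test_scenario_hash_stable_and_sensitive(self, scenario):
        h1 = scenario_hash(scenario.chemicals, scenario.model, scenario.groupings)
        h2 = scenario_hash(scenario.chemicals, scenario.model, scenario.groupings)
        assert h1 == h2
        h3 = scenario_hash(scenario.chemicals[:-1], scenario.model, scenario.groupings[:1])
        assert h3 != h1


class TestDiscreteOracle:
    """Exceedance probability vs exhaustive enumeration on discrete factors."""

    C_VALS, C_PROBS = np.array([5.0, 30.0, 120.0]), np.array([0.5, 0.3, 0.2])
    ET_VALS, ET_PROBS = np.array([6.0, 8.0, 10.0]), np.array([0.25, 0.5, 0.25])
    ED_VALS, ED_PROBS = np.array([2.0, 10.0, 30.0]), np.array([0.4, 0.4, 0.2])
    EF_VALS, EF_PROBS = np.array([200.0, 250.0, 300.0]), np.array([0.3, 0.4, 0.3])

    def _hq(self, c, et, ed, ef):
        return (c * 106.17 / 24.45) * et * ed * ef / (AT * 24.0) / 0.1

    def test_monte_carlo_matches_enumeration(self):
        p_true = 0.0
        for (c, pc), (et, pet), (ed, ped), (ef, pef) in itertools.product(
            zip(self.C_VALS, self.C_PROBS),
            zip(self.ET_VALS, self.ET_PROBS),
            zip(self.ED_VALS, self.ED_PROBS),
            zip(self.EF_VALS, self.EF_PROBS),
        ):
            if self._hq(c, et, ed, ef) > 1.0:
                p_true += pc * pet * ped * pef
        assert 0.05 < p_true < 0.95  # the toy grid must actually straddle 1

        n = 40_000
        rng = np.random.default_rng(2024)
        draws = FactorDraws(
            n=n,
            seed=2024,
            et=rng.choice(self.ET_VALS, n, p=self.ET_PROBS),
            ed=rng.choice(self.ED_VALS, n, p=self.ED_PROBS),
            ef=rng.choice(self.EF_VALS, n, p=self.EF_PROBS),
            concentrations={"x": rng.choice(self.C_VALS, n, p=self.C_PROBS)},
        )
        chem = sr.ChemicalSpec("x", 106.17, rfc_by_toxicity={"nervous": 0.1})
        res = sr.evaluate_draws([chem], draws, [sr.ToxicityGrouping("nervous", ("x",))], AT)
        p_mc = np.mean(res.hq["x"].to_numpy() > 1.0)
        tol = 3 * np.sqrt(p_true * (1 - p_true) / n)
        assert p_mc == pytest.approx(p_true, abs=tol)
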