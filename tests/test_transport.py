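import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dmpk.synth import SimConfig, simulate_transport
from dmpk.transport import (
    BBB_PERMEABILITY_THRESHOLD,
    CytotoxicityCurve,
    PappResult,
    TransportExperiment,
    apparent_permeability,
    cumulative_receiver_amount,
    efflux_ratio,
    fit_tc50,
    inhibitor_effect,
)


def make_experiment(concs, times=None, direction="AtoB", c0=1.0,
                    receiver=1200.0, sample=50.0):
    times = times if times is not None else [15.0 * (i + 1) for i in range(len(concs))]
    return TransportExperiment(direction=direction, c0=c0,
                               samples=list(zip(times, concs)),
                               receiver_volume=receiver, sample_volume=sample)


class TestCumulativeAmount:
    def test_no_replacement_limit(self):
        exp = make_experiment([2.0, 2.0, 2.0], sample=0.0)
        q = cumulative_receiver_amount(exp)
        assert [amt for _, amt in q] == pytest.approx([2.4, 2.4, 2.4])

    def test_hand_arithmetic_replacement(self):
        # C = [1, 1] μg/mL, V_r = 1200 μL, V_s = 50 μL
        exp = make_experiment([1.0, 1.0], times=[15.0, 30.0])
        q = cumulative_receiver_amount(exp)
        assert [amt for _, amt in q] == pytest.approx([1.2, 1.25])

    def test_correction_off_matches_naive(self):
        exp = make_experiment([1.0, 2.0, 3.0])
        naive = cumulative_receiver_amount(exp, correct_sampling=False)
        assert [a for _, a in naive] == pytest.approx([1.2, 2.4, 3.6])

    def test_corrected_linear_naive_sublinear(self):
        """Under constant flux the corrected Q is linear in t; the naive
        reconstruction falls short at later times."""
        ab, _ = simulate_transport(SimConfig(seed=3, model="transport",
                                             parameters={"noise_cv": 0.0}))
        t = ab.times
        q_corr = np.array([a for _, a in cumulative_receiver_amount(ab)])
        q_naive = np.array([a for _, a in
                            cumulative_receiver_amount(ab, correct_sampling=False)])
        slope = q_corr / t
        assert np.allclose(slope, slope[0], rtol=1e-9)
        assert q_naive[-1] < q_corr[-1]


class TestApparentPermeability:
    def test_generator_inversion_noise_free(self):
        ab, _ = simulate_transport(SimConfig(
            seed=1, model="transport",
            parameters={"papp": 1e-5, "efflux_factor": 1.0, "noise_cv": 0.0}))
        res = apparent_permeability(ab)
        assert res.papp == pytest.approx(1e-5, rel=1e-9)
        assert res.slope_r2 == pytest.approx(1.0)

    def test_zero_concentrations_flagged(self):
        exp = make_experiment([0.0, 0.0, 0.0])
        res = apparent_permeability(exp)
        assert res.papp == 0.0
        assert res.flags["zero_flux"]

    def test_too_few_points_rejected(self):
        exp = make_experiment([1.0, 2.0])
        with pytest.raises(ValueError, match=">= 3"):
            apparent_permeability(exp)

    def test_bbb_flag_follows_threshold(self):
        fast, _ = simulate_transport(SimConfig(
            seed=2, model="transport",
            parameters={"papp": 6.6e-6, "efflux_factor": 1.0, "noise_cv": 0.0}))
        res = apparent_permeability(fast)
        assert res.papp > BBB_PERMEABILITY_THRESHOLD
        assert res.flags["bbb_permeable"]
        slow, _ = simulate_transport(SimConfig(
            seed=2, model="transport",
            parameters={"papp": 1e-6, "efflux_factor": 1.0, "noise_cv": 0.0,
                        "c0": 5.0}))
        assert not apparent_permeability(slow).flags["bbb_permeable"]


class TestEffluxRatio:
    def test_symmetric_transport_not_substrate(self):
        ab = PappResult(papp=5e-6, slope_r2=1.0, direction="AtoB")
        ba = PappResult(papp=5e-6, slope_r2=1.0, direction="BtoA")
        res = efflux_ratio(ab, ba)
        assert res.er == pytest.approx(1.0)
        assert not res.flags["pgp_substrate"]

    def test_efflux_factor_inverted_and_substrate_called(self):
        ab, ba = simulate_transport(SimConfig(
            seed=5, model="transport",
            parameters={"efflux_factor": 1.9, "noise_cv": 0.0}))
        res = efflux_ratio(apparent_permeability(ab), apparent_permeability(ba))
        assert res.er == pytest.approx(1.9, rel=1e-9)
        assert res.flags["pgp_substrate"]

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale):
        ab = PappResult(papp=4e-6, slope_r2=1.0, direction="AtoB")
        ba = PappResult(papp=7.6e-6, slope_r2=1.0, direction="BtoA")
        base = efflux_ratio(ab, ba).er
        ab2 = PappResult(papp=4e-6 * scale, slope_r2=1.0, direction="AtoB")
        ba2 = PappResult(papp=7.6e-6 * scale, slope_r2=1.0, direction="BtoA")
        assert efflux_ratio(ab2, ba2).er == pytest.approx(base, rel=1e-9)

    def test_zero_ab_papp_censored(self):
        ab = PappResult(papp=0.0, slope_r2=float("nan"), direction="AtoB")
        ba = PappResult(papp=5e-6, slope_r2=1.0, direction="BtoA")
        res = efflux_ratio(ab, ba)
        assert res.er is None
        assert res.flags["er_censored"]


class TestInhibitorEffect:
    def _paired(self, seed, inhibitor=False):
        cfg = SimConfig(seed=seed, model="transport",
                        parameters={"noise_cv": 0.0, "inhibitor": inhibitor})
        return list(simulate_transport(cfg))

    def test_identical_data_fold_change_one(self):
        base = self._paired(1)
        table = inhibitor_effect(base, self._paired(1))
        assert table["fold_change"].tolist() == pytest.approx([1.0, 1.0])

    def test_efflux_removal_raises_atob(self):
        table = inhibitor_effect(self._paired(1), self._paired(1, inhibitor=True))
        ab_row = table[table["direction"] == "AtoB"].iloc[0]
        assert ab_row["fold_change"] > 1.0
        er = table.attrs["er_summary"].iloc[0]
        assert er["er_base"] == pytest.approx(1.9, rel=1e-9)
        assert er["er_inhibited"] == pytest.approx(1.0, rel=1e-9)

    def test_empty_inhibited_rejected(self):
        with pytest.raises(ValueError, match="required"):
            inhibitor_effect(self._paired(1), [])


class TestTC50:
    def _curve(self, tc50=80.0, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        conc = np.array([1.28e-3, 6.4e-3, 0.032, 0.16, 0.8, 4.0, 20.0, 100.0, 500.0])
        rgr = 100.0 / (1.0 + (conc / tc50) ** 1.5)
        rgr = rgr * (1 + noise * rng.standard_normal(len(conc)))
        return CytotoxicityCurve(concentrations=conc, rgr=rgr)

    def test_recovers_synthetic_tc50(self):
        res = fit_tc50(self._curve(tc50=80.0, noise=0.02, seed=4))
        assert not res.censored
        assert res.tc50 == pytest.approx(80.0, rel=0.10)

    def test_flat_high_rgr_censored(self):
        conc = np.array([0.01, 0.1, 1.0, 10.0, 100.0])
        res = fit_tc50(CytotoxicityCurve(concentrations=conc,
                                         rgr=np.full(5, 98.0)))
        assert res.censored
        assert "max tested" in res.flags["note"]

    def test_steep_curve_hits_observed_midpoint(self):
        conc = np.array([1.0, 3.0, 10.0, 30.0, 100.0])
        rgr = np.array([100.0, 99.0, 50.0, 1.0, 0.0])
        res = fit_tc50(CytotoxicityCurve(concentrations=conc, rgr=rgr))
        assert res.tc50 == pytest.approx(10.0, rel=0.15)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            fit_tc50(CytotoxicityCurve(concentrations=np.array([1.0, 2, 4, 8]),
                                       rgr=np.array([90.0, 70, 40, 10])))
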