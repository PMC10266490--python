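"""Closed-form measures, their identities, and the Monte-Carlo oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pericausal as pc
from conftest import rand_stable_model


def random_psd(rng, p):
    A = rng.standard_normal((p, p + 2))
    return A @ A.T / (p + 2)


class TestClosedForms:
    def test_zero_coupling_gives_zero(self):
        S = random_psd(np.random.default_rng(1), 3)
        b = np.zeros(3)
        ref = pc.ReferenceMoments((0, 5), np.ones(3), S)
        assert pc.transfer_entropy_t(b, S, 1.0) == 0.0
        assert pc.dynamic_causal_strength_t(b, S, 1.0) == 0.0
        assert pc.relative_dcs_t(b, np.zeros(3), S, 1.0, ref) == 0.0

    def test_gc_direct_arithmetic(self):
        assert pc.granger_causality_t(1.0, 1.0) == 0.0
        assert pc.granger_causality_t(np.e * 2.0, 2.0) == pytest.approx(0.5)

    def test_deterministic_cause_kills_te(self):
        """X2 = k X1 makes the conditional cause-past covariance a zero
        Schur complement, hence TE = 0 despite nonzero coupling."""
        rng = np.random.default_rng(3)
        S11 = random_psd(rng, 2)
        k = 2.0
        S22, S12 = k * k * S11, k * S11
        cond = pc.schur_complement(S22, S12.T, S11)
        te = pc.transfer_entropy_t(np.array([1.5, 0.3]), cond, 1.0)
        assert te == pytest.approx(0.0, abs=1e-12)

    def test_te_monotone_in_conditional_covariance(self):
        rng = np.random.default_rng(5)
        S = random_psd(rng, 2)
        b = rng.standard_normal(2)
        vals = [pc.transfer_entropy_t(b, c * S, 1.3)
                for c in (1.0, 0.5, 0.1, 0.0)]
        assert all(x > y for x, y in zip(vals, vals[1:]))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_te_le_dcs_and_nonnegative(self, seed):
        """TE <= DCS (conditioning shrinks the covariance seen through b)
        and all analytic measures are nonnegative."""
        rng = np.random.default_rng(seed)
        p = int(rng.integers(1, 4))
        joint = random_psd(rng, 2 * p)
        b = rng.standard_normal(p)
        s = float(rng.uniform(0.1, 2.0))
        S_ee, S_cc = joint[:p, :p], joint[p:, p:]
        S_ce = joint[p:, :p]
        cond = pc.schur_complement(S_cc, S_ce, S_ee)
        te = pc.transfer_entropy_t(b, cond, s)
        dcs = pc.dynamic_causal_strength_t(b, S_cc, s)
        assert 0.0 <= te <= dcs + 1e-12
        ref = pc.ReferenceMoments((0, 1), rng.standard_normal(p),
                                  random_psd(rng, p))
        assert pc.relative_dcs_t(b, rng.standard_normal(p), S_cc, s,
                                 ref) >= 0.0

    def test_rdcs_equals_dcs_for_reference_equal_to_current(self):
        rng = np.random.default_rng(9)
        S = random_psd(rng, 2)
        mu = rng.standard_normal(2)
        b = rng.standard_normal(2)
        ref = pc.ReferenceMoments((0, 1), mu, S)
        assert pc.relative_dcs_t(b, mu, S, 0.7, ref) == pytest.approx(
            pc.dynamic_causal_strength_t(b, S, 0.7), abs=1e-14)

    def test_rdcs_minus_dcs_identity(self):
        """Check the printed difference formula for a perturbed cause."""
        rng = np.random.default_rng(11)
        S_t = random_psd(rng, 2)
        S_ref = random_psd(rng, 2)
        mu_t, mu_ref = rng.standard_normal(2), rng.standard_normal(2)
        b = rng.standard_normal(2)
        s = 0.9
        ref = pc.ReferenceMoments((0, 1), mu_ref, S_ref)
        rdcs = pc.relative_dcs_t(b, mu_t, S_t, s, ref)
        dcs = pc.dynamic_causal_strength_t(b, S_t, s)
        v = b @ S_ref @ b + s
        w = b @ S_t @ b + s
        dmu = b @ (mu_t - mu_ref)
        expected_diff = 0.5 * (np.log(v / w)
                               + (s + b @ S_t @ b + dmu ** 2) / v
                               - (s + b @ S_t @ b) / w)
        assert rdcs - dcs == pytest.approx(expected_diff, abs=1e-12)


class TestPopulationIdentities:
    def test_te_equals_dcs_without_self_dependence(self):
        """White cause and no effect self-dependence: the effect past is
        uninformative about the cause past, so TE and DCS both equal the
        mutual information of cause past and effect present — bitwise."""
        model = pc.SVARModel.stationary((0.0,), (0.8,), (0.0,), (0.0,),
                                        innov_var_1=0.5, innov_var_2=1.5)
        res = pc.population_causality(model.resolved(24), ref_window=(1, 8))
        v = res.values["2->1"]
        assert np.array_equal(v["te"], v["dcs"])
        # MI closed form: 1/2 ln(1 + b^2 var(X2)/s1)
        mi = 0.5 * np.log1p(0.8 ** 2 * 1.5 / 0.5)
        np.testing.assert_allclose(v["te"], mi, atol=1e-12)

    def test_rdcs_equals_dcs_on_stationary_segments(self, svar4_model):
        res = pc.population_causality(svar4_model.resolved(40),
                                      ref_window=(1, 16))
        for d in ("2->1", "1->2"):
            np.testing.assert_allclose(res.values[d]["rdcs"],
                                       res.values[d]["dcs"], atol=1e-10)

    def test_innovation_mean_invariance(self, svar4_model):
        """TE and DCS are bitwise invariant to any innovation-mean
        profile; rDCS strictly increases wherever (b' dmu)^2 > 0."""
        T = 50
        base = svar4_model.resolved(T)
        k2 = np.zeros(T)
        k2[25:30] = 3.0
        pert = pc.SVARModel(order=4, coeff_a=base.coeff_a,
                            coeff_b=base.coeff_b, coeff_c=base.coeff_c,
                            coeff_d=base.coeff_d,
                            innov_mean_2=base.innov_mean_2 + k2)
        r0 = pc.population_causality(base, ref_window=(1, 16))
        r1 = pc.population_causality(pert, ref_window=(1, 16))
        assert np.array_equal(r0.values["2->1"]["te"],
                              r1.values["2->1"]["te"])
        assert np.array_equal(r0.values["2->1"]["dcs"],
                              r1.values["2->1"]["dcs"])
        bump = r1.values["2->1"]["rdcs"] - r0.values["2->1"]["rdcs"]
        assert np.all(bump[(r1.peri_times >= 26) & (r1.peri_times < 35)] > 0)
        np.testing.assert_allclose(bump[r1.peri_times < 25], 0.0, atol=1e-12)


class TestMCOracle:
    def setup_row(self, seed, p=1):
        rng = np.random.default_rng(seed)
        model = rand_stable_model(rng, p=p)
        mr = model.resolved(20)
        pop = pc.population_moments(mr)
        t = 15
        mu, P = pop.past_stats(t)
        return mr, t, mu, P

    def test_identical_conditionals_give_zero(self):
        mr, t, mu, P = self.setup_row(2)
        est, se = pc.mc_kl_oracle(mr.coeff_a[t], np.zeros(mr.order), 0.0,
                                  1.0, mu, P, "joint_copy",
                                  n_samples=2000, seed=0)
        assert est == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed,p", [(7, 1), (8, 2)])
    def test_oracle_confirms_closed_forms(self, seed, p):
        mr, t, mu, P = self.setup_row(seed, p=p)
        res = pc.population_causality(mr, ref_window=(1, 10))
        i = np.nonzero(res.peri_times == t)[0][0]
        te = res.values["2->1"]["te"][i]
        dcs = res.values["2->1"]["dcs"][i]
        a, b = mr.coeff_a[t], mr.coeff_b[t]
        s = mr.innov_var_1[t]
        for mode, target in (("conditional_marginalize", te),
                             ("joint_copy", dcs)):
            est, se = pc.mc_kl_oracle(a, b, 0.0, s, mu, P, mode,
                                      n_samples=60000, seed=seed)
            assert abs(est - target) < 3 * se

    def test_reference_copy_reduces_to_dcs(self):
        mr, t, mu, P = self.setup_row(10, p=2)
        a, b = mr.coeff_a[t], mr.coeff_b[t]
        s = mr.innov_var_1[t]
        ref = pc.ReferenceMoments((0, 0), mu[2:], P[2:, 2:])
        dcs = pc.dynamic_causal_strength_t(b, P[2:, 2:], s)
        est, se = pc.mc_kl_oracle(a, b, 0.0, s, mu, P, "reference_copy",
                                  ref=ref, n_samples=60000, seed=3)
        assert abs(est - dcs) < 3 * se


class TestTimecourse:
    def test_channel_swap_swaps_directions(self, stationary_ensemble):
        swapped = pc.EventEnsemble(
            data=stationary_ensemble.data[:, :, ::-1],
            peri_event_time=stationary_ensemble.peri_event_time)
        r0 = pc.causality_timecourse(stationary_ensemble, 4, n_boot=0)
        r1 = pc.causality_timecourse(swapped, 4, n_boot=0)
        for m in ("gc", "te", "dcs", "rdcs"):
            np.testing.assert_allclose(r0.values["2->1"][m],
                                       r1.values["1->2"][m], atol=1e-12)

    def test_stationary_unidirectional_flat_and_dominant(
            self, stationary_ensemble):
        res = pc.causality_timecourse(stationary_ensemble, 4, n_boot=0)
        fwd, rev = res.values["2->1"], res.values["1->2"]
        for m in ("te", "dcs", "rdcs"):
            assert np.all(fwd[m] > rev[m])
            spread = fwd[m].std() / fwd[m].mean()
            assert spread < 0.1   # flat in time up to estimation noise

    def test_bootstrap_sd_shapes_and_reproducibility(
            self, stationary_ensemble):
        r0 = pc.causality_timecourse(stationary_ensemble, 2, n_boot=8,
                                     seed=5)
        r1 = pc.causality_timecourse(stationary_ensemble, 2, n_boot=8,
                                     seed=5)
        sd = r0.sd["2->1"]["te"]
        assert sd.shape == r0.peri_times.shape
        assert np.all(sd > 0)
        np.testing.assert_array_equal(sd, r1.sd["2->1"]["te"])

    def test_result_frame_roundtrip(self, stationary_ensemble, tmp_path):
        res = pc.causality_timecourse(stationary_ensemble, 2, n_boot=4)
        frame = res.to_frame()
        assert set(frame["measure"]) == {"gc", "te", "dcs", "rdcs"}
        assert set(frame["direction"]) == {"2->1", "1->2"}
        res.to_csv(tmp_path / "r.csv")
        res.save_summary(tmp_path / "s.json")
        assert (tmp_path / "r.csv").stat().st_size > 0
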