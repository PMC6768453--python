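import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hydrabind import (
    FreeEnergyResult,
    GaussianAlchemyTruth,
    LambdaSampleSet,
    LambdaSchedule,
    SoftCoreParams,
    TransferConfig,
    decompose,
    generate_lambda_samples,
    kbt,
    softcore_transform,
    swap_acceptance,
    transfer_free_energy,
    uwham_solve,
)
from hydrabind.alchemy import read_samples_csv, write_samples_csv


class TestSchedule:
    def test_preset_has_28_states(self):
        sched = LambdaSchedule.preset("d3-28")
        assert len(sched) == 28
        assert sched.values[0] == 0.0 and sched.values[-1] == 1.0

    def test_validation(self):
        with pytest.raises(ValueError):
            LambdaSchedule((0.0, 0.5, 0.5, 1.0))
        with pytest.raises(ValueError):
            LambdaSchedule((0.1, 1.0))


class TestSoftCore:
    def test_identity_below_onset_and_continuity(self):
        p = SoftCoreParams(u_c=100.0, u_max=300.0)
        assert softcore_transform(-50.0, p) == -50.0
        assert softcore_transform(100.0, p) == pytest.approx(100.0)

    def test_cap_at_infinity(self):
        p = SoftCoreParams(u_c=100.0, u_max=300.0)
        assert softcore_transform(1e9, p) == pytest.approx(300.0, abs=1e-6)

    def test_tanh_value_one_span_above_onset(self):
        p = SoftCoreParams(u_c=100.0, u_max=300.0)
        assert softcore_transform(300.0, p) == pytest.approx(
            100.0 + 200.0 * math.tanh(1.0)
        )

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-500, 5000), st.floats(-500, 5000))
    def test_monotone_and_bounded(self, a, b):
        p = SoftCoreParams(u_c=100.0, u_max=300.0)
        fa, fb = softcore_transform(a, p), softcore_transform(b, p)
        if a <= b:
            assert fa <= fb + 1e-12
        assert fa <= 300.0 and fb <= 300.0


class TestSwapAcceptance:
    def test_energy_neutral_swap_accepted(self):
        assert swap_acceptance(0.2, 0.7, -10.0, -10.0, 300.0) == 1.0

    def test_downhill_swap_accepted(self):
        # swapping lowers lambda_j*u: the strongly bound configuration moves
        # to the more strongly coupled state
        assert swap_acceptance(0.0, 0.5, -20.0, -5.0, 300.0) == 1.0

    def test_numeric_example_capped_at_one(self):
        # exp[+(0.1)(10)/kT] > 1 -> capped
        assert swap_acceptance(0.0, 0.1, -5.0, 5.0, 300.0) == 1.0

    @settings(derandomize=True, max_examples=50)
    @given(
        li=st.floats(0, 1), lj=st.floats(0, 1),
        ui=st.floats(-50, 50), uj=st.floats(-50, 50),
    )
    def test_detailed_balance(self, li, lj, ui, uj):
        beta = 1.0 / kbt(300.0)
        delta = (li - lj) * (uj - ui)
        p_fwd = swap_acceptance(li, lj, ui, uj, 300.0)
        # reverse move: same lambda pair, configurations already exchanged
        p_rev = swap_acceptance(li, lj, uj, ui, 300.0)
        assert p_fwd / p_rev == pytest.approx(math.exp(-beta * delta), rel=1e-9)


class TestUWHAM:
    def test_identical_ensembles_give_zero_dG(self):
        rng = np.random.default_rng(0)
        u = rng.normal(-10, 2, 800)
        sched = LambdaSchedule((0.0, 1.0))
        # same lambda spacing trick is not possible; use same samples at two
        # states of a schedule where both states see identical distributions
        ss = LambdaSampleSet(sched, [u, u], temperature=300.0,
                             softcore=SoftCoreParams(enabled=False))
        # dG(1) for identical sample pools equals the Zwanzig estimate, and
        # the two duplicated states must carry identical weights: G is finite
        # and the estimator converges
        res = uwham_solve(ss)
        assert res.converged
        # duplicated-state check: two states at the same lambda
        truth = GaussianAlchemyTruth(mu=-10.0, sigma=2.0)
        sched3 = LambdaSchedule((0.0, 0.5, 0.5000001, 1.0))
        ss3 = generate_lambda_samples(truth, sched3, 2000, seed=3)
        res3 = uwham_solve(ss3)
        dg_mid = res3.free_energies[2] - res3.free_energies[1]
        assert abs(dg_mid) < 3 * math.hypot(res3.errors[1], res3.errors[2]) + 1e-3

    def test_gaussian_closed_form_recovery(self):
        truth = GaussianAlchemyTruth(mu=-40.0, sigma=3.0, temperature=300.0)
        sched = LambdaSchedule.preset("d3-28")
        ss = generate_lambda_samples(truth, sched, 1000, seed=42)
        res = uwham_solve(ss)
        assert res.converged
        assert abs(res.dG - truth.dG(1.0)) < 3 * res.dG_err
        # intermediate states track the closed form too
        for k in (10, 18, 24):
            lam = sched.values[k]
            tol = 3 * res.errors[k] + 0.02
            assert abs(res.free_energies[k] - truth.dG(lam)) < tol

    def test_constant_shift_invariance(self):
        truth = GaussianAlchemyTruth(mu=-20.0, sigma=2.0)
        sched = LambdaSchedule.uniform(6)
        ss = generate_lambda_samples(truth, sched, 500, seed=5)
        res = uwham_solve(ss)
        shift = 7.5
        ss_shifted = LambdaSampleSet(
            sched, [s + shift for s in ss.samples], ss.temperature, ss.softcore
        )
        res_s = uwham_solve(ss_shifted)
        for k, lam in enumerate(sched.values):
            assert res_s.free_energies[k] - res.free_energies[k] == pytest.approx(
                lam * shift, abs=1e-6
            )

    def test_zwanzig_reduction_single_sampled_state(self):
        rng = np.random.default_rng(8)
        mu, sigma = -5.0, 1.5
        u = rng.normal(mu, sigma, 5000)
        sched = LambdaSchedule((0.0, 0.3, 1.0))
        ss = LambdaSampleSet(sched, [u, np.empty(0), np.empty(0)],
                             temperature=300.0,
                             softcore=SoftCoreParams(enabled=False))
        res = uwham_solve(ss)
        beta = 1.0 / kbt(300.0)
        for k, lam in enumerate(sched.values):
            zwanzig = -kbt(300.0) * (
                np.log(np.mean(np.exp(-beta * lam * (u - u.mean()))))
            ) + lam * u.mean()
            assert res.free_energies[k] == pytest.approx(zwanzig, abs=1e-8)

    def test_gaussian_recovery_sweep(self):
        # mu x sigma sweep: estimate within 3 reported sigma in >= 95% of runs
        sched = LambdaSchedule.uniform(8)
        hits, total = 0, 0
        for mu in (-20.0, -40.0):
            for sigma in (1.0, 2.0, 3.0):
                truth = GaussianAlchemyTruth(mu=mu, sigma=sigma)
                for seed in range(3):
                    ss = generate_lambda_samples(truth, sched, 400, seed=100 + seed)
                    res = uwham_solve(ss)
                    total += 1
                    if abs(res.dG - truth.dG(1.0)) < 3 * max(res.dG_err, 1e-6):
                        hits += 1
        assert hits / total >= 0.95

    def test_no_samples_rejected(self):
        sched = LambdaSchedule((0.0, 1.0))
        ss = LambdaSampleSet(sched, [np.empty(0), np.empty(0)])
        with pytest.raises(ValueError):
            uwham_solve(ss)


class TestTransfer:
    def test_printed_value_at_standard_conditions(self):
        cfg = TransferConfig(site_radius=3.5, standard_concentration=1.0,
                             temperature=298.15)
        assert round(transfer_free_energy(cfg), 2) == 1.32

    def test_unit_volume_gives_zero(self):
        # V_site = 1/C° per molecule -> log term vanishes
        r = (3.0 * 1660.54 / (4.0 * math.pi)) ** (1.0 / 3.0)
        cfg = TransferConfig(site_radius=r, temperature=298.15)
        assert transfer_free_energy(cfg) == pytest.approx(0.0, abs=1e-10)

    def test_direct_evaluation_at_5A_300K(self):
        cfg = TransferConfig(site_radius=5.0, temperature=300.0)
        assert transfer_free_energy(cfg) == pytest.approx(0.688, abs=5e-4)

    def test_monotone_in_radius_and_temperature(self):
        vals = [
            transfer_free_energy(TransferConfig(site_radius=r, temperature=298.15))
            for r in (2.0, 3.5, 5.0, 7.0)
        ]
        assert all(b < a for a, b in zip(vals, vals[1:]))
        vals_t = [
            transfer_free_energy(TransferConfig(site_radius=3.5, temperature=t))
            for t in (280.0, 300.0, 320.0)
        ]
        assert all(b > a for a, b in zip(vals_t, vals_t[1:]))  # C°V < 1 here


class TestDecompose:
    def test_full_decomposition_invariants(self):
        truth = GaussianAlchemyTruth(mu=-40.0, sigma=3.0)
        sched = LambdaSchedule.uniform(8)
        ss = generate_lambda_samples(truth, sched, 800, seed=12)
        res = uwham_solve(ss)
        cfg = TransferConfig()
        out = decompose(ss, res, cfg, dG_ionization=0.4)
        assert out.dG_b_standard == pytest.approx(
            out.dG_b + out.dG_transfer + out.dG_ionization
        )
        assert out.dG_reorg == pytest.approx(out.dG_b_standard - out.dE_b)
        assert out.dG_reorg_err == pytest.approx(
            math.hypot(out.dG_b_err, out.dE_b_err)
        )
        # dE_b is the mean coupled-state binding energy
        assert out.dE_b == pytest.approx(float(np.mean(ss.samples[-1])))
        se = np.std(ss.samples[-1], ddof=1) / math.sqrt(len(ss.samples[-1]))
        assert out.dE_b_err == pytest.approx(float(se))
        # closed-form cross-check of the mean coupled-state energy
        assert abs(out.dE_b - truth.tilted_mean(1.0)) < 4 * out.dE_b_err

    def test_empty_coupled_state_rejected(self):
        sched = LambdaSchedule((0.0, 1.0))
        ss = LambdaSampleSet(sched, [np.array([-1.0, -2.0]), np.empty(0)])
        res_fake = uwham_solve(
            LambdaSampleSet(sched, [np.array([-1.0, -2.0]), np.array([-1.5])])
        )
        with pytest.raises(ValueError):
            decompose(ss, res_fake, TransferConfig())

    def test_zero_reorganization_when_means_match(self):
        r = FreeEnergyResult(
            dG_b=-5.0, dG_b_err=0.1, dG_transfer=1.32, dG_ionization=0.0,
            dG_b_standard=-3.68, dE_b=-3.68, dE_b_err=0.2,
            dG_reorg=0.0, dG_reorg_err=math.hypot(0.1, 0.2),
        )
        assert r.dG_reorg == r.dG_b_standard - r.dE_b == 0.0


def test_samples_csv_roundtrip_and_discard(tmp_path):
    truth = GaussianAlchemyTruth()
    sched = LambdaSchedule.uniform(4)
    ss = generate_lambda_samples(truth, sched, 100, seed=2)
    write_samples_csv(ss, tmp_path / "s.csv", tmp_path / "m.json")
    back = read_samples_csv(tmp_path / "s.csv", metadata_path=tmp_path / "m.json")
    assert back.temperature == ss.temperature
    assert np.allclose(back.samples[0], ss.samples[0])
    half = back.discard_initial(0.5)
    assert len(half.samples[0]) == 50
    assert np.allclose(half.samples[0], ss.samples[0][50:])
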