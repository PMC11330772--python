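"""Bi-substrate rate laws, fitting and mechanism discrimination."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aaokin.errors import InputError, ModelSpecificationError
from aaokin.steady_state import (
    BiSubstrateDataset,
    BiSubstrateRegressor,
    SteadyStateParams,
    discriminate_mechanism,
    fit_bisubstrate,
    hanes_woolf,
    pingpong_rate,
    sequential_rate,
)
from aaokin.synthetic_data import NoiseSpec, gen_bisubstrate

PP = dict(kcat=201.0, Km_alcohol_uM=50.0, Km_acceptor_uM=176.0)

positive = st.floats(min_value=1e-2, max_value=1e5, allow_nan=False)


class TestRateLaws:
    @pytest.mark.parametrize(
        "A,B,expected",
        [
            (50.0, 176.0, 201.0 / 3.0),     # symmetric half-saturation
            (100.0, 176.0, 80.4),           # 201*17600/44000
            (0.0, 176.0, 0.0),
            (50.0, 0.0, 0.0),
        ],
    )
    def test_pingpong_values(self, A, B, expected):
        assert pingpong_rate(A, B, **PP) == pytest.approx(expected, rel=1e-12)

    def test_pingpong_saturates_at_kcat(self):
        assert pingpong_rate(1e10, 1e10, **PP) == pytest.approx(201.0, rel=1e-5)

    def test_sequential_value(self):
        # kcat*A*B/(KmB*A + KmA*B + A*B + Kd*KmB) = 201*8800/40480
        v = sequential_rate(50.0, 176.0, **PP, Kd_alcohol_uM=80.0)
        assert v == pytest.approx(201.0 * 8800.0 / 40480.0, rel=1e-12)
        assert v == pytest.approx(43.7, abs=0.05)

    def test_sequential_reduces_to_pingpong_at_zero_Kd(self):
        A = np.array([10.0, 300.0, 5000.0])
        B = np.array([20.0, 176.0, 2000.0])
        np.testing.assert_allclose(
            sequential_rate(A, B, **PP, Kd_alcohol_uM=0.0),
            pingpong_rate(A, B, **PP),
        )

    def test_sequential_saturates_at_kcat(self):
        v = sequential_rate(1e12, 1e12, **PP, Kd_alcohol_uM=80.0)
        assert v == pytest.approx(201.0, rel=1e-6)

    def test_negative_concentration_rejected(self):
        with pytest.raises(InputError):
            pingpong_rate(-1.0, 10.0, **PP)

    def test_sequential_requires_Kd(self):
        with pytest.raises(ModelSpecificationError):
            sequential_rate(10.0, 10.0, **PP)

    @given(kcat=positive, KmA=positive, KmB=positive,
           A=positive, B=positive, factor=st.floats(1.01, 100.0))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, kcat, KmA, KmB, A, B, factor):
        v = pingpong_rate(A, B, kcat, KmA, KmB)
        assert 0.0 <= v <= kcat
        assert pingpong_rate(A * factor, B, kcat, KmA, KmB) >= v
        assert pingpong_rate(A, B * factor, kcat, KmA, KmB) >= v

    @given(kcat=positive, KmA=positive, KmB=positive,
           A=positive, B=positive, Kd=st.floats(0.0, 1e5))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_sequential_never_exceeds_pingpong(self, kcat, KmA, KmB, A, B, Kd):
        assert sequential_rate(A, B, kcat, KmA, KmB, Kd) <= \
            pingpong_rate(A, B, kcat, KmA, KmB) + 1e-12


class TestHanesWoolf:
    def test_pingpong_common_intercept(self, peaao_o2_params, no_noise):
        data = gen_bisubstrate(peaao_o2_params, noise=no_noise)
        lines = hanes_woolf(data)
        intercepts = [ln.intercept for ln in lines]
        # exact ping-pong data: intercept = KmA/kcat at every B level
        np.testing.assert_allclose(intercepts, 50.0 / 201.0, rtol=1e-8)

    def test_sequential_intercepts_rise_at_low_B(self, no_noise):
        p = SteadyStateParams(201.0, 50.0, 176.0, Kd_alcohol_uM=80.0)
        data = gen_bisubstrate(p, model="sequential", noise=no_noise)
        lines = sorted(hanes_woolf(data), key=lambda ln: ln.acceptor_uM)
        intercepts = [ln.intercept for ln in lines]
        assert all(a > b for a, b in zip(intercepts, intercepts[1:]))
        # intercept = (KmA + Kd*KmB/B)/kcat
        for ln in lines:
            expect = (50.0 + 80.0 * 176.0 / ln.acceptor_uM) / 201.0
            assert ln.intercept == pytest.approx(expect, rel=1e-8)

    def test_single_acceptor_level_flagged(self, peaao_o2_params):
        A = np.geomspace(10, 500, 5)
        data = BiSubstrateDataset(
            A, np.full(5, 176.0),
            pingpong_rate(A, 176.0, **PP),
        )
        with pytest.raises(InputError):
            hanes_woolf(data)


class TestFitting:
    @pytest.mark.parametrize("model", ["ping-pong", "sequential"])
    def test_noiseless_recovery(self, model, no_noise):
        p = SteadyStateParams(
            201.0, 50.0, 176.0,
            Kd_alcohol_uM=80.0 if model == "sequential" else None,
        )
        data = gen_bisubstrate(p, model=model, noise=no_noise)
        fit, _ = fit_bisubstrate(data, model)
        assert fit.kcat == pytest.approx(201.0, rel=1e-6)
        assert fit.Km_alcohol_uM == pytest.approx(50.0, rel=1e-6)
        assert fit.Km_acceptor_uM == pytest.approx(176.0, rel=1e-6)
        if model == "sequential":
            assert fit.Kd_alcohol_uM == pytest.approx(80.0, rel=1e-4)

    def test_noisy_kcat_within_5pct(self, peaao_o2_params):
        data = gen_bisubstrate(peaao_o2_params, noise=NoiseSpec(sd=0.02, seed=7))
        fit, _ = fit_bisubstrate(data, "ping-pong")
        assert fit.kcat == pytest.approx(201.0, rel=0.05)

    def test_single_B_level_rejected(self):
        A = np.geomspace(10, 500, 6)
        X = np.column_stack([A, np.full(6, 176.0)])
        y = pingpong_rate(A, 176.0, **PP)
        with pytest.raises(InputError):
            BiSubstrateRegressor().fit(X, y)

    def test_efficiencies_are_unit_converted_ratios(self, peaao_o2_params,
                                                    no_noise):
        data = gen_bisubstrate(peaao_o2_params, noise=no_noise)
        fit, _ = fit_bisubstrate(data, "ping-pong")
        assert fit.eff_alcohol == pytest.approx(
            fit.kcat / fit.Km_alcohol_uM * 1000.0
        )
        assert fit.eff_acceptor == pytest.approx(
            fit.kcat / fit.Km_acceptor_uM * 1000.0
        )
        # PeAAO/O2 efficiencies as conventionally tabulated
        assert fit.eff_alcohol == pytest.approx(4020.0, rel=0.01)
        assert fit.eff_acceptor == pytest.approx(1142.0, rel=0.01)

    def test_recovery_bias_over_seeds(self, peaao_o2_params):
        """Median relative bias of each parameter < 2% at 2% noise."""
        rel = {"kcat": [], "KmA": [], "KmB": []}
        for seed in range(20):
            data = gen_bisubstrate(
                peaao_o2_params, noise=NoiseSpec(sd=0.02, seed=seed)
            )
            fit, _ = fit_bisubstrate(data, "ping-pong")
            rel["kcat"].append(fit.kcat / 201.0 - 1.0)
            rel["KmA"].append(fit.Km_alcohol_uM / 50.0 - 1.0)
            rel["KmB"].append(fit.Km_acceptor_uM / 176.0 - 1.0)
        for name, biases in rel.items():
            assert abs(np.median(biases)) < 0.02, name


class TestDiscrimination:
    def test_pingpong_data_chooses_pingpong(self, peaao_o2_params):
        """At 2% noise the verdict is ping-pong for nearly every seed."""
        votes = [
            discriminate_mechanism(
                gen_bisubstrate(peaao_o2_params,
                                noise=NoiseSpec(sd=0.02, seed=s))
            ).chosen_model
            for s in range(10)
        ]
        assert votes.count("ping-pong") >= 9

    def test_strongly_sequential_data_chooses_sequential(self):
        p = SteadyStateParams(201.0, 50.0, 176.0, Kd_alcohol_uM=500.0)
        for seed in range(5):
            data = gen_bisubstrate(p, model="sequential",
                                   noise=NoiseSpec(sd=0.02, seed=seed))
            assert discriminate_mechanism(data).chosen_model == "sequential"

    @pytest.mark.parametrize("model,Kd", [("ping-pong", None),
                                          ("sequential", 500.0)])
    def test_noiseless_margin_exceeds_10(self, model, Kd, no_noise):
        p = SteadyStateParams(201.0, 50.0, 176.0, Kd_alcohol_uM=Kd)
        data = gen_bisubstrate(p, model=model, noise=no_noise)
        verdict = discriminate_mechanism(data)
        assert verdict.chosen_model == model
        if model == "sequential":
            assert verdict.delta_aicc < -10
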