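"""Catalytic-cycle ODE simulation vs King-Altman closed forms."""

import numpy as np
import pytest

from aaokin.errors import FitError, InputError, ModelSpecificationError
from aaokin.mechanism import (
    CatalyticCycleModel,
    default_epsilons,
    redox_fraction,
    scan_apparent_kinetics,
    simulate_turnover,
    steady_state_closed_form,
)
from aaokin.steady_state import fit_bisubstrate, hanes_woolf


def baaao_o2_model(**overrides):
    """BaAAO-like minimal cycle (reduction + O2 reoxidation constants)."""
    kwargs = dict(
        kred=117.0, Kd_alcohol_uM=765.0, app_kox=216.0,
        alcohol_uM=5000.0, acceptor_uM=258.0, enzyme_uM=10.0,
    )
    kwargs.update(overrides)
    return CatalyticCycleModel(**kwargs)


class TestSimulation:
    def test_conservation_laws(self):
        trace = simulate_turnover(baaao_o2_model(), 2.0)
        assert trace.conservation_error() < 1e-9

    def test_no_acceptor_single_turnover(self):
        """Without acceptor the enzyme reduces once and stays reduced."""
        trace = simulate_turnover(baaao_o2_model(acceptor_uM=0.0), 5.0)
        assert trace.species_uM["Ered"][-1] == pytest.approx(10.0, rel=1e-6)
        assert trace.aldehyde_uM[-1] == pytest.approx(10.0, rel=1e-6)

    def test_no_alcohol_flat_trace(self):
        trace = simulate_turnover(
            baaao_o2_model(alcohol_uM=0.0), 2.0,
            epsilons=default_epsilons(),
        )
        assert np.ptp(trace.A462) < 1e-12
        assert trace.species_uM["Eox"][-1] == pytest.approx(10.0)

    def test_bq_exhausted_before_alcohol(self):
        """Excess alcohol over BQ: acceptor runs out first and the enzyme
        ends fully reduced (band I collapses to the reduced level)."""
        model = CatalyticCycleModel(
            kred=251.0, Kd_alcohol_uM=80.0, app_kox=792.0,
            alcohol_uM=2000.0, acceptor_uM=300.0, enzyme_uM=10.0,
            branch="BQ",
        )
        trace = simulate_turnover(model, 5.0, epsilons=default_epsilons())
        assert trace.acceptor_uM[-1] < 1e-6
        assert trace.reduced_acceptor_uM[-1] == pytest.approx(300.0, rel=1e-6)
        # one alcohol per BQ plus the one reducing equivalent left on FAD
        assert trace.alcohol_uM[-1] == pytest.approx(2000.0 - 300.0 - 10.0,
                                                     rel=1e-6)
        assert trace.oxidized_fraction()[-1] < 1e-6
        assert trace.conservation_error() < 1e-9

    def test_product_release_variant_conserves(self):
        model = baaao_o2_model(variant="product_release", krel=150.0)
        trace = simulate_turnover(model, 2.0)
        assert trace.conservation_error() < 1e-9

    def test_missing_variant_constants_rejected(self):
        with pytest.raises(ModelSpecificationError):
            baaao_o2_model(variant="product_release")

    def test_bad_t_end_rejected(self):
        with pytest.raises(InputError):
            simulate_turnover(baaao_o2_model(), -1.0)


class TestClosedForm:
    def test_symmetric_rates_half_oxidized(self):
        # k_a = k_b -> fraction 0.5: saturating alcohol, B tuned so that
        # app_kox*B = kred
        model = baaao_o2_model(kred=100.0, Kd_alcohol_uM=1e-6, app_kox=100.0)
        s = steady_state_closed_form(model, 1e9, 1000.0)
        assert s.fraction_oxidized == pytest.approx(0.5, rel=1e-6)

    def test_peaao_bq_example(self):
        # k_a = 251 (saturating), k_b = 792*0.3 = 237.6
        model = CatalyticCycleModel(
            kred=251.0, Kd_alcohol_uM=1e-9, app_kox=792.0,
            alcohol_uM=1e9, acceptor_uM=300.0, enzyme_uM=10.0,
        )
        s = steady_state_closed_form(model, 1e9, 300.0)
        assert s.fraction_oxidized == pytest.approx(237.6 / (251.0 + 237.6),
                                                    rel=1e-4)
        assert s.apparent_kcat == pytest.approx(122.1, abs=0.2)

    def test_product_release_limit_reduces_to_two_state(self):
        base = baaao_o2_model()
        with_rel = baaao_o2_model(variant="product_release", krel=1e12)
        s2 = steady_state_closed_form(base, 5000.0, 258.0)
        s3 = steady_state_closed_form(with_rel, 5000.0, 258.0)
        assert s3.apparent_kcat == pytest.approx(s2.apparent_kcat, rel=1e-9)

    def test_zero_rate_gives_zero_turnover(self):
        s = steady_state_closed_form(baaao_o2_model(app_kox=0.0),
                                     5000.0, 258.0)
        assert s.apparent_kcat == 0.0
        assert s.fraction_oxidized == 0.0

    def test_ode_matches_closed_form_on_clamped_pools(self):
        """Oracle equivalence: relaxed clamped-pool ODE vs King-Altman."""
        model = baaao_o2_model()
        cf = steady_state_closed_form(model, model.alcohol_uM,
                                      model.acceptor_uM)
        trace = simulate_turnover(model, 2.0, clamp_pools=True,
                                  epsilons=default_epsilons())
        frac = redox_fraction(trace, slope_fraction=1e-4)
        assert frac.fraction_oxidized == pytest.approx(
            cf.fraction_oxidized, abs=1e-4
        )
        assert trace.oxidized_fraction()[-1] == pytest.approx(
            cf.fraction_oxidized, abs=1e-6
        )


class TestRedoxFraction:
    def test_fast_reoxidation_mostly_oxidized(self):
        model = baaao_o2_model(app_kox=50000.0)
        trace = simulate_turnover(model, 0.5, clamp_pools=True,
                                  epsilons=default_epsilons())
        frac = redox_fraction(trace)
        assert frac.fraction_oxidized > 0.97

    def test_absorbance_and_species_routes_agree(self):
        trace = simulate_turnover(baaao_o2_model(), 2.0, clamp_pools=True,
                                  epsilons=default_epsilons())
        frac = redox_fraction(trace)
        assert frac.fraction_oxidized_from_A462 == pytest.approx(
            frac.fraction_oxidized, abs=1e-6
        )

    def test_flat_trace_has_no_plateau_info(self):
        trace = simulate_turnover(baaao_o2_model(alcohol_uM=0.0), 1.0,
                                  epsilons=default_epsilons())
        with pytest.raises(FitError):
            redox_fraction(trace)

    def test_fraction_monotone_in_acceptor(self):
        fracs = [
            steady_state_closed_form(baaao_o2_model(), 5000.0, b)
            .fraction_oxidized
            for b in (50.0, 258.0, 1000.0)
        ]
        assert fracs[0] < fracs[1] < fracs[2]


class TestScanApparentKinetics:
    def test_minimal_cycle_is_exactly_pingpong(self):
        model = baaao_o2_model()
        data = scan_apparent_kinetics(
            model, np.geomspace(100.0, 5000.0, 5),
            np.geomspace(30.0, 1000.0, 5),
        )
        fit, reg = fit_bisubstrate(data, "ping-pong")
        assert reg.rss_ < 1e-18
        assert fit.kcat == pytest.approx(117.0, rel=1e-8)
        assert fit.Km_alcohol_uM == pytest.approx(765.0, rel=1e-8)
        # Km(acceptor) = kred/app_kox in mM -> µM
        assert fit.Km_acceptor_uM == pytest.approx(117.0 / 216.0 * 1000.0,
                                                   rel=1e-8)

    def test_hanes_intercepts_b_independent(self):
        data = scan_apparent_kinetics(
            baaao_o2_model(), np.geomspace(100.0, 5000.0, 5),
            np.geomspace(30.0, 1000.0, 5),
        )
        lines = hanes_woolf(data)
        intercepts = np.array([ln.intercept for ln in lines])
        assert np.ptp(intercepts) < 1e-9 * intercepts.mean()

    def test_single_point_grid_breaks_downstream_fit(self):
        data = scan_apparent_kinetics(
            baaao_o2_model(), np.array([500.0]),
            np.geomspace(30.0, 1000.0, 5),
        )
        with pytest.raises(InputError):
            fit_bisubstrate(data, "ping-pong")
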