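"""Mechanism simulators: conservation, equilibria, observables, SSA oracle."""

import numpy as np
import pytest

from ccexchange import fitting
from ccexchange.errors import DomainError, InputError, SchemaError
from ccexchange.kinetics import (
    DimerDissociationParams,
    DimerIntermediateParams,
    SwapKernelParams,
    dimer_dissociation_network,
    dimer_intermediate_network,
    fluorescence_from_state,
    gillespie_oracle,
    intermediate_params_from_slope,
    simulate_dissociation_mechanism,
    simulate_intermediate_mechanism,
    simulate_swap_kernel,
    swap_network,
)
from ccexchange.species import QuenchModel

from conftest import binomial_pmf


def dimer_distribution(state) -> np.ndarray:
    c = state.concentrations
    d = np.array([c["UU"], c["LU"], c["LL"]])
    return d / d.sum()


class TestZeroRate:
    def test_intermediate_zero_rate_is_static(self):
        traj = simulate_intermediate_mechanism(
            DimerIntermediateParams(k_assoc=0.0, k_resolve=1.0),
            {"LL": 1.0, "UU": 10.0},
            np.linspace(0, 100, 11),
        )
        assert np.max(np.abs(traj.concentrations - traj.concentrations[0])) < 1e-12

    def test_dissociation_zero_koff_no_exchange(self):
        traj = simulate_dissociation_mechanism(
            DimerDissociationParams(k_off=0.0, k_on=100.0),
            {"LL": 1.0, "UU": 10.0},
            np.linspace(0, 100, 11),
        )
        np.testing.assert_allclose(traj.observable, 0.0, atol=1e-12)

    def test_swap_zero_rate_is_static(self):
        traj = simulate_swap_kernel(
            SwapKernelParams(n=3, k_swap=0.0),
            {"A3": 1.0, "A0": 10.0},
            np.linspace(0, 100, 11),
        )
        assert np.max(np.abs(traj.concentrations - traj.concentrations[0])) < 1e-12


class TestEquilibria:
    """Long-time limits: label-blind mixing must reach the binomial state."""

    def test_intermediate_reaches_binomial_mixing(self, calibrated_intermediate):
        traj = simulate_intermediate_mechanism(
            calibrated_intermediate, {"LL": 1.0, "UU": 10.0}, [0.0, 2e4]
        )
        tv = 0.5 * np.abs(
            dimer_distribution(traj.final_state()) - binomial_pmf(2, 1 / 11)
        ).sum()
        assert tv < 1e-6

    def test_intermediate_equilibrium_quotient_is_four(self):
        params = DimerIntermediateParams(k_assoc=0.01, k_resolve=10.0)
        traj = simulate_intermediate_mechanism(
            params, {"LL": 5.0, "UU": 5.0}, [0.0, 5e4]
        )
        c = traj.final_state().concentrations
        assert c["LU"] ** 2 / (c["LL"] * c["UU"]) == pytest.approx(4.0, abs=1e-4)

    def test_dissociation_reaches_binomial_and_monomers_stay_rare(self):
        params = DimerDissociationParams.from_kd(k_off=0.08, K_D=1e-4)
        traj = simulate_dissociation_mechanism(
            params, {"LL": 1.0, "UU": 10.0}, [0.0, 2e3]
        )
        c = traj.final_state().concentrations
        tv = 0.5 * np.abs(
            dimer_distribution(traj.final_state()) - binomial_pmf(2, 1 / 11)
        ).sum()
        assert tv < 1e-6
        # folded dimers dominate: total conc >> K_D so monomers are scarce
        monomer_chain_fraction = (c["L"] + c["U"]) / 22.0
        assert monomer_chain_fraction < 0.01

    def test_swap_kernel_trimer_reaches_binomial(self):
        traj = simulate_swap_kernel(
            SwapKernelParams(n=3, k_swap=1e-3), {"A3": 1.0, "A0": 10.0}, [0.0, 1e5]
        )
        c = traj.final_state().concentrations
        dist = np.array([c[f"A{l}"] for l in range(4)])
        tv = 0.5 * np.abs(dist / dist.sum() - binomial_pmf(3, 1 / 11)).sum()
        assert tv < 1e-6

    def test_dimer_swap_matches_intermediate_long_time_limit(
        self, calibrated_intermediate
    ):
        swap = simulate_swap_kernel(
            SwapKernelParams(n=2, k_swap=1e-3), {"A2": 1.0, "A0": 10.0}, [0.0, 1e5]
        )
        inter = simulate_intermediate_mechanism(
            calibrated_intermediate, {"LL": 1.0, "UU": 10.0}, [0.0, 2e4]
        )
        cs = swap.final_state().concentrations
        swap_dist = np.array([cs["A0"], cs["A1"], cs["A2"]])
        swap_dist /= swap_dist.sum()
        tv = 0.5 * np.abs(swap_dist - dimer_distribution(inter.final_state())).sum()
        assert tv < 1e-6


@pytest.mark.parametrize(
    "make",
    [
        lambda: (
            DimerIntermediateParams(k_assoc=5e-3, k_resolve=50.0),
            {"LL": 1.0, "UU": 10.0},
        ),
        lambda: (
            DimerDissociationParams.from_kd(k_off=0.1, K_D=1e-4),
            {"LL": 1.0, "UU": 10.0},
        ),
        lambda: (SwapKernelParams(n=5, k_swap=1e-3), {"A5": 1.0, "A0": 10.0}),
    ],
    ids=["intermediate", "dissociation", "swap5"],
)
def test_chain_conservation_along_trajectories(make):
    from ccexchange.kinetics import network_for

    params, init = make()
    net = network_for(params)
    traj = net.simulate(init, np.linspace(0, 500, 40))
    lab0, unl0 = traj.total_labelled()[0], traj.total_unlabelled()[0]
    assert np.max(np.abs(traj.total_labelled() - lab0)) / lab0 < 1e-9
    assert np.max(np.abs(traj.total_unlabelled() - unl0)) / unl0 < 1e-9


class TestPseudoFirstOrder:
    """Emergent single-exponential behaviour of the intermediate mechanism."""

    def test_traces_are_single_exponential_and_kobs_linear(
        self, calibrated_intermediate
    ):
        k_ref = calibrated_intermediate.k_assoc / 1.5
        concs = np.array([20.0, 50.0, 100.0, 200.0])  # unlabelled chains, uM
        kobs = []
        for u in concs:
            t_max = 5.0 / (k_ref * (u / 2 + 1))
            traj = simulate_intermediate_mechanism(
                calibrated_intermediate,
                {"LL": 1.0, "UU": u / 2},
                np.linspace(0, t_max, 101),
            )
            fit = fitting.fit_exponential_rise(traj.times, traj.observable)
            assert fit.r_squared_ >= 0.999
            kobs.append(fit.k_obs_)
        line = fitting.fit_concentration_dependence(concs, kobs)
        assert line.r_squared_ >= 0.99
        # slope in chain units is half the assembly-level slope k_ref
        assert line.slope_ == pytest.approx(k_ref / 2, rel=0.02)

    def test_labelled_concentration_insensitivity(self, calibrated_intermediate):
        """k_obs tracks total dimer concentration, so at a fixed 200 uM
        unlabelled background the variation across 1-20 uM labelled is small:
        its coefficient of variation stays below 5%."""
        kobs = []
        for lab in [1.0, 2.0, 5.0, 10.0, 20.0]:
            traj = simulate_intermediate_mechanism(
                calibrated_intermediate,
                {"LL": lab / 2, "UU": 100.0},
                np.linspace(0, 30, 101),
            )
            kobs.append(fitting.fit_exponential_rise(traj.times, traj.observable).k_obs_)
        kobs = np.array(kobs)
        assert np.std(kobs, ddof=1) / kobs.mean() < 0.05

    def test_dissociation_mechanism_kobs_flat_in_unlabelled_excess(self):
        """With k_off rate-limiting, k_obs is set by dimer dissociation and
        barely moves across a 10-fold range of unlabelled excess."""
        params = DimerDissociationParams.from_kd(k_off=0.08, K_D=1e-4)
        kobs = []
        for u in [10.0, 25.0, 50.0, 100.0]:  # unlabelled dimers, uM
            traj = simulate_dissociation_mechanism(
                params, {"LL": 1.0, "UU": u}, np.linspace(0, 60, 101)
            )
            kobs.append(fitting.fit_exponential_rise(traj.times, traj.observable).k_obs_)
        kobs = np.array(kobs)
        assert (kobs.max() - kobs.min()) / kobs.mean() < 0.05


class TestObservable:
    def test_fluorescence_counts_unquenched_labels(self):
        net = dimer_dissociation_network(DimerDissociationParams(k_off=1.0, k_on=1.0))
        assert fluorescence_from_state(net.make_state({"UU": 3.0})) == 0.0
        assert fluorescence_from_state(net.make_state({"LU": 2.5})) == pytest.approx(2.5)
        assert fluorescence_from_state(net.make_state({"LL": 2.0})) == 0.0
        qm = QuenchModel(residual_quench=0.1)
        assert fluorescence_from_state(net.make_state({"LL": 2.0}), qm) == pytest.approx(0.4)

    def test_free_labelled_monomers_are_fully_fluorescent(self):
        net = dimer_dissociation_network(DimerDissociationParams(k_off=1.0, k_on=1.0))
        assert fluorescence_from_state(net.make_state({"L": 1.5})) == pytest.approx(1.5)

    def test_unknown_species_rejected(self):
        net = dimer_intermediate_network(DimerIntermediateParams(1e-3, 10.0))
        with pytest.raises(SchemaError):
            net.simulate({"XX": 1.0}, [0, 1])


class TestInputValidation:
    def test_nonmonotone_time_grid_rejected(self, calibrated_intermediate):
        with pytest.raises(InputError):
            simulate_intermediate_mechanism(
                calibrated_intermediate, {"LL": 1.0}, [0.0, 2.0, 1.0]
            )

    def test_negative_times_rejected(self, calibrated_intermediate):
        with pytest.raises(InputError):
            simulate_intermediate_mechanism(
                calibrated_intermediate, {"LL": 1.0}, [-1.0, 1.0]
            )

    def test_negative_rates_rejected(self):
        with pytest.raises(DomainError):
            DimerIntermediateParams(k_assoc=-1.0, k_resolve=1.0)
        with pytest.raises(DomainError):
            SwapKernelParams(n=1, k_swap=1.0)

    def test_kd_consistency(self):
        params = DimerDissociationParams.from_kd(k_off=0.5, K_D=1e-4)
        assert params.K_D == pytest.approx(params.k_off / params.k_on, rel=1e-12)


class TestGillespieOracle:
    def test_seeded_runs_are_bit_identical(self, calibrated_intermediate):
        kw = dict(
            init={"LL": 1.0, "UU": 10.0},
            volume=100.0,
            seed=42,
            t_end=30.0,
            record_times=np.linspace(0, 30, 6),
        )
        a = gillespie_oracle(calibrated_intermediate, **kw)
        b = gillespie_oracle(calibrated_intermediate, **kw)
        assert np.array_equal(a.concentrations, b.concentrations)

    def test_zero_rate_never_fires(self):
        traj = gillespie_oracle(
            DimerIntermediateParams(k_assoc=0.0, k_resolve=0.0),
            {"LL": 1.0, "UU": 10.0},
            volume=100.0,
            seed=1,
            t_end=10.0,
        )
        assert np.max(np.abs(traj.concentrations - traj.concentrations[0])) == 0

    def test_stochastic_mean_matches_ode(self, calibrated_intermediate):
        """Mean of 200 SSA runs agrees with the ODE trajectory to within
        3x the Monte-Carlo standard error at 5 checkpoints."""
        grid = np.linspace(0, 30, 6)[1:]  # 5 checkpoints past t=0
        net_traj = simulate_intermediate_mechanism(
            calibrated_intermediate, {"LL": 1.0, "UU": 10.0}, np.linspace(0, 30, 6)
        )
        ode_obs = net_traj.observable[1:]
        runs = np.array(
            [
                gillespie_oracle(
                    calibrated_intermediate,
                    {"LL": 1.0, "UU": 10.0},
                    volume=100.0,
                    seed=1000 + s,
                    t_end=30.0,
                    record_times=grid,
                ).observable
                for s in range(200)
            ]
        )
        mean = runs.mean(axis=0)
        se = runs.std(axis=0, ddof=1) / np.sqrt(runs.shape[0])
        assert np.all(np.abs(mean - ode_obs) <= 3.0 * se)


def test_trajectory_csv_round_trip(tmp_path, calibrated_intermediate):
    import pandas as pd

    traj = simulate_intermediate_mechanism(
        calibrated_intermediate, {"LL": 1.0, "UU": 10.0}, np.linspace(0, 10, 11)
    )
    path = tmp_path / "traj.csv"
    traj.to_csv(path)
    df = pd.read_csv(path)
    assert list(df.columns[:1]) == ["time_min"]
    np.testing.assert_allclose(df["fluorescence_au"], traj.observable, rtol=1e-12)
    np.testing.assert_allclose(df["LU"], traj.concentrations[:, traj.species_ids.index("LU")], rtol=1e-12)
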