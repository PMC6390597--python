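"""Model core: kinetics, trajectories, steady states, conservation."""

import numpy as np
import pytest

from enflux.constants import ACOA_PER_TG
from enflux.model import (
    FLUX_NAMES,
    STATE_NAMES,
    DietSpec,
    MetabolitePools,
    VirtualIndividual,
    build_odes,
    carbon_balance_audit,
    compute_fluxes,
    compute_steady_state,
    simulate_trajectory,
)


def _flux(series, name):
    return float(series[list(FLUX_NAMES).index(name)]) if isinstance(series, np.ndarray) else float(series[name])


class TestActivationHook:
    def test_negative_activation_rejected(self, reference_individual, diet):
        with pytest.raises(ValueError):
            build_odes(reference_individual, diet, f_act=-0.1)

    def test_unit_activation_is_identity(self, reference_individual, diet):
        rhs_base = build_odes(reference_individual, diet)
        rhs_one = build_odes(reference_individual, diet, f_act=1.0)
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.uniform(0.1, 100.0, size=len(STATE_NAMES))
            np.testing.assert_array_equal(rhs_base(0.0, x), rhs_one(0.0, x))

    def test_zero_peripheral_acoa_kills_respiration(self, reference_individual, diet):
        x = reference_individual.initial_state.as_array()
        x[STATE_NAMES.index("acoa_per")] = 0.0
        for f_act in (1.0, 5.0, 100.0):
            j = compute_fluxes(x, reference_individual, diet, f_act)
            assert _flux(j, "resp_per") == 0.0

    def test_activation_scales_peripheral_respiration_linearly(
        self, reference_individual, diet
    ):
        x = reference_individual.initial_state.as_array()
        j1 = compute_fluxes(x, reference_individual, diet, f_act=1.3)
        j2 = compute_fluxes(x, reference_individual, diet, f_act=2.6)
        assert _flux(j2, "resp_per") == pytest.approx(2 * _flux(j1, "resp_per"), rel=1e-12)
        # every other flux is untouched
        mask = [n != "resp_per" for n in FLUX_NAMES]
        np.testing.assert_array_equal(j1[mask], j2[mask])


class TestTrajectory:
    def test_pure_accumulation(self, diet):
        """With all transport/metabolic rates at zero, plasma pools grow
        linearly at the dietary inflow rate."""
        ind = _inert_individual()
        traj = simulate_trajectory(ind, diet)
        t = traj.time
        np.testing.assert_allclose(
            traj.pools["glc_plasma"], diet.carb_intake * t, rtol=1e-6, atol=1e-6
        )
        np.testing.assert_allclose(
            traj.pools["tg_plasma"], diet.fat_intake * t, rtol=1e-6, atol=1e-6
        )

    def test_zero_diet_zero_pools_stays_zero(self):
        ind = _inert_individual()
        empty = DietSpec(0.0, 0.0, 0.0, 0.0)
        traj = simulate_trajectory(ind, empty)
        assert np.all(traj.pools.to_numpy() == 0.0)
        assert np.all(traj.fluxes.drop(columns=["diet_carb", "diet_fat"]).to_numpy() == 0.0)

    def test_grid_and_nonnegativity(self, reference_individual, diet):
        traj = simulate_trajectory(reference_individual, diet)
        assert len(traj.time) == 91
        assert traj.time[0] == 0.0 and traj.time[-1] == 90.0
        assert (traj.pools.to_numpy() >= 0.0).all()
        assert (traj.fluxes.to_numpy() >= 0.0).all()

    def test_carbon_balance_closes(self, reference_individual, diet):
        """Trapezoidal audit: inflow − respiration − turnover loss − Δpools
        vanishes up to daily-grid discretisation error."""
        traj = simulate_trajectory(reference_individual, diet)
        audit = carbon_balance_audit(traj, diet)
        assert abs(audit["relative_error"]) < 1e-2

    def test_carbon_balance_closes_across_cohort(self, reference_trajectories, diet):
        errs = [
            abs(carbon_balance_audit(t, diet)["relative_error"])
            for t in list(reference_trajectories.values())[:20]
        ]
        assert max(errs) < 2e-2
        assert np.median(errs) < 2e-3


class TestSteadyState:
    def test_flux_balance_per_pool(self, reference_individual, diet):
        ss = compute_steady_state(reference_individual, diet)
        assert ss.converged
        f = ss.fluxes
        balances = {
            "glc_plasma": (f["diet_carb"], f["uptake_glc_hep"] + f["uptake_glc_per"]),
            "tg_plasma": (
                f["diet_fat"] + f["vldl_secretion"],
                f["uptake_tg_hep"] + f["uptake_tg_per"],
            ),
            "g6p_hep": (f["uptake_glc_hep"], f["glycolysis_hep"]),
            "acoa_hep": (
                f["glycolysis_hep"] + f["diet_protein_hep"] + ACOA_PER_TG * f["betaox_hep"],
                f["resp_hep"] + f["dnl"],
            ),
            "tg_hep": (
                f["uptake_tg_hep"] + f["dnl"] / ACOA_PER_TG,
                f["betaox_hep"] + f["vldl_secretion"] + f["tg_loss_hep"],
            ),
            "g6p_per": (f["uptake_glc_per"], f["glycolysis_per"]),
            "acoa_per": (
                f["glycolysis_per"] + f["diet_protein_per"] + ACOA_PER_TG * f["betaox_per"],
                f["resp_per"],
            ),
            "tg_per": (f["uptake_tg_per"], f["betaox_per"] + f["tg_loss_per"]),
        }
        for pool, (inflow, outflow) in balances.items():
            rel = abs(inflow - outflow) / max(inflow, 1e-12)
            assert rel <= 1e-6, f"{pool}: {inflow} vs {outflow}"

    def test_independent_of_initial_pools(self, reference_individual, diet):
        ss1 = compute_steady_state(reference_individual, diet)
        x0 = reference_individual.initial_state.as_array() * 3.7 + 1.0
        ss2 = compute_steady_state(reference_individual, diet, x0=x0)
        np.testing.assert_allclose(ss1.pools, ss2.pools, rtol=1e-6, atol=1e-9)

    def test_excess_demand_depletes_peripheral_acoa(self, diet, reference_individual):
        """An activation factor far above the supply bound drains the
        peripheral ACoA pool to the floor and is flagged infeasible."""
        supply = (
            diet.carb_intake
            + ACOA_PER_TG * diet.fat_intake
            + diet.ketogenic_fraction * diet.protein_intake
        )
        floor = 1e-6
        f_act = 10.0 * supply / (reference_individual.k_resp_per * floor)
        ss = compute_steady_state(reference_individual, diet, f_act=f_act)
        assert not ss.converged
        assert ss.pools["acoa_per"] < floor


def _inert_individual():
    zeroed = dict.fromkeys(
        (
            "k_glyc_hep",
            "k_glyc_per",
            "k_boxid_hep",
            "k_boxid_per",
            "k_resp_hep",
            "k_dnl",
            "k_uptake_glc_hep",
            "k_uptake_glc_per",
            "k_uptake_tg_hep",
            "k_uptake_tg_per",
            "k_secr_vldl",
            "k_loss_hep",
            "k_loss_per",
        ),
        0.0,
    )
    return VirtualIndividual(
        id="inert",
        k_resp_per=1.0,  # must be positive; the pool it acts on stays empty
        km_acoa_hep=40.0,
        km_acoa_per=40.0,
        protein_split_hep_per=1.0,  # ketogenic ACoA routed to the (inert) liver
        initial_state=MetabolitePools(0, 0, 0, 0, 0, 0, 0, 0),
        **zeroed,
    )
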