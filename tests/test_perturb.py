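"""Activation experiment: ladder sweep, selection, energy shifts, change maps."""

import numpy as np
import pytest

from enflux.energy import EnergyProfile, energy_profile
from enflux.model import compute_steady_state
from enflux.perturb import (
    DEFAULT_LADDER,
    FactorResult,
    PerturbationResult,
    energy_shift,
    relative_changes,
    run_ladder,
    select_activation,
)


class TestLadder:
    def test_default_ladder_spans_the_scales(self):
        assert len(DEFAULT_LADDER) == 27
        assert DEFAULT_LADDER[0] == 1 + 1e-10
        assert DEFAULT_LADDER[5] == 1 + 1e-2
        assert DEFAULT_LADDER[-4:] == (10.0, 15.0, 20.0, 25.0)
        assert all(b > a for a, b in zip(DEFAULT_LADDER, DEFAULT_LADDER[1:]))
        assert all(f > 1.0 for f in DEFAULT_LADDER)


class TestRunLadder:
    def test_unit_factor_reproduces_baseline(self, reference_individual, diet):
        res = run_ladder(reference_individual, diet, ladder=(1.0,))
        only = res.factors[0]
        assert only.feasible
        np.testing.assert_allclose(
            only.steady_state.pools, res.baseline.pools, rtol=1e-6
        )
        assert only.profile.ee_total == pytest.approx(
            res.baseline_profile.ee_total, rel=1e-6
        )

    def test_total_ee_nondecreasing_along_feasible_ladder(
        self, reference_individual, diet
    ):
        """Re-solve each rung independently and check the EE ordering."""
        res = run_ladder(reference_individual, diet)
        ees = [fr.profile.ee_total for fr in res.factors if fr.feasible]
        assert len(ees) == len(DEFAULT_LADDER)
        assert all(b >= a - 1e-9 for a, b in zip(ees, ees[1:]))
        # independent re-solve (fresh initial state, no warm start)
        check = compute_steady_state(reference_individual, diet, f_act=25.0)
        assert energy_profile(check).ee_total == pytest.approx(ees[-1], rel=1e-6)

    def test_supply_limited_individual_flags_high_factors(
        self, reference_individual, diet
    ):
        """Extreme demand relative to supply drains peripheral ACoA below
        the depletion floor; such rungs are infeasible, not fatal."""
        res = run_ladder(reference_individual, diet, ladder=(2.0, 1e8))
        assert res.factors[0].feasible
        assert not res.factors[-1].feasible
        assert res.factors[-1].profile is None
        assert res.factors[-1].steady_state.pools["acoa_per"] < 1e-6


class TestSelection:
    def _result(self, base_ee, factor_ees, factors=None):
        baseline = EnergyProfile(
            ee_hep=base_ee / 2, ee_per=base_ee / 2,
            substrates_hep=(1, 0, 0), substrates_per=(1, 0, 0),
        )
        frs = []
        for i, ee in enumerate(factor_ees):
            prof = EnergyProfile(
                ee_hep=ee / 2, ee_per=ee / 2,
                substrates_hep=(1, 0, 0), substrates_per=(1, 0, 0),
            )
            frs.append(
                FactorResult(
                    factor=(factors[i] if factors else float(i + 2)),
                    steady_state=None, profile=prof, feasible=True,
                )
            )
        return PerturbationResult(
            individual_id="x", baseline=None, baseline_profile=baseline, factors=frs
        )

    def test_no_feasible_factor_gives_none(self):
        res = PerturbationResult(
            individual_id="x",
            baseline=None,
            baseline_profile=EnergyProfile(6, 6, (1, 0, 0), (1, 0, 0)),
            factors=[FactorResult(2.0, None, None, False)],
        )
        assert select_activation(res) is None

    def test_monotone_gains_select_largest_factor(self):
        res = self._result(10.0, [10.1, 10.5, 11.0])
        assert select_activation(res) == 4.0
        assert res.selected_rel_increase == pytest.approx(0.1)

    def test_below_minimum_increase_gives_none(self):
        res = self._result(10.0, [10.0001, 10.0005])
        assert select_activation(res) is None
        assert res.selected_rel_increase == pytest.approx(5e-5)

    def test_tie_breaks_to_smaller_factor(self):
        res = self._result(10.0, [11.0, 11.0], factors=[3.0, 8.0])
        assert select_activation(res) == 3.0


class TestEnergyShift:
    def test_identical_profiles_shift_nothing(self):
        p = EnergyProfile(5.0, 7.0, (1, 0, 0), (0, 1, 0))
        s = energy_shift(p, p)
        assert (s.delta_ee_per, s.delta_ee_hep, s.delta_ee_total, s.delta_surplus) == (
            0.0, 0.0, 0.0, 0.0,
        )

    def test_additivity_and_surplus_bookkeeping(self):
        a = EnergyProfile(5.0, 7.0, (1, 0, 0), (0, 1, 0))
        b = EnergyProfile(4.2, 9.1, (1, 0, 0), (0, 1, 0))
        s = energy_shift(a, b)
        assert s.delta_ee_total == pytest.approx(s.delta_ee_per + s.delta_ee_hep)
        assert s.delta_surplus == -s.delta_ee_total


class TestChangeMap:
    def test_identity_at_unit_activation(self, reference_individual, diet):
        base = compute_steady_state(reference_individual, diet)
        again = compute_steady_state(
            reference_individual, diet, f_act=1.0, x0=base.pools.to_numpy() * 2.0
        )
        cm = relative_changes(base, again)
        assert np.nanmax(np.abs(cm.to_numpy())) < 1e-6

    def test_halved_pool_reads_minus_half(self, reference_individual, diet):
        base = compute_steady_state(reference_individual, diet)
        import copy

        pert = copy.deepcopy(base)
        pert.pools["tg_per"] *= 0.5
        cm = relative_changes(base, pert)
        assert cm["tg_per"] == pytest.approx(-0.5)

    def test_mismatched_variables_rejected(self, reference_individual, diet):
        base = compute_steady_state(reference_individual, diet)
        import copy

        pert = copy.deepcopy(base)
        pert.pools = pert.pools.rename({"tg_per": "tg_elsewhere"})
        with pytest.raises(ValueError):
            relative_changes(base, pert)


class TestReferenceCohortAudit:
    """Sign structure of the activation response across the seeded cohort."""

    def test_selected_individuals_show_the_reported_shifts(
        self, reference_perturbations, diet
    ):
        assert reference_perturbations, "final subgroup is empty"
        for iid, res in reference_perturbations.items():
            assert res.selected_factor is not None, iid
            assert res.selected_rel_increase >= 1e-3
            s = res.shift
            assert s.delta_ee_per > 0, iid
            assert s.delta_ee_hep <= 0, iid
            assert s.delta_surplus == pytest.approx(-s.delta_ee_total)
            # the surplus shrinks but never flips to a deficit
            surplus = diet.energy_intake - (
                res.baseline_profile.ee_total + s.delta_ee_total
            )
            assert 0 < surplus < diet.energy_intake

    def test_lipid_pools_decrease_with_activation(self, reference_perturbations):
        for iid, res in reference_perturbations.items():
            cm = res.change_map
            assert cm["tg_per"] < 0, iid
            assert cm["tg_plasma"] < 0, iid
            assert cm["resp_per"] > 0, iid
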