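"""Cohort stratification: plausibility, EE window, subgroups, fat criterion."""

import numpy as np
import pytest

from enflux.energy import ee_series, energy_profile
from enflux.model import Trajectory
from enflux.stratify import (
    EEConstraints,
    SubgroupLabel,
    build_envelopes,
    classify_subgroup,
    filter_ee,
    filter_fat_oxidation,
    filter_plausibility,
    stratify_cohort,
)


class TestEEFilter:
    def _grid(self, values):
        return np.asarray(values, dtype=float)

    def test_constant_in_range_passes(self):
        ok, reasons = filter_ee(np.full(91, 12.0))
        assert ok and reasons == []

    def test_constant_above_ceiling_fails(self):
        ok, reasons = filter_ee(np.full(91, 21.0))
        assert not ok
        assert any("overall_max" in r for r in reasons)

    def test_transient_dip_fails_only_overall_minimum(self):
        ee = np.full(91, 12.0)
        ee[50] = 8.0
        ok, reasons = filter_ee(ee)
        assert not ok
        assert len(reasons) == 1 and "overall_min" in reasons[0]

    def test_missing_checkpoint_days_rejected(self):
        with pytest.raises(ValueError):
            filter_ee(np.full(10, 12.0), time=np.arange(10.0))

    def test_four_criteria_against_manual_predicates(self):
        """The filter agrees with evaluating the four predicates by hand on
        a battery of trajectories."""
        c = EEConstraints()
        rng = np.random.default_rng(7)
        for _ in range(50):
            ee = rng.uniform(6.0, 22.0, size=91)
            expected = (
                c.ci_3w[0] <= ee[21] <= c.ci_3w[1]
                and c.ci_10w[0] <= ee[70] <= c.ci_10w[1]
                and ee.min() >= c.overall_min
                and ee.max() < c.overall_max
            )
            assert filter_ee(ee, c)[0] == expected


class TestSubgroups:
    @pytest.mark.parametrize(
        "fraction,label",
        [
            (0.95, SubgroupLabel.P),
            (0.05, SubgroupLabel.H),
            (0.50, SubgroupLabel.PH),
            (0.80, SubgroupLabel.PH),   # boundary: strict inequalities
            (0.20, SubgroupLabel.PH),
        ],
    )
    def test_classification(self, fraction, label):
        assert classify_subgroup(fraction) is label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_subgroup(1.2)

    def test_partition_of_ee_passing_individuals(self, reference_report):
        counts = reference_report.subgroup_counts
        assert sum(counts.values()) == reference_report.n_ee_pass
        assert all(counts[k] > 0 for k in ("P", "H", "PH"))


class TestFatOxidation:
    @pytest.mark.parametrize(
        "fat,expected", [(0.60, True), (0.15, False), (0.57, True)]
    )
    def test_threshold_is_inclusive(self, fat, expected):
        fractions = ((1.0 - fat) * 0.8, fat, (1.0 - fat) * 0.2)
        assert filter_fat_oxidation(fractions) is expected

    def test_fractions_must_normalise(self):
        with pytest.raises(ValueError):
            filter_fat_oxidation((0.5, 0.4, 0.4))


class TestPlausibility:
    def test_reference_cohort_mostly_inside_own_envelopes(
        self, reference_trajectories, reference_envelopes
    ):
        inside = sum(
            filter_plausibility(t, reference_envelopes)[0]
            for t in reference_trajectories.values()
        )
        assert 0.5 * len(reference_trajectories) < inside < len(reference_trajectories)

    def test_violation_names_the_variable(
        self, reference_trajectories, reference_envelopes
    ):
        t = next(iter(reference_trajectories.values()))
        blown = Trajectory(t.individual_id, t.time, t.pools, t.fluxes.copy())
        blown.fluxes["uptake_glc_per"] *= 1000.0
        ok, reasons = filter_plausibility(blown, reference_envelopes)
        assert not ok
        assert any("uptake_glc_per" in r for r in reasons)

    def test_injected_outliers_rejected_at_injection_rate(
        self, reference_trajectories, reference_envelopes
    ):
        """Scale 10% of the clean trajectories far outside the envelopes;
        the rejection count equals the injection count for those."""
        rng = np.random.default_rng(3)
        clean = {
            iid: t
            for iid, t in reference_trajectories.items()
            if filter_plausibility(t, reference_envelopes)[0]
        }
        ids = list(clean)
        n_inject = max(1, len(ids) // 10)
        injected = set(rng.choice(ids, size=n_inject, replace=False))
        rejected = 0
        for iid in ids:
            t = clean[iid]
            if iid in injected:
                t = Trajectory(iid, t.time, t.pools * 20.0, t.fluxes)
            if not filter_plausibility(t, reference_envelopes)[0]:
                rejected += 1
        assert rejected == n_inject


class TestStratifyCohort:
    def test_counts_match_bruteforce_predicate_sweep(
        self, reference_trajectories, reference_envelopes, reference_report
    ):
        """Re-derive every stage count by composing the public predicates
        one individual at a time."""
        n_bio = n_ee = n_fat = 0
        sub = {"P": 0, "H": 0, "PH": 0}
        final = []
        for iid, traj in reference_trajectories.items():
            if not filter_plausibility(traj, reference_envelopes)[0]:
                continue
            n_bio += 1
            if not filter_ee(ee_series(traj), time=traj.time)[0]:
                continue
            n_ee += 1
            profile = energy_profile(traj)
            label = classify_subgroup(profile.peripheral_fraction)
            sub[label.value] += 1
            if label is SubgroupLabel.P and filter_fat_oxidation(profile.substrates_per):
                n_fat += 1
                final.append(iid)
        assert reference_report.n_biomarker_pass == n_bio
        assert reference_report.n_ee_pass == n_ee
        assert reference_report.subgroup_counts == sub
        assert reference_report.n_fat_pass == n_fat
        assert reference_report.final_ids == sorted(final)

    def test_filter_chain_is_monotone(self, reference_report):
        r = reference_report
        assert r.n_input >= r.n_biomarker_pass >= r.n_ee_pass >= r.n_fat_pass
        assert len(r.final_ids) == r.n_fat_pass

    def test_order_invariance(
        self, reference_trajectories, reference_envelopes, reference_report
    ):
        shuffled = stratify_cohort(
            reference_trajectories, reference_envelopes, shuffle_seed=99
        )
        assert shuffled.final_ids == reference_report.final_ids
        assert shuffled.subgroup_counts == reference_report.subgroup_counts

    def test_degenerate_ceiling_empties_the_cohort(
        self, reference_trajectories, reference_envelopes
    ):
        report = stratify_cohort(
            reference_trajectories,
            reference_envelopes,
            EEConstraints(overall_max=0.0),
        )
        assert report.n_ee_pass == 0 and report.final_ids == []
        for flag in report.flags.values():
            if flag.get("ee_pass") is False:
                assert any("overall_max" in r for r in flag["ee_reasons"])

    def test_empty_cohort_rejected(self, reference_envelopes):
        with pytest.raises(ValueError):
            stratify_cohort({}, reference_envelopes)
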