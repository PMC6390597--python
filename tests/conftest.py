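"""Shared fixtures: a hand-built reference individual and the seeded cohort.

The seeded cohort (n=200, seed=1, default hyperparameters) is the study
condition every cohort-level check runs against; it is simulated once per
session.
"""

import pytest

from enflux.cohort import DEFAULT_DIET, CohortHyperparams, generate_cohort
from enflux.model import MetabolitePools, VirtualIndividual, simulate_trajectory
from enflux.perturb import run_ladder, select_activation
from enflux.stratify import build_envelopes, stratify_cohort


@pytest.fixture(scope="session")
def diet():
    return DEFAULT_DIET


@pytest.fixture()
def reference_individual():
    """A deterministic, physiologically sensible virtual individual."""
    return VirtualIndividual(
        id="ref",
        k_glyc_hep=50.0,
        k_glyc_per=50.0,
        k_boxid_hep=0.25,
        k_boxid_per=0.45,
        k_resp_hep=500.0,
        k_resp_per=500.0,
        k_dnl=60.0,
        k_uptake_glc_hep=300.0,
        k_uptake_glc_per=700.0,
        k_uptake_tg_hep=150.0,
        k_uptake_tg_per=700.0,
        k_secr_vldl=0.10,
        k_loss_hep=0.04,
        k_loss_per=0.06,
        km_acoa_hep=40.0,
        km_acoa_per=40.0,
        protein_split_hep_per=0.35,
        # near the individual's steady state, as a developed phenotype
        initial_state=MetabolitePools(
            glc_plasma=9.2,
            tg_plasma=2.7,
            g6p_hep=55.0,
            acoa_hep=17.1,
            tg_hep=1420.0,
            g6p_per=129.0,
            acoa_per=47.0,
            tg_per=3200.0,
        ),
    )


@pytest.fixture(scope="session")
def reference_cohort():
    return generate_cohort(CohortHyperparams(n=200, seed=1))


@pytest.fixture(scope="session")
def reference_trajectories(reference_cohort):
    return {ind.id: simulate_trajectory(ind, DEFAULT_DIET) for ind in reference_cohort}


@pytest.fixture(scope="session")
def reference_envelopes(reference_trajectories):
    return build_envelopes(reference_trajectories)


@pytest.fixture(scope="session")
def reference_report(reference_trajectories, reference_envelopes):
    return stratify_cohort(reference_trajectories, reference_envelopes)


@pytest.fixture(scope="session")
def reference_perturbations(reference_cohort, reference_report):
    """Full ladder runs for a handful of final-subgroup individuals."""
    by_id = {ind.id: ind for ind in reference_cohort}
    out = {}
    for iid in reference_report.final_ids[:4]:
        res = run_ladder(by_id[iid], DEFAULT_DIET)
        select_activation(res)
        out[iid] = res
    return out
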