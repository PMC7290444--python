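import numpy as np
import pytest

import somgait
from somgait import io as gio
from somgait.scores import compute_gvs, gvs_matrix
from somgait.som import SOMTrainConfig, normalize_features, train_som
from somgait.clustering import cluster_som, assign_limbs, select_k

DEFAULT_SEED = 0


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (25 TD children + 5 x 40 CP limbs, seed 0)."""
    cycles, truth = somgait.generate_cohort(somgait.CohortConfig(seed=DEFAULT_SEED))
    return cycles, truth


@pytest.fixture(scope="session")
def cohort_scores(default_cohort):
    """Reference, barefoot GVS vectors and the feature matrix of the cohort."""
    cycles, truth = default_cohort
    barefoot = [c for c in cycles if c.condition == "barefoot"]
    td = [c for c in barefoot if c.cohort == "TD"]
    ref = gio.build_reference(td)
    gvs = [compute_gvs(c, ref) for c in barefoot]
    return {"barefoot": barefoot, "td": td, "ref": ref, "gvs": gvs,
            "matrix": gvs_matrix(gvs), "truth": truth}


@pytest.fixture(scope="session")
def trained_som(cohort_scores):
    z, params = normalize_features(cohort_scores["matrix"])
    model = train_som(z, SOMTrainConfig(seed=DEFAULT_SEED), norm_params=params)
    return model


@pytest.fixture(scope="session")
def sensitivity(trained_som):
    chosen_k, diagnostics = select_k(trained_som, range(2, 11), seed=DEFAULT_SEED)
    return chosen_k, diagnostics


@pytest.fixture(scope="session")
def cohort_assignment(trained_som, cohort_scores, sensitivity):
    chosen_k, _ = sensitivity
    clusters, _ = cluster_som(trained_som, chosen_k, seed=DEFAULT_SEED)
    return assign_limbs(trained_som, clusters, cohort_scores["gvs"])


@pytest.fixture
def small_cycle():
    """A deterministic single TD cycle for unit tests."""
    rng = np.random.default_rng(42)
    curves = {
        v: rng.normal(0.0, 5.0, somgait.N_SAMPLES)
        for v in somgait.KINEMATIC_VARIABLES
    }
    return somgait.GaitCycle(
        limb_id="L1", subject_id="S1", side="left", cohort="TD",
        condition="barefoot", orthosis_type="none", curves=curves,
    )
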