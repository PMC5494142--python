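import numpy as np
import pandas as pd
import pytest

import mircortex as mc


@pytest.fixture(scope="session")
def cohort700():
    """Default synthetic cohort at the study's sample size."""
    return mc.generate_cohort(700, 42)


@pytest.fixture(scope="session")
def small_cohort():
    return mc.generate_cohort(150, 7)


@pytest.fixture(scope="session")
def planted_run():
    """One full run with a planted AD feature among nulls, preprocessed."""
    cohort = mc.generate_cohort(700, 19)
    truth = mc.GroundTruth(seed=19)
    truth.effects["miR-synth-0001"] = ("ad", -0.067)
    raw, bg = mc.generate_mirna_counts(cohort, truth, 60, 19)
    processed, report = mc.preprocess_mirna(raw, bg)
    return {"cohort": cohort, "truth": truth, "raw": raw, "background": bg,
            "processed": processed, "report": report}


def random_matrix(n_feat, n_samp, seed, missing_frac=0.0, state="filtered",
                  feature_class="mirna", low=1.0, high=100.0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(low, high, size=(n_feat, n_samp))
    if missing_frac:
        x[rng.random(x.shape) < missing_frac] = np.nan
    values = pd.DataFrame(
        x, index=[f"f{i}" for i in range(n_feat)],
        columns=[f"s{j}" for j in range(n_samp)])
    return mc.ExpressionMatrix(values=values, feature_class=feature_class,
                               state=state)
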