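import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from xslux import abundance, cross_species, de_stats, homology_integration, synthetic

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_bundle():
    """Default synthetic study (4 species x 2 treatments x 5 replicates) run
    through DE, integration, abundance and baseline estimation once."""
    cfg = synthetic.SimConfig(seed=17)
    truth = synthetic.generate_truth(cfg)
    matrices, samples = synthetic.simulate_counts(truth)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        de = {sp: de_stats.wald_de_test(m, samples) for sp, m in matrices.items()}
        tpms = {sp: abundance.tpm(m) for sp, m in matrices.items()}
        mean_sp = {
            sp: abundance.mean_tpm(tpms[sp], samples, "species") for sp in matrices
        }
        cls = homology_integration.integrate_de_status(
            truth.homology, de, cfg.species
        )
        baseline_groups = cross_species.select_baseline_groups(
            cls, truth.homology, mean_sp, min_tpm=1.0
        )
        baseline = cross_species.pairwise_log2_ratios(
            baseline_groups, truth.homology, mean_sp
        )
    return {
        "cfg": cfg,
        "truth": truth,
        "matrices": matrices,
        "samples": samples,
        "de": de,
        "tpms": tpms,
        "mean_tpm": mean_sp,
        "cls": cls,
        "baseline_groups": baseline_groups,
        "baseline": baseline,
    }


@pytest.fixture()
def small_counts():
    """A tiny two-group count matrix with NB-free structure for unit tests."""
    from xslux.io_formats import CountMatrix

    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.integers(5, 500, size=(40, 8)),
        index=[f"g{i}" for i in range(40)],
        columns=[f"s{j}" for j in range(8)],
    )
    lengths = pd.Series(rng.integers(500, 3000, size=40), index=counts.index)
    return CountMatrix("Xx", counts, lengths)


@pytest.fixture()
def small_samples():
    return pd.DataFrame(
        {
            "sample_id": [f"s{j}" for j in range(8)],
            "species_id": ["Xx"] * 8,
            "treatment": ["HL"] * 4 + ["LL"] * 4,
            "replicate": [1, 2, 3, 4, 1, 2, 3, 4],
        }
    )
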