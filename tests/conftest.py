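import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phyloepi import (
    CalibrationSpec,
    MultipleAlignment,
    calibrate,
    classify_alignment,
    evolve,
    hominid_preset,
    p_distance,
    percent_identity,
    recode_alignment,
    rf_distance,
    upgma,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_alignment() -> MultipleAlignment:
    """Three taxa, one consistent CpG, one variable CpG, one SNP column."""
    return MultipleAlignment(
        taxa=("t1", "t2", "t3"),
        rows=("CGCGTA", "CGTGTA", "CGCGTT"),
    )


@pytest.fixture(scope="session")
def hominid_runs():
    """The 10-replicate hominid recovery study (seeds 1..10), shared.

    Each entry: dict with the simulation result, site classification,
    recoded-matrix UPGMA tree, genetic UPGMA tree, identity matrix and
    the calibrated human-chimp divergence age.
    """
    runs = []
    for seed in range(1, 11):
        result = evolve(hominid_preset(seed=seed))
        sc = classify_alignment(result.alignment)
        t_epi = upgma(p_distance(recode_alignment(sc)))
        t_gen = upgma(p_distance(result.alignment))
        pid = percent_identity(result.alignment)
        cal = calibrate(t_epi, CalibrationSpec("chimp", "bonobo", 1.7))
        hc_age = cal.heights()[cal.mrca(["human", "chimp"])]
        runs.append(
            {
                "seed": seed,
                "result": result,
                "sc": sc,
                "tree_epi": t_epi,
                "tree_gen": t_gen,
                "identity": pid,
                "rf_epi_truth": rf_distance(t_epi, result.true_tree),
                "hc_age": hc_age,
            }
        )
    return runs


def random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Symmetric matrix with distinct positive off-diagonal entries."""
    v = np.zeros((n, n))
    upper = rng.uniform(0.1, 10.0, size=n * (n - 1) // 2)
    iu = np.triu_indices(n, k=1)
    v[iu] = upper
    v.T[iu] = upper
    return v
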