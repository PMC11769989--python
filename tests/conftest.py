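import numpy as np
import pandas as pd
import pytest

import corhythm as cr

MOUSE_ZT = np.repeat([2.0, 6.0, 10.0, 14.0, 18.0, 22.0], 5)


@pytest.fixture(scope="session")
def mouse_grid():
    """Sample times of the balanced 6-timepoint mouse design (n=5/ZT)."""
    return MOUSE_ZT.copy()


@pytest.fixture(scope="session")
def small_study():
    """A small two-species study with known ground truth (seed 11)."""
    cfg = cr.SimulationConfig(n_genes=400, seed=11)
    return cr.generate_study(cfg)


@pytest.fixture(scope="session")
def fitted_small_study(small_study):
    """Normalized fits per group for the small study."""
    expr, samples, truth = small_study
    results = {}
    for sp in ("mouse", "human"):
        ss = samples.select(species=sp)
        sc = expr.subset_samples(ss.sample_ids)
        norm, kept = cr.preprocess.preprocess_species(sc, ss)
        for g in ss.groups():
            results[g] = cr.fit_group(norm, ss, g)
    return results


def tiny_counts(values, genes=None, samples=None, **kw):
    genes = genes or [f"g{i + 1}" for i in range(len(values))]
    samples = samples or [f"s{j + 1}" for j in range(len(values[0]))]
    return cr.ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), **kw
    )
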