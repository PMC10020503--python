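import numpy as np
import pandas as pd
import pytest

from herbsurv.synthetic_claims import (
    GeneratorConfig,
    HerbProduct,
    PlantedPair,
    generate_bundle,
)


@pytest.fixture(scope="session")
def small_bundle():
    """A 1,500-patient bundle with planted traffic in every exclusion bin."""
    cfg = GeneratorConfig(n_patients=1500, seed=20240901)
    return generate_bundle(cfg)


@pytest.fixture(scope="session")
def small_cohort(small_bundle):
    from herbsurv.cohort_builder import build_cohort

    cohort, tally = build_cohort(small_bundle)
    return cohort, tally


@pytest.fixture
def tiny_catalog():
    return (
        HerbProduct("AA", "single_herb", 0.05, 1.0),
        HerbProduct("BB", "single_herb", 0.05, 2.0),
    )


@pytest.fixture
def toy_events():
    """Hand-written diagnosis events for the visit-rule operations."""

    def make(rows):
        return pd.DataFrame(rows, columns=["date", "setting", "code"])

    return make


def brute_force_pair_counts(product_sets):
    """Independent oracle: nested-loop marginal and pair tallies."""
    from collections import Counter

    marginal, joint = Counter(), Counter()
    for prods in product_sets:
        items = sorted(set(prods))
        for i, a in enumerate(items):
            marginal[a] += 1
            for b in items[i + 1:]:
                joint[(a, b)] += 1
    return marginal, joint
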