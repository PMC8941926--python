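import numpy as np
import pandas as pd
import pytest

from phyllodyn import synth
from phyllodyn.data_model import (
    RANKS,
    UNKNOWN,
    FeatureTable,
    SampleMetadata,
    TaxonomyTable,
)


@pytest.fixture(scope="session")
def tiny_data():
    """One small synthetic data set with ground truth (desk-test scale)."""
    return synth.generate(synth.preset("tiny"), seed=0)


@pytest.fixture(scope="session")
def paper_data():
    """One study-scale synthetic data set with ground truth."""
    return synth.generate(synth.preset("paper_like"), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_table(rng, n_features=10, n_samples=6, lam=20.0, prefix="F"):
    counts = rng.poisson(lam, size=(n_features, n_samples))
    return FeatureTable(
        pd.DataFrame(
            counts,
            index=[f"{prefix}{i}" for i in range(n_features)],
            columns=[f"S{j}" for j in range(n_samples)],
        )
    )


def flat_taxonomy(feature_ids, genus=None):
    """Uniform all-bacterial taxonomy for a list of features."""
    rows = {
        f: ("Bacteria", "P", "C", "O", "Fam", genus or f"G_{f}") for f in feature_ids
    }
    return TaxonomyTable(
        pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    )


def simple_metadata(sample_ids, compartment="leaf", trees=None, days=None,
                    city="Antwerp", land_use="park", blanks=()):
    rows = {}
    for i, s in enumerate(sample_ids):
        rows[s] = dict(
            city=city,
            tree_id=trees[i] if trees else "T1",
            compartment=compartment,
            collection_date="2018-04-24",
            days_since_emergence=float(days[i]) if days is not None else 7.0,
            land_use=land_use,
            is_blank=False,
        )
    for b in blanks:
        rows[b] = dict(
            city=city, tree_id=np.nan, compartment=np.nan, collection_date=np.nan,
            days_since_emergence=np.nan, land_use=np.nan, is_blank=True,
        )
    return SampleMetadata(pd.DataFrame.from_dict(rows, orient="index"),
                          validate=False)
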