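import numpy as np
import pytest

from ifncomp import GeneSetDesign, feature_table, generate_gene_set


@pytest.fixture(scope="session")
def small_gene_set():
    """A 30+30+30 synthetic interferome with default effect sizes."""
    design = GeneSetDesign(n_isg=30, n_irg=30, n_random=30, seed=20240)
    records, de_table, labels, manifest = generate_gene_set(design)
    return {
        "design": design,
        "records": records,
        "de_table": de_table,
        "labels": labels,
        "manifest": manifest,
    }


@pytest.fixture(scope="session")
def small_features(small_gene_set):
    X = feature_table(small_gene_set["records"])
    y = np.array([small_gene_set["labels"][g] for g in X.index])
    return X, y


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))
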