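import numpy as np
import pandas as pd
import pytest

from bltsub.io import ExpressionMatrix, SubtypeLabelSet
from bltsub.pipeline import run_pipeline
from bltsub.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (100/85/15, delta=2, sigma=1, seed=17)."""
    return generate_cohort(SyntheticConfig())


@pytest.fixture(scope="session")
def pipeline_result():
    """Full pipeline run on the default cohort; shared across modules."""
    return run_pipeline(SyntheticConfig())


@pytest.fixture(scope="session")
def small_cohort():
    """A quick cohort for CLI and error-path tests."""
    return generate_cohort(SyntheticConfig(n_luminal=30, n_basal=25, n_double_negative=5,
                                           n_background_genes=50, seed=5))


def make_matrix(values: np.ndarray, scale: str = "log_median_normalized",
                genes=None, samples=None) -> ExpressionMatrix:
    """Wrap a raw array as an ExpressionMatrix with synthetic identifiers."""
    g, s = values.shape
    genes = genes if genes is not None else [f"G{i:03d}" for i in range(g)]
    samples = samples if samples is not None else [f"S{i:03d}" for i in range(s)]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), scale=scale)


def make_labels(mapping: dict[str, str], provenance: str = "truth") -> SubtypeLabelSet:
    return SubtypeLabelSet(pd.Series(mapping), provenance=provenance)
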