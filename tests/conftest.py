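import numpy as np
import pandas as pd
import pytest

from mirsynergy.simulate import (
    AnnotationBundle,
    ExpressionMatrix,
    SimulationConfig,
    simulate_annotations,
    simulate_expression,
)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    """The study-default simulation profile (830 miRNAs, 6 pairs, seed 42)."""
    return SimulationConfig(seed=42)


@pytest.fixture(scope="session")
def default_expr(default_config) -> ExpressionMatrix:
    return simulate_expression(default_config)


@pytest.fixture(scope="session")
def default_bundle(default_config) -> AnnotationBundle:
    return simulate_annotations(default_config, seed=42)


@pytest.fixture()
def small_expr() -> ExpressionMatrix:
    """A fast 40-miRNA cohort for IO and pipeline tests."""
    return simulate_expression(SimulationConfig(n_mirnas=40, n_up=6, n_down=5, seed=7))


def make_expression(values: np.ndarray, mirnas: list[str],
                    classes: list[str], pairs: list[str]) -> ExpressionMatrix:
    """Hand-build an ExpressionMatrix from an array and per-sample labels."""
    sample_ids = [f"{c}_{p}" for c, p in zip(classes, pairs)]
    frame = pd.DataFrame(values, index=pd.Index(mirnas, name="mirna"), columns=sample_ids)
    samples = pd.DataFrame(
        {"tissue_class": classes, "pair_id": pairs},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ExpressionMatrix(values=frame, samples=samples)
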