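import numpy as np
import pandas as pd
import pytest

from cellascribe import ExpressionMatrix, SampleAnnotation, SectionFractions


def make_matrix(values, probe_ids=None, sample_ids=None, scale="log2"):
    values = np.asarray(values, dtype=float)
    probe_ids = probe_ids or [f"P{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=probe_ids, columns=sample_ids), scale)


def make_annotation(sample_id, group, t, s, a, n_sections=1):
    return SampleAnnotation(sample_id, group, [SectionFractions(t, s, a)] * n_sections)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed cohort with planted compartment effects (session-cached)."""
    from cellascribe import SimulationConfig, generate_cohort

    cfg = SimulationConfig(
        n_dm=20, n_nodm=20, n_genes=400, n_de_tumor=20, n_de_stroma=20,
        n_de_shared=10, effect_log2=2.0, seed=424242,
    )
    return generate_cohort(cfg)
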