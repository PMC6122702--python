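import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from mimicmap.io_formats import ExpressionDataset  # noqa: E402
from mimicmap.synthetic import GeneratorConfig, generate  # noqa: E402


def make_dataset(rng, n_probes=50, n_per_group=4, dataset_id="DS1",
                 groups=("A", "B"), shift=None):
    """Small random ExpressionDataset for unit tests."""
    samples = [f"{g}{i}" for g in groups for i in range(n_per_group)]
    values = rng.normal(8.0, 1.0, size=(n_probes, len(samples)))
    if shift is not None:
        values[:, :n_per_group] += shift[:, None]
    probes = [f"p{i:03d}" for i in range(n_probes)]
    frame = pd.DataFrame(values, index=pd.Index(probes, name="probe_id"),
                         columns=samples)
    return ExpressionDataset(
        dataset_id=dataset_id, platform_id="SIMPLAT",
        values=frame,
        probe_to_gene={p: f"GENE{i:03d}" for i, p in enumerate(probes)},
        sample_groups={s: (groups[0] if s.startswith(groups[0]) else groups[1])
                       for s in samples})


@pytest.fixture(scope="session")
def small_bundle():
    """Shared small synthetic instance (cheap, deterministic)."""
    return generate(GeneratorConfig(n_genes=300, seed=11))


@pytest.fixture(scope="session")
def study_bundle():
    """The study-condition instance: 2000 genes, 3 cell-line + 4 tumour
    datasets, effect 3 noise SDs, 10 samples/group, seed 42."""
    return generate(GeneratorConfig(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
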