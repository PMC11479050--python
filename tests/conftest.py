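import numpy as np
import pytest

from tonus import pipeline, synth


@pytest.fixture(scope="session")
def tiny_cfg() -> pipeline.RunConfig:
    return pipeline.make_fixture("tiny", seed=7)


@pytest.fixture(scope="session")
def tiny_sessions(tiny_cfg):
    return synth.generate_cohort(tiny_cfg.generator)


@pytest.fixture(scope="session")
def tiny_table(tiny_cfg, tiny_sessions):
    return pipeline.cohort_feature_table(tiny_sessions, tiny_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_toy_table(
    n_per_class: int = 10,
    separation: float = 8.0,
    noise: float = 0.5,
    seed: int = 0,
    permute_labels: bool = False,
):
    """Labeled table with the full 22-column schema and four Gaussian
    clusters: every fourth column carries one class's offset, so the
    separation survives per-column standardization."""
    import pandas as pd

    from tonus.classify import CLASS_ORDER, FEATURE_COLUMNS

    rng = np.random.default_rng(seed)
    n_cols = len(FEATURE_COLUMNS)
    rows, labels = [], []
    for k, cls in enumerate(CLASS_ORDER):
        center = np.where(np.arange(n_cols) % 4 == k, separation, 0.0)
        for _ in range(n_per_class):
            rows.append(center + rng.normal(0.0, noise, n_cols))
            labels.append(cls)
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    if permute_labels:
        labels = list(rng.permutation(labels))
    df["label"] = labels
    df.index = pd.Index(
        [f"S{i:03d}" for i in range(len(df))], name="subject_id"
    )
    return df
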