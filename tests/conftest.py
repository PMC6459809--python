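import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import braincoex as bc

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_dataset(x: np.ndarray, genotypes, regions,
                 detection: np.ndarray | None = None) -> bc.ExpressionDataset:
    """Wrap a raw array as an ExpressionDataset with minimal metadata."""
    genes = [f"g{i}" for i in range(x.shape[0])]
    samples = [f"s{i}" for i in range(x.shape[1])]
    meta = pd.DataFrame({"genotype": list(genotypes),
                         "region": list(regions)}, index=samples)
    det = None
    if detection is not None:
        det = pd.DataFrame(detection, index=genes, columns=samples)
    return bc.ExpressionDataset(
        values=pd.DataFrame(x, index=genes, columns=samples),
        metadata=meta, detection=det)


def two_group_dataset(x1: np.ndarray, x2: np.ndarray,
                      region: str = "R") -> bc.ExpressionDataset:
    """Selected vs control dataset for a single region."""
    x = np.hstack([x1, x2])
    genotypes = ["selected"] * x1.shape[1] + ["control"] * x2.shape[1]
    return make_dataset(x, genotypes, [region] * x.shape[1])


@pytest.fixture(scope="session")
def benchmark_data():
    """The standard synthetic benchmark dataset plus its ground truth."""
    config = bc.benchmark_config(seed=0)
    ds, truth = bc.generate_dataset(config)
    return config, ds, truth


@pytest.fixture(scope="session")
def benchmark_network(benchmark_data):
    """Similarity, soft threshold, adjacency, TOM and detected modules on
    the standard benchmark (shared across tests: the dense matrices are
    the expensive part of the suite)."""
    _, ds, truth = benchmark_data
    s = bc.signed_similarity(ds.values)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pick = bc.pick_soft_threshold(s)
    a = bc.adjacency(s, pick.beta)
    tom = bc.topological_overlap(a)
    det = bc.detect_modules(tom, min_module_size=80, cut_height=0.995,
                            deep_split=True)
    return {"similarity": s, "pick": pick, "adjacency": a, "tom": tom,
            "detection": det, "ds": ds, "truth": truth}


def majority_map(labels: pd.Series, truth: bc.GroundTruth) -> dict[str, str]:
    """Detected module color -> planted module id by majority overlap."""
    planted = pd.Series(truth.gene_module)[labels.index]
    out = {}
    for color in labels.unique():
        if color == "grey":
            continue
        out[color] = planted[labels.index[labels == color]].mode().iloc[0]
    return out
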