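import numpy as np
import pandas as pd
import pytest

import rankatlas as ra


@pytest.fixture(scope="session")
def bulk_cohort():
    """Default simulated multi-platform cohort with ground truth."""
    cfg = ra.SimConfig(seed=0)
    matrix, samples, truth = ra.simulate_bulk(cfg)
    return cfg, matrix, samples, truth


@pytest.fixture(scope="session")
def built(bulk_cohort):
    """Rank matrix, gene stats and fitted atlas for the default cohort."""
    _, matrix, samples, _ = bulk_cohort
    ranks = ra.rank_transform(matrix)
    stats = ra.filter_genes(ranks, samples)
    model = ra.build_atlas(ranks, samples, stats)
    return {"ranks": ranks, "stats": stats, "model": model, "samples": samples,
            "matrix": matrix}


@pytest.fixture(scope="session")
def holdout():
    """Cohort with a third platform held out of training for identity recovery."""
    cfg = ra.SimConfig(seed=0, n_datasets=6, n_platforms=3)
    matrix, samples, truth = ra.simulate_bulk(cfg)
    train_ids = samples.data.index[samples.data.platform != "platform2"]
    test_ids = samples.data.index[samples.data.platform == "platform2"]
    train_ranks = ra.rank_transform(matrix.select_samples(train_ids))
    train_samples = samples.select(train_ids)
    stats = ra.filter_genes(train_ranks, train_samples)
    model = ra.build_atlas(train_ranks, train_samples, stats)
    centroids = ra.build_centroids(model, ranks=train_ranks)
    return {"cfg": cfg, "matrix": matrix, "samples": samples, "truth": truth,
            "test_ids": test_ids, "model": model, "centroids": centroids,
            "train_ranks": train_ranks, "train_samples": train_samples}


@pytest.fixture()
def tiny_rank_matrix():
    """A 4-gene x 4-sample rank matrix with clean structure."""
    vals = pd.DataFrame(
        {
            "s1": [0.125, 0.375, 0.625, 0.875],
            "s2": [0.375, 0.125, 0.625, 0.875],
            "s3": [0.875, 0.625, 0.375, 0.125],
            "s4": [0.625, 0.875, 0.125, 0.375],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    return ra.ExpressionMatrix(vals, "rank")
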