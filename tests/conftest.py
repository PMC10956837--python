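import warnings

import numpy as np
import pytest

from hyperdti import evaluation, hierarchy, model, synthdata


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_lorentz_points(rng, n, d, beta=1.0, scale=1.0):
    """Random on-manifold points via the origin exponential map."""
    from hyperdti import geometry

    v = rng.normal(0.0, scale, size=(n, d))
    return geometry.exp_map_origin(v, beta)


@pytest.fixture(scope="session")
def default_benchmark():
    """The standard synthetic study: data, trees and LCA distance matrices."""
    data, dtree, ttree = synthdata.generate_benchmark(synthdata.SynthConfig(seed=0))
    dd = hierarchy.lca_distance_matrix(dtree)
    td = hierarchy.lca_distance_matrix(ttree)
    return data, dtree, ttree, dd, td


@pytest.fixture(scope="session")
def small_benchmark():
    """A fast benchmark for training smoke tests (small trees, few pairs)."""
    cfg = synthdata.SynthConfig(
        branching_drugs=(3, 2, 2, 1, 1),
        branching_targets=(3, 2, 2),
        n_drugs=36,
        n_targets=12,
        feature_dim=40,
        sparsity=0.2,
        seed=3,
    )
    data, dtree, ttree = synthdata.generate_benchmark(cfg)
    dd = hierarchy.lca_distance_matrix(dtree)
    td = hierarchy.lca_distance_matrix(ttree)
    return data, dtree, ttree, dd, td


@pytest.fixture(scope="session")
def default_training_runs(default_benchmark):
    """Models trained under the standard schedule on the default benchmark:
    regularized and unregularized Lorentz heads plus a regularized Euclidean
    head, with held-out-fold AUCs and in-sample target-hierarchy EDP."""
    data, dtree, ttree, dd, td = default_benchmark
    xd, xt = data.feature_arrays()
    split = evaluation.crossval_split(data, 5, np.random.default_rng(0))
    train_idx, test_idx = split.split(0)
    runs = {}
    for name, head, lam in (
        ("lorentz_reg", "lorentz_distance", 0.1),
        ("lorentz_unreg", "lorentz_distance", 0.0),
        ("euclidean_reg", "euclidean_dot", 0.1),
    ):
        m, trace = model.train_model(
            data, dd, td, head=head,
            train_cfg=model.TrainingConfig(lambda_drug=lam, lambda_target=lam, seed=1),
            train_idx=train_idx,
        )
        scores = m.predict(xd[data.pairs[test_idx, 0]], xt[data.pairs[test_idx, 1]])
        rocauc, prauc = evaluation.binary_aucs(data.labels[test_idx], scores)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # leaf level has no same-class pair
            edp_target = evaluation.latent_edp(m, data, ttree, "target", k=10, rng=np.random.default_rng(7))
            edp_drug = evaluation.latent_edp(m, data, dtree, "drug", k=10, rng=np.random.default_rng(7))
        runs[name] = {
            "model": m, "trace": trace, "rocauc": rocauc, "prauc": prauc,
            "edp_target": edp_target, "edp_drug": edp_drug,
        }
    return runs


def small_train_cfg(**kw):
    defaults = dict(epochs=6, batch_interactions=256, learning_rate=1e-3, n_anchors=4, m_negatives=16, seed=5)
    defaults.update(kw)
    return model.TrainingConfig(**defaults)


def small_encoder_cfg(input_dim, latent_dim=4):
    return model.EncoderConfig(input_dim, hidden=(32, 32), dropout=0.1, latent_dim=latent_dim)
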