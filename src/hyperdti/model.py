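"""Pairwise drug-target interaction model with hierarchy regularization.

Two feed-forward encoders map precomputed drug and target feature vectors
into a shared latent space. Two prediction heads are supported:

* ``euclidean_dot`` — interaction probability ``sigmoid(<d, t>)`` between
  the raw latent vectors;
* ``lorentz_distance`` — latents are norm-clipped (threshold ``alpha``),
  pushed onto the hyperboloid ``<x,x>_L = -beta`` with the origin
  exponential map, and scored ``exp(-d_L^2(d, t))`` with the squared
  Lorentzian distance.

The objective combines a class-weighted binary cross-entropy over labeled
interactions with a ranking regularizer per modality: for sampled hierarchy
anchors, the latent distance to a hierarchy-nearby positive is pushed below
the distances to hierarchy-farther negatives,

    L_reg = sum_i [ d(x_i, x_i+) + log sum_k exp(-d(x_i, x_k)) ],

weighted by ``lambda_drug`` / ``lambda_target`` in the total loss. Training
uses Adam on Xavier-initialized weights and is reproducible from the seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy.special import logsumexp as _np_logsumexp

from . import geometry
from ._autodiff import Tensor, concat
from ._nn import MLP, Adam
from .hierarchy import HierarchyDistanceMatrix, RegularizationBatch, sample_regularization_batch
from .workbench import InteractionSet

__all__ = [
    "EncoderConfig",
    "TrainingConfig",
    "TrainingBatch",
    "DTIModel",
    "predict_interaction",
    "weighted_bce",
    "hierarchy_reg_loss",
    "total_loss",
    "sample_training_batch",
    "train_model",
]

_EPS = 1e-12
_CLAMP = 1e-7


@dataclass
class EncoderConfig:
    """Architecture of one feature encoder (drug or target)."""

    input_dim: int
    hidden: tuple = (1024, 1024)
    dropout: float = 0.10
    latent_dim: int = 8

    def __post_init__(self):
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class TrainingConfig:
    """Optimization schedule and loss weighting.

    Defaults follow the standard configuration: 16 epochs, interaction
    batches of 1024, Adam at 5e-5, n = 10 hierarchy anchors with up to
    m = 256 negatives per batch and modality. ``pos_weight:neg_weight``
    offsets class imbalance (e.g. 2:1 for a negatives-heavy panel, 1:2 for
    a positives-heavy one). ``include_positive`` optionally adds the
    positive's term to the ranking denominator (softmax form); the default
    keeps negatives only.
    """

    epochs: int = 16
    batch_interactions: int = 1024
    learning_rate: float = 5e-5
    pos_weight: float = 1.0
    neg_weight: float = 1.0
    lambda_drug: float = 0.1
    lambda_target: float = 0.1
    n_anchors: int = 10
    m_negatives: int = 256
    include_positive: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("epochs", "batch_interactions", "learning_rate", "pos_weight", "neg_weight", "n_anchors"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lambda_drug < 0 or self.lambda_target < 0 or self.m_negatives < 0:
            raise ValueError("lambda weights and m_negatives must be non-negative")


@dataclass
class TrainingBatch:
    """One optimizer step's worth of data: interaction rows plus, per
    modality, an anchor/positive/negatives hierarchy batch (``None`` when
    the modality is unregularized)."""

    interaction_idx: np.ndarray
    drug_reg: RegularizationBatch | None = None
    target_reg: RegularizationBatch | None = None


class DTIModel:
    """Two encoders plus a prediction head over the shared latent space."""

    HEADS = ("euclidean_dot", "lorentz_distance")

    def __init__(
        self,
        drug_cfg: EncoderConfig,
        target_cfg: EncoderConfig,
        head: str = "lorentz_distance",
        alpha: float = 1.0,
        beta: float = 1.0,
        rng: np.random.Generator | None = None,
    ):
        if head not in self.HEADS:
            raise ValueError(f"head must be one of {self.HEADS}")
        if drug_cfg.latent_dim != target_cfg.latent_dim:
            raise ValueError("drug and target encoders must share latent_dim")
        if alpha <= 0 or beta <= 0:
            raise ValueError("alpha and beta must be positive")
        rng = rng or np.random.default_rng()
        self.head = head
        self.alpha = float(alpha)
        self.beta = float(beta)
        self.drug_cfg, self.target_cfg = drug_cfg, target_cfg
        self.drug_encoder = MLP(drug_cfg.input_dim, tuple(drug_cfg.hidden), drug_cfg.latent_dim, drug_cfg.dropout, rng)
        self.target_encoder = MLP(target_cfg.input_dim, tuple(target_cfg.hidden), target_cfg.latent_dim, target_cfg.dropout, rng)

    # ---- differentiable forward pieces ----------------------------------
    def _lorentz_metric(self, d_plus_1: int) -> Tensor:
        g = np.ones(d_plus_1, dtype=np.float32)
        g[0] = -1.0
        return Tensor(g)

    def _to_manifold_t(self, u: Tensor) -> Tensor:
        """Clip latent norms to ``alpha`` then exp-map onto the hyperboloid."""
        n = ((u * u).sum(axis=1, keepdims=True) + _EPS).sqrt()
        u = u * (self.alpha / n).clamp(hi=1.0)
        sb = float(np.sqrt(self.beta))
        r = ((u * u).sum(axis=1, keepdims=True) + _EPS).sqrt()
        x0 = (r * (1.0 / sb)).cosh() * sb
        rest = (r * (1.0 / sb)).sinh() * sb / r * u
        return concat([x0, rest], axis=1)

    def _latents_t(self, xd, xt, train: bool, rng) -> tuple:
        zd = self.drug_encoder(xd, train=train, rng=rng)
        zt = self.target_encoder(xt, train=train, rng=rng)
        if self.head == "lorentz_distance":
            zd, zt = self._to_manifold_t(zd), self._to_manifold_t(zt)
        return zd, zt

    def _pair_probs_t(self, zd: Tensor, zt: Tensor) -> Tensor:
        if self.head == "euclidean_dot":
            return (zd * zt).sum(axis=1).sigmoid()
        g = self._lorentz_metric(zd.shape[1])
        inner = (zd * zt * g).sum(axis=1)
        d2 = ((-2.0 * self.beta) - 2.0 * inner).clamp(lo=0.0)
        return (d2 * -1.0).exp()

    def _sq_dists_t(self, za: Tensor, zb: Tensor) -> Tensor:
        """Latent-space distance used by the ranking regularizer.

        Squared Lorentzian distance for the hyperbolic head; Euclidean
        distance between raw latents for the dot-product head (the inner
        product itself is not a distance).
        """
        if self.head == "lorentz_distance":
            g = self._lorentz_metric(za.shape[1])
            inner = (za * zb * g).sum(axis=1)
            return ((-2.0 * self.beta) - 2.0 * inner).clamp(lo=0.0)
        return (((za - zb) ** 2).sum(axis=1) + _EPS).sqrt()

    # ---- inference -------------------------------------------------------
    def encode_drugs(self, x) -> np.ndarray:
        """Latent drug embeddings (deterministic, dropout off).

        Hyperboloid points of shape ``(n, latent_dim + 1)`` for the Lorentz
        head, raw latents of shape ``(n, latent_dim)`` otherwise.
        """
        z = self.drug_encoder(np.asarray(x, dtype=np.float32))
        if self.head == "lorentz_distance":
            z = self._to_manifold_t(z)
        return z.data.astype(float)

    def encode_targets(self, x) -> np.ndarray:
        z = self.target_encoder(np.asarray(x, dtype=np.float32))
        if self.head == "lorentz_distance":
            z = self._to_manifold_t(z)
        return z.data.astype(float)

    def predict(self, xd, xt) -> np.ndarray:
        """Interaction probabilities for row-aligned feature matrices."""
        xd, xt = np.atleast_2d(xd), np.atleast_2d(xt)
        if xd.shape[1] != self.drug_cfg.input_dim or xt.shape[1] != self.target_cfg.input_dim:
            raise ValueError("feature dimension does not match encoder input_dim")
        if xd.shape[0] != xt.shape[0]:
            raise ValueError("need one target row per drug row")
        zd, zt = self._latents_t(xd.astype(np.float32), xt.astype(np.float32), train=False, rng=None)
        return self._pair_probs_t(zd, zt).data.astype(float)

    def latent_distance_matrix(self, z: np.ndarray) -> np.ndarray:
        """Pairwise latent distances (head-matched) for clustering/EDP."""
        z = np.asarray(z, dtype=float)
        if self.head == "lorentz_distance":
            inner = geometry.lorentz_inner(z[:, None, :], z[None, :, :])
            d = np.maximum(-2.0 * self.beta - 2.0 * inner, 0.0)
        else:
            diff = z[:, None, :] - z[None, :, :]
            d = np.sqrt(np.sum(diff * diff, axis=-1))
        np.fill_diagonal(d, 0.0)
        return (d + d.T) / 2.0

    # ---- serialization ---------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "head": self.head,
            "alpha": self.alpha,
            "beta": self.beta,
            "drug_cfg": asdict(self.drug_cfg),
            "target_cfg": asdict(self.target_cfg),
            "format_version": 1,
        }
        arrays = {f"drug__{k}": v for k, v in self.drug_encoder.state_dict().items()}
        arrays |= {f"target__{k}": v for k, v in self.target_encoder.state_dict().items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "DTIModel":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["__meta__"]).decode())
            arrays = {k: npz[k] for k in npz.files if k != "__meta__"}
        for cfg in (meta["drug_cfg"], meta["target_cfg"]):
            cfg["hidden"] = tuple(cfg["hidden"])
        model = cls(
            EncoderConfig(**meta["drug_cfg"]),
            EncoderConfig(**meta["target_cfg"]),
            head=meta["head"],
            alpha=meta["alpha"],
            beta=meta["beta"],
            rng=np.random.default_rng(0),
        )
        model.drug_encoder.load_state_dict({k.split("__", 1)[1]: v for k, v in arrays.items() if k.startswith("drug__")})
        model.target_encoder.load_state_dict({k.split("__", 1)[1]: v for k, v in arrays.items() if k.startswith("target__")})
        return model


def predict_interaction(model: DTIModel, drug_features, target_features) -> float:
    """Interaction probability for a single (drug, target) feature pair."""
    return float(model.predict(np.atleast_2d(drug_features), np.atleast_2d(target_features))[0])


def weighted_bce(predictions, labels, pos_weight: float = 1.0, neg_weight: float = 1.0) -> float:
    """Class-weighted binary cross-entropy, mean over samples.

    ``labels`` may be {0,1} or signed {-1,+1}. Predictions are clamped to
    ``[1e-7, 1 - 1e-7]`` before the logs.
    """
    p = np.clip(np.asarray(predictions, dtype=float), _CLAMP, 1.0 - _CLAMP)
    y = np.asarray(labels, dtype=float)
    y = np.where(y > 0, 1.0, 0.0)
    if p.shape != y.shape:
        raise ValueError("predictions and labels length mismatch")
    w = np.where(y > 0, pos_weight, neg_weight)
    return float(np.mean(-w * (y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


def hierarchy_reg_loss(latents, batch: RegularizationBatch, dist) -> float:
    """Ranking regularizer over anchor/positive/negatives triples.

    ``dist(a, B)`` must return distances from one latent row ``a`` to the
    rows of ``B``. Anchors with an empty negative set contribute nothing
    (with a warning). Decreasing any negative's distance or increasing the
    positive's distance increases the loss.
    """
    latents = np.asarray(latents, dtype=float)
    out = 0.0
    for a, p, negs in zip(batch.anchors, batch.positives, batch.negatives):
        if len(negs) == 0:
            warnings.warn(f"anchor {a} has no negatives; term skipped", stacklevel=2)
            continue
        d_pos = float(dist(latents[a], latents[[p]])[0])
        d_negs = np.asarray(dist(latents[a], latents[negs]), dtype=float)
        out += d_pos + _np_logsumexp(-d_negs)
    return float(out)


def total_loss(bce: float, reg_drug: float, reg_target: float, lambda_drug: float, lambda_target: float) -> float:
    """Composite objective ``L_wBCE + lambda_drug * L_reg^drug + lambda_target * L_reg^target``."""
    return float(bce + lambda_drug * reg_drug + lambda_target * reg_target)


def sample_training_batch(
    data: InteractionSet,
    drug_dist: HierarchyDistanceMatrix | None,
    target_dist: HierarchyDistanceMatrix | None,
    cfg: TrainingConfig,
    rng: np.random.Generator,
) -> TrainingBatch:
    """Draw one training batch: ``b`` interactions plus one hierarchy batch
    per regularized modality (sampled only over hierarchy-covered entities)."""
    if data.n_interactions == 0:
        raise ValueError("no labeled interactions")
    b = min(cfg.batch_interactions, data.n_interactions)
    idx = rng.choice(data.n_interactions, size=b, replace=False)
    dreg = (
        sample_regularization_batch(drug_dist, cfg.n_anchors, cfg.m_negatives, rng)
        if drug_dist is not None and cfg.lambda_drug > 0
        else None
    )
    treg = (
        sample_regularization_batch(target_dist, cfg.n_anchors, cfg.m_negatives, rng)
        if target_dist is not None and cfg.lambda_target > 0
        else None
    )
    return TrainingBatch(idx, dreg, treg)


def _reg_term_t(model: DTIModel, z_cov: Tensor, reg: RegularizationBatch, include_positive: bool) -> Tensor:
    terms = None
    for a, p, negs in zip(reg.anchors, reg.positives, reg.negatives):
        if len(negs) == 0:
            warnings.warn(f"anchor {a} has no negatives; term skipped", stacklevel=2)
            continue
        d_pos = model._sq_dists_t(z_cov[[int(a)]], z_cov[[int(p)]])
        pool = [int(p), *map(int, negs)] if include_positive else [int(k) for k in negs]
        d_negs = model._sq_dists_t(z_cov[[int(a)] * len(pool)], z_cov[pool])
        t = d_pos.sum() + (d_negs * -1.0).logsumexp(axis=0)
        terms = t if terms is None else terms + t
    return terms if terms is not None else Tensor(np.float32(0.0))


def train_model(
    data: InteractionSet,
    drug_dist: HierarchyDistanceMatrix | None = None,
    target_dist: HierarchyDistanceMatrix | None = None,
    drug_cfg: EncoderConfig | None = None,
    target_cfg: EncoderConfig | None = None,
    head: str = "lorentz_distance",
    train_cfg: TrainingConfig | None = None,
    alpha: float = 1.0,
    beta: float = 1.0,
    train_idx: np.ndarray | None = None,
) -> tuple:
    """Fit a pairwise DTI model; returns ``(model, loss_trace)``.

    ``loss_trace`` is a list of per-epoch dicts with mean ``bce``,
    ``reg_drug``, ``reg_target`` and ``total`` components. ``train_idx``
    restricts the interaction rows used for the BCE term (cross-validation
    folds); hierarchy regularization always sees the covered entities, as
    hierarchy preservation is evaluated in-sample. Fully reproducible from
    ``train_cfg.seed`` on a single thread.
    """
    cfg = train_cfg or TrainingConfig()
    data.validate()
    xd_all, xt_all = data.feature_arrays()
    xd_all = xd_all.astype(np.float32)
    xt_all = xt_all.astype(np.float32)
    drug_cfg = drug_cfg or EncoderConfig(input_dim=xd_all.shape[1])
    target_cfg = target_cfg or EncoderConfig(input_dim=xt_all.shape[1])

    rng = np.random.default_rng(cfg.seed)
    model = DTIModel(drug_cfg, target_cfg, head=head, alpha=alpha, beta=beta, rng=rng)
    opt = Adam(model.drug_encoder.params + model.target_encoder.params, lr=cfg.learning_rate)

    idx_pool = np.arange(data.n_interactions) if train_idx is None else np.asarray(train_idx, dtype=int)
    pairs, labels = data.pairs[idx_pool], data.labels[idx_pool]
    y01 = np.where(labels > 0, 1.0, 0.0).astype(np.float32)
    w = np.where(labels > 0, cfg.pos_weight, cfg.neg_weight).astype(np.float32)

    # hierarchy-covered entity feature blocks, aligned with the distance matrices
    def _covered(dist_m, ids, feats):
        if dist_m is None:
            return None, None
        rows = [ids.index(e) for e in dist_m.entities]
        return dist_m, feats[rows]

    drug_dist, xd_cov = _covered(drug_dist, data.drug_ids, xd_all)
    target_dist, xt_cov = _covered(target_dist, data.target_ids, xt_all)
    use_dreg = drug_dist is not None and cfg.lambda_drug > 0
    use_treg = target_dist is not None and cfg.lambda_target > 0

    trace = []
    n = len(pairs)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        sums = {"bce": 0.0, "reg_drug": 0.0, "reg_target": 0.0, "total": 0.0}
        n_batches = 0
        for start in range(0, n, cfg.batch_interactions):
            take = order[start : start + cfg.batch_interactions]
            zd, zt = model._latents_t(xd_all[pairs[take, 0]], xt_all[pairs[take, 1]], train=True, rng=rng)
            p = model._pair_probs_t(zd, zt).clamp(_CLAMP, 1.0 - _CLAMP)
            yb, wb = Tensor(y01[take]), Tensor(w[take])
            bce = ((yb * p.log() + (1.0 - yb) * (1.0 - p).log()) * wb * -1.0).mean()

            loss = bce
            rd = rt = None
            if use_dreg:
                reg = sample_regularization_batch(drug_dist, cfg.n_anchors, cfg.m_negatives, rng)
                z_cov = model.drug_encoder(xd_cov, train=True, rng=rng)
                if head == "lorentz_distance":
                    z_cov = model._to_manifold_t(z_cov)
                rd = _reg_term_t(model, z_cov, reg, cfg.include_positive)
                loss = loss + cfg.lambda_drug * rd
            if use_treg:
                reg = sample_regularization_batch(target_dist, cfg.n_anchors, cfg.m_negatives, rng)
                z_cov = model.target_encoder(xt_cov, train=True, rng=rng)
                if head == "lorentz_distance":
                    z_cov = model._to_manifold_t(z_cov)
                rt = _reg_term_t(model, z_cov, reg, cfg.include_positive)
                loss = loss + cfg.lambda_target * rt

            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}: "
                    f"bce={float(bce.data):.4g}, reg_drug={rd and float(rd.data)}, reg_target={rt and float(rt.data)}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()

            sums["bce"] += float(bce.data)
            sums["reg_drug"] += float(rd.data) if rd is not None else 0.0
            sums["reg_target"] += float(rt.data) if rt is not None else 0.0
            sums["total"] += float(loss.data)
            n_batches += 1
        trace.append({"epoch": epoch, **{k: v / n_batches for k, v in sums.items()}})
    return model, trace
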