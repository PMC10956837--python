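"""Tabular I/O and the in-memory interaction container.

All tabular formats are header-carrying TSV:

* interactions — ``drug  target  value`` (raw affinities, binarized at load
  time) or ``drug  target  label`` with labels already in {0,1} or {-1,+1};
* features — ``id`` followed by fixed-width numeric columns, one row per
  drug or target (e.g. 300-dimensional Mol2vec/ProtVec-style vectors);
* hierarchies — see :mod:`hyperdti.hierarchy`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hierarchy import HierarchyTree

__all__ = [
    "InteractionSet",
    "RunConfig",
    "load_interactions",
    "load_features",
    "write_features_tsv",
    "write_hierarchy_tsv",
]


@dataclass
class InteractionSet:
    """Sparse signed drug-target labels plus per-entity feature vectors.

    ``pairs`` holds ``(drug_index, target_index)`` rows into ``drug_ids`` /
    ``target_ids``; ``labels`` are +1 (interacting) or -1. Unobserved pairs
    are simply absent. Feature tables may be attached after construction;
    :meth:`validate` enforces that every labeled entity has features.
    """

    drug_ids: list
    target_ids: list
    pairs: np.ndarray
    labels: np.ndarray
    affinities: np.ndarray | None = None
    drug_features: pd.DataFrame | None = None
    target_features: pd.DataFrame | None = None

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.pairs) != len(self.labels):
            raise ValueError("pairs and labels length mismatch")
        if len(self.labels) and not set(np.unique(self.labels)) <= {-1, 1}:
            raise ValueError("labels must be +1/-1")
        seen = set(map(tuple, self.pairs))
        if len(seen) != len(self.pairs):
            raise ValueError("duplicate (drug, target) pair")
        if len(self.pairs):
            if self.pairs[:, 0].max() >= len(self.drug_ids) or self.pairs[:, 1].max() >= len(self.target_ids):
                raise ValueError("pair index out of range")

    # ---- bookkeeping -----------------------------------------------------
    @property
    def n_interactions(self) -> int:
        return len(self.labels)

    @property
    def sparsity(self) -> float:
        """Fraction of the drug-by-target grid left unobserved."""
        total = len(self.drug_ids) * len(self.target_ids)
        return 1.0 - self.n_interactions / total if total else 1.0

    def validate(self) -> None:
        for name, ids, feats in (
            ("drug", self.drug_ids, self.drug_features),
            ("target", self.target_ids, self.target_features),
        ):
            if feats is None:
                raise ValueError(f"{name} features not attached")
            missing = [i for i in ids if i not in feats.index]
            if missing:
                raise ValueError(f"{name}s without features: {missing[:5]} ...")

    def feature_arrays(self) -> tuple:
        """Features as float arrays aligned with ``drug_ids`` / ``target_ids``."""
        self.validate()
        xd = self.drug_features.loc[self.drug_ids].to_numpy(dtype=float)
        xt = self.target_features.loc[self.target_ids].to_numpy(dtype=float)
        return xd, xt

    def write_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "drug": [self.drug_ids[i] for i in self.pairs[:, 0]],
                "target": [self.target_ids[j] for j in self.pairs[:, 1]],
                "label": np.where(self.labels > 0, 1, 0),
            }
        )
        if self.affinities is not None:
            df["value"] = self.affinities
        df.to_csv(path, sep="\t", index=False)


def load_interactions(path, threshold: float = 3.0, direction: str = "ge") -> InteractionSet:
    """Read an interaction TSV and binarize affinities.

    Raw affinity values are thresholded (default 3, the conventional
    dissociation-constant cutoff on log-transformed scales): with
    ``direction="ge"`` (higher = stronger, pKd-like) values ``>= threshold``
    become positives; ``direction="le"`` flips the rule for raw-Kd-like
    scales. Columns named ``label`` (or third columns whose values are all
    in {0,1} or {-1,+1}) are taken as pre-binarized and pass through.
    """
    if direction not in ("ge", "le"):
        raise ValueError("direction must be 'ge' or 'le'")
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: need drug, target and value/label columns")
    for col in ("drug", "target"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    value_col = "label" if "label" in df.columns else [c for c in df.columns if c not in ("drug", "target")][0]
    values = pd.to_numeric(df[value_col], errors="coerce")
    if values.isna().any():
        raise ValueError(f"{path}: non-numeric entries in column {value_col!r}")
    if df.duplicated(subset=["drug", "target"]).any():
        dup = df[df.duplicated(subset=["drug", "target"])].iloc[0]
        raise ValueError(f"{path}: duplicate pair ({dup['drug']}, {dup['target']})")

    uniq = set(values.unique())
    affinities = None
    if uniq <= {0, 1} or uniq <= {-1, 1}:
        labels = np.where(values.to_numpy() > 0, 1, -1)
    else:
        affinities = values.to_numpy(dtype=float)
        pos = affinities >= threshold if direction == "ge" else affinities <= threshold
        labels = np.where(pos, 1, -1)

    drug_ids = sorted(df["drug"].astype(str).unique())
    target_ids = sorted(df["target"].astype(str).unique())
    d_index = {d: i for i, d in enumerate(drug_ids)}
    t_index = {t: i for i, t in enumerate(target_ids)}
    pairs = np.array(
        [[d_index[str(d)], t_index[str(t)]] for d, t in zip(df["drug"], df["target"])],
        dtype=int,
    ).reshape(-1, 2)
    return InteractionSet(drug_ids, target_ids, pairs, labels, affinities)


def load_features(path) -> pd.DataFrame:
    """Read a feature TSV into a DataFrame indexed by entity id.

    Rows must be rectangular and numeric; ids must be unique.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate id {dup!r}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric feature value ({exc})") from exc
    if df.isna().any().any():
        raise ValueError(f"{path}: ragged or missing feature values")
    return df


@dataclass
class RunConfig:
    """Validated bundle of run-level knobs, loadable from YAML or JSON.

    Keys mirror the CLI flags: ``head``, ``latent_dim``, ``alpha``,
    ``beta``, ``epochs``, ``batch_interactions``, ``learning_rate``,
    ``pos_weight``, ``neg_weight``, ``lambda_drug``, ``lambda_target``,
    ``n_anchors``, ``m_negatives``, ``edp_k``, ``threshold``,
    ``direction``, ``folds``, ``seed``.
    """

    head: str = "lorentz_distance"
    latent_dim: int = 8
    alpha: float = 1.0
    beta: float = 1.0
    epochs: int = 16
    batch_interactions: int = 1024
    learning_rate: float = 5e-5
    pos_weight: float = 1.0
    neg_weight: float = 1.0
    lambda_drug: float = 0.1
    lambda_target: float = 0.1
    n_anchors: int = 10
    m_negatives: int = 256
    edp_k: int = 10
    threshold: float = 3.0
    direction: str = "ge"
    folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.head not in ("euclidean_dot", "lorentz_distance", "euclidean", "lorentz"):
            raise ValueError(f"unknown head {self.head!r}")
        self.head = {"euclidean": "euclidean_dot", "lorentz": "lorentz_distance"}.get(self.head, self.head)
        if self.latent_dim < 2 or self.edp_k < 1 or self.folds < 2:
            raise ValueError("latent_dim >= 2, edp_k >= 1 and folds >= 2 required")
        if self.direction not in ("ge", "le"):
            raise ValueError("direction must be 'ge' or 'le'")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import json

        import yaml

        with open(path) as fh:
            raw = json.load(fh) if str(path).endswith(".json") else yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)


def write_features_tsv(features: pd.DataFrame, path) -> None:
    features.to_csv(path, sep="\t", index_label="id")


def write_hierarchy_tsv(tree: HierarchyTree, path) -> None:
    with open(path, "w") as fh:
        if tree.kind == "graph":
            for a, b in tree.edges:
                fh.write(f"{a}\t{b}\n")
            return
        for ent, plist in tree.paths.items():
            for p in plist:
                fh.write("\t".join([str(ent), *p]) + "\n")
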