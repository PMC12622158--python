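"""Shallow classifier heads over frozen per-residue embeddings.

Two head architectures: the cysteine-ligandability head is a small MLP with
two hidden layers ("three-layer" counting the output), and the
binding-residue head is a single linear layer to a probability.  Heads are
fit with scikit-learn (MLPClassifier / LogisticRegression) and their weights
are extracted into a plain numpy forward pass, so prediction, persistence
and replay are independent of the fitting backend.

Ensembles are (n_splits x models_per_split) collections of heads: each split
re-partitions the training material with cluster/uid leakage rules (via
:mod:`cysligand.clustering`), and each seed trains one head on that split.
The ensemble score of a site is the mean of the member probabilities; the
ensemble uncertainty is their population standard deviation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier

from ._hash import stable_u31
from .clustering import CysCluster, partition_clusters
from .errors import ContractError, DegenerateDataError
from .metrics import PredictionSet

Site = tuple[str, int]


@dataclass(frozen=True)
class LabeledSite:
    """One training example: a site, its binary label, cluster id, embedding."""

    uid: str
    position: int
    label: int  # 1 = ligandable
    cluster_id: int
    vector: tuple  # embedding values, kept hashable

    @property
    def site(self) -> Site:
        return (self.uid, self.position)

    @classmethod
    def make(cls, uid, position, label, cluster_id, vector) -> "LabeledSite":
        return cls(uid, position, int(label), int(cluster_id),
                   tuple(float(v) for v in np.asarray(vector)))


@dataclass(frozen=True)
class HeadConfig:
    task: str = "ligcys"               # "ligcys" | "ligbind"
    hidden_layers: tuple[int, ...] = (256, 64)
    activation: str = "relu"
    epochs: int = 150
    learning_rate: float = 1e-3
    class_weighted: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.task == "ligbind" and self.hidden_layers:
            raise ValueError("ligbind head is single-layer: hidden_layers must be ()")

    @classmethod
    def ligbind(cls, **kw) -> "HeadConfig":
        return cls(task="ligbind", hidden_layers=(), **kw)


@dataclass(frozen=True)
class EnsembleSpec:
    n_splits: int
    models_per_split: int

    @property
    def total_models(self) -> int:
        return self.n_splits * self.models_per_split

    @classmethod
    def parse(cls, text: str) -> "EnsembleSpec":
        a, b = text.lower().split("x")
        return cls(int(a), int(b))


@dataclass
class TrainedHead:
    """Weights of a fitted head; prediction is a plain numpy forward pass."""

    weights: list[np.ndarray]     # one (in, out) matrix per layer
    biases: list[np.ndarray]
    activation: str
    config: HeadConfig
    loss_curve: list[float] | None = None

    @property
    def input_dim(self) -> int:
        return self.weights[0].shape[0]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.input_dim:
            raise ContractError(
                f"expected (*, {self.input_dim}) input, got {X.shape}")
        h = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = h @ W + b
            if self.activation == "relu":
                h = np.maximum(h, 0.0)
            elif self.activation == "tanh":
                h = np.tanh(h)
            else:
                raise ContractError(f"unknown activation {self.activation!r}")
        z = (h @ self.weights[-1] + self.biases[-1]).ravel()
        return 1.0 / (1.0 + np.exp(-z))


def _replication_counts(y: np.ndarray) -> np.ndarray:
    """Integer per-row repeats approximating balanced class weights."""
    counts = np.bincount(y, minlength=2)
    reps = np.ones(len(y), dtype=int)
    if counts[0] and counts[1]:
        minority = int(np.argmin(counts))
        ratio = max(1, round(counts[1 - minority] / counts[minority]))
        reps[y == minority] = ratio
    return reps


def train_head(X, y, config: HeadConfig) -> TrainedHead:
    """Fit one head; deterministic given the config seed.

    Raises :class:`DegenerateDataError` when only one class is present.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("training set contains a single class")
    if config.class_weighted:
        reps = _replication_counts(y)
        X = np.repeat(X, reps, axis=0)
        y = np.repeat(y, reps)
    if config.hidden_layers:
        clf = MLPClassifier(
            hidden_layer_sizes=config.hidden_layers,
            activation=config.activation,
            solver="adam",
            learning_rate_init=config.learning_rate,
            max_iter=config.epochs,
            random_state=config.seed,
            tol=0.0,                 # run the full epoch budget
            n_iter_no_change=config.epochs,
        )
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
            clf.fit(X, y)
        return TrainedHead(
            weights=[np.asarray(w) for w in clf.coefs_],
            biases=[np.asarray(b).ravel() for b in clf.intercepts_],
            activation=config.activation,
            config=config,
            loss_curve=[float(v) for v in clf.loss_curve_],
        )
    clf = LogisticRegression(max_iter=max(config.epochs, 200))
    clf.fit(X, y)
    return TrainedHead(
        weights=[np.asarray(clf.coef_).T],
        biases=[np.asarray(clf.intercept_).ravel()],
        activation=config.activation,
        config=config,
        loss_curve=None,
    )


@dataclass
class Ensemble:
    members: list[TrainedHead]
    tags: list[dict]                       # split/seed provenance per member
    spec: EnsembleSpec
    config: HeadConfig

    def _member_matrix(self, X: np.ndarray) -> np.ndarray:
        return np.stack([m.predict_proba(X) for m in self.members])

    def predict(self, sites: list[Site], vectors) -> PredictionSet:
        X = np.stack([np.asarray(vectors[s], dtype=float) for s in sites])
        mean = self._member_matrix(X).mean(axis=0)
        return PredictionSet(
            scores={s: float(v) for s, v in zip(sites, mean)},
            provenance={"spec": (self.spec.n_splits, self.spec.models_per_split)},
        )

    def uncertainty(self, sites: list[Site], vectors) -> dict[Site, float]:
        if len(self.members) < 2:
            raise DegenerateDataError("uncertainty undefined for a single member")
        X = np.stack([np.asarray(vectors[s], dtype=float) for s in sites])
        sd = self._member_matrix(X).std(axis=0)  # population SD
        return {s: float(v) for s, v in zip(sites, sd)}

    # ---- persistence (directory of .npz weights + JSON manifest) ----

    def save(self, path) -> None:
        # one .npy per weight/bias array (np.save is byte-reproducible,
        # unlike zip-based formats) plus a JSON manifest
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        n_layers = []
        for i, head in enumerate(self.members):
            for j, (W, b) in enumerate(zip(head.weights, head.biases)):
                np.save(path / f"member_{i:03d}_W{j}.npy", W)
                np.save(path / f"member_{i:03d}_b{j}.npy", b)
            n_layers.append(len(head.weights))
        manifest = {
            "spec": [self.spec.n_splits, self.spec.models_per_split],
            "config": {k: list(v) if isinstance(v, tuple) else v
                       for k, v in self.config.__dict__.items()},
            "tags": self.tags,
            "n_members": len(self.members),
            "n_layers": n_layers,
        }
        (path / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))

    @classmethod
    def load(cls, path) -> "Ensemble":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        cfg = dict(manifest["config"])
        cfg["hidden_layers"] = tuple(cfg["hidden_layers"])
        config = HeadConfig(**cfg)
        members = []
        for i in range(manifest["n_members"]):
            nl = manifest["n_layers"][i]
            members.append(TrainedHead(
                weights=[np.load(path / f"member_{i:03d}_W{j}.npy") for j in range(nl)],
                biases=[np.load(path / f"member_{i:03d}_b{j}.npy") for j in range(nl)],
                activation=config.activation, config=config))
        return cls(members=members, tags=manifest["tags"],
                   spec=EnsembleSpec(*manifest["spec"]), config=config)


def _clusters_from_sites(sites: list[LabeledSite]) -> tuple[list[CysCluster], dict[int, list[LabeledSite]]]:
    groups: dict[int, list[LabeledSite]] = {}
    for s in sites:
        groups.setdefault(s.cluster_id, []).append(s)
    clusters = []
    order = []
    for cid in sorted(groups):
        members = sorted(ls.site for ls in groups[cid])
        clusters.append(CysCluster(members=members, representative=members[0]))
        order.append(cid)
    return clusters, {i: groups[cid] for i, cid in enumerate(order)}


def train_ensemble(sites: list[LabeledSite], spec: EnsembleSpec,
                   config: HeadConfig, seed: int = 0,
                   holdout_fraction: float = 0.15) -> Ensemble:
    """Train an (n_splits x models_per_split) ensemble of heads.

    Each split draws a fresh leakage-safe partition of the labeled clusters
    (clusters sharing a uid stay together); ``holdout_fraction`` of sites is
    set aside per split and simply not trained on, which decorrelates the
    members.  All randomness is derived from ``seed``.
    """
    if not sites:
        raise DegenerateDataError("no training sites")
    clusters, by_index = _clusters_from_sites(sites)
    members: list[TrainedHead] = []
    tags: list[dict] = []
    for split in range(spec.n_splits):
        split_seed = stable_u31(seed, "split", split)
        if spec.n_splits == 1 or holdout_fraction <= 0:
            train_sites = sites
        else:
            assignment = partition_clusters(
                clusters, (1.0 - holdout_fraction, holdout_fraction, 0.0),
                seed=split_seed)
            train_sites = [ls for i, lss in by_index.items()
                           if assignment.assignment[i] == "train" for ls in lss]
        X = np.asarray([ls.vector for ls in train_sites])
        y = np.asarray([ls.label for ls in train_sites])
        for j in range(spec.models_per_split):
            head_cfg = replace(config, seed=stable_u31(seed, "head", split, j))
            members.append(train_head(X, y, head_cfg))
            tags.append({"split": split, "seed_index": j})
    return Ensemble(members=members, tags=tags, spec=spec, config=config)


def blend(pred_a: PredictionSet, pred_b: PredictionSet) -> PredictionSet:
    """Unweighted per-site mean of two prediction sets over the same sites."""
    if set(pred_a.scores) != set(pred_b.scores):
        raise ContractError("blend requires identical site sets")
    return PredictionSet(
        scores={s: 0.5 * (pred_a.scores[s] + pred_b.scores[s])
                for s in pred_a.scores},
        provenance={"blend_of": [pred_a.provenance, pred_b.provenance]},
    )


__all__ = [
    "LabeledSite", "HeadConfig", "EnsembleSpec", "TrainedHead", "Ensemble",
    "train_head", "train_ensemble", "blend",
]
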