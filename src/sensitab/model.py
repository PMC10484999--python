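"""Semi-supervised gated tabular network and baseline classifier panel.

The core learner is a compact feed-forward network for tabular data with an
instance-wise soft feature-attention gate: a small subnetwork computes a
per-feature gate in (0, 1) that multiplies the input before the hidden
stack, and an L1 sparsity penalty on the gate encourages the model to
attend to few features.  The same encoder supports two training modes:

* self-supervised pretraining — random feature masking with a linear
  reconstruction head, trained to impute the masked values (loss is the
  mean squared error over masked entries only);
* supervised fine-tuning — a logistic head trained with cross-entropy,
  optionally initialized from pretrained encoder weights, with early
  stopping on validation NegLog2RMSL.

Everything is plain numpy with hand-written backpropagation and Adam, so
runs are bit-reproducible for a fixed seed on a fixed BLAS.
"""

from __future__ import annotations

import hashlib
import json
import os
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .data import ExpressionMatrix, LabeledDataset
from .metrics import MetricReport, metric_suite, neglog2_rmsl

__all__ = [
    "HyperParams",
    "EncoderState",
    "FittedModel",
    "pretrain",
    "fit",
    "predict_proba",
    "fit_baselines",
    "BASELINE_PANEL",
    "save_model",
    "load_model",
]

_ENCODER_KEYS_PREFIXES = ("gate_", "hidden_")
_LEAK = 0.01   # leaky-ReLU slope; keeps gradient alive through inactive units


def _leaky(z):
    return np.where(z > 0, z, _LEAK * z)


def _leaky_grad(z):
    return np.where(z > 0, 1.0, _LEAK)


@dataclass(frozen=True)
class HyperParams:
    """Configuration of the gated tabular network.

    decision_width
        Width of each hidden (decision) layer.
    attention_width
        Width of the gate subnetwork's hidden layer.
    n_decision_steps
        Number of hidden layers after the gate.
    relaxation_gamma
        Sharpness (>= 1) of the gate sigmoid; larger pushes gates toward
        hard 0/1 feature selection.
    sparsity_coefficient
        Weight of the L1 penalty on mean gate activation.
    """

    decision_width: int = 16
    attention_width: int = 8
    n_decision_steps: int = 2
    relaxation_gamma: float = 1.5
    sparsity_coefficient: float = 1e-4
    learning_rate: float = 0.02
    batch_size: int = 32
    max_epochs: int = 100
    early_stop_patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("decision_width", "attention_width", "n_decision_steps",
                     "batch_size", "max_epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.relaxation_gamma < 1:
            raise ValueError("relaxation_gamma must be >= 1")
        if self.sparsity_coefficient < 0:
            raise ValueError("sparsity_coefficient must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.early_stop_patience < 0:
            raise ValueError("early_stop_patience must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "HyperParams":
        return cls(**d)

    def n_parameters(self, n_features: int) -> int:
        """Trainable parameter count of the classifier for a feature count."""
        d, m, h, L = n_features, self.attention_width, self.decision_width, self.n_decision_steps
        gate = d * m + m + m * d + d
        hidden = d * h + h + (L - 1) * (h * h + h)
        head = h + 1
        return gate + hidden + head


def _init_params(hp: HyperParams, n_features: int, rng: np.random.Generator) -> dict:
    d, m, h = n_features, hp.attention_width, hp.decision_width

    def glorot(n_in, n_out):
        s = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-s, s, size=(n_in, n_out))

    params = {
        "gate_U1": glorot(d, m), "gate_c1": np.zeros(m),
        "gate_U2": glorot(m, d), "gate_c2": np.zeros(d),
    }
    width_in = d
    for layer in range(hp.n_decision_steps):
        params[f"hidden_W{layer}"] = glorot(width_in, h)
        # small positive bias keeps ReLU units live at initialization
        params[f"hidden_b{layer}"] = np.full(h, 0.01)
        width_in = h
    params["head_w"] = glorot(h, 1)[:, 0]
    params["head_b"] = np.zeros(())
    return params


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward_encoder(params: dict, hp: HyperParams, x: np.ndarray):
    """Gate + hidden stack; returns final hidden activations and a cache."""
    z1 = x @ params["gate_U1"] + params["gate_c1"]
    a1 = _leaky(z1)
    z2 = a1 @ params["gate_U2"] + params["gate_c2"]
    gate = _sigmoid(hp.relaxation_gamma * z2)
    h = x * gate
    cache = {"x": x, "z1": z1, "a1": a1, "gate": gate, "pre": [], "post": [x * gate]}
    for layer in range(hp.n_decision_steps):
        s = h @ params[f"hidden_W{layer}"] + params[f"hidden_b{layer}"]
        h = _leaky(s)
        cache["pre"].append(s)
        cache["post"].append(h)
    return h, cache


def _backward_encoder(params: dict, hp: HyperParams, cache: dict,
                      d_h: np.ndarray, grads: dict, sparsity_grad: float) -> None:
    """Backprop d_h (grad wrt final hidden) through the stack and gate.

    ``sparsity_grad`` is dLoss/dGate from the sparsity penalty (a scalar,
    applied uniformly).
    """
    for layer in range(hp.n_decision_steps - 1, -1, -1):
        d_s = d_h * _leaky_grad(cache["pre"][layer])
        grads[f"hidden_W{layer}"] = cache["post"][layer].T @ d_s
        grads[f"hidden_b{layer}"] = d_s.sum(axis=0)
        d_h = d_s @ params[f"hidden_W{layer}"].T
    x, gate = cache["x"], cache["gate"]
    d_gate = d_h * x + sparsity_grad
    d_z2 = d_gate * gate * (1.0 - gate) * hp.relaxation_gamma
    grads["gate_U2"] = cache["a1"].T @ d_z2
    grads["gate_c2"] = d_z2.sum(axis=0)
    d_a1 = d_z2 @ params["gate_U2"].T
    d_z1 = d_a1 * _leaky_grad(cache["z1"])
    grads["gate_U1"] = x.T @ d_z1
    grads["gate_c1"] = d_z1.sum(axis=0)


def _supervised_loss_grads(params: dict, hp: HyperParams, x: np.ndarray, y: np.ndarray):
    """Cross-entropy + gate-sparsity loss and its gradients."""
    n = x.shape[0]
    h, cache = _forward_encoder(params, hp, x)
    logits = h @ params["head_w"] + params["head_b"]
    p = _sigmoid(logits)
    eps = 1e-12
    bce = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
    loss = bce + hp.sparsity_coefficient * cache["gate"].mean()
    grads: dict = {}
    d_logits = (p - y) / n
    grads["head_w"] = h.T @ d_logits
    grads["head_b"] = np.asarray(d_logits.sum())
    d_h = d_logits[:, None] * params["head_w"][None, :]
    sparsity_grad = hp.sparsity_coefficient / cache["gate"].size
    _backward_encoder(params, hp, cache, d_h, grads, sparsity_grad)
    return loss, grads


def _recon_loss_grads(params: dict, hp: HyperParams, x: np.ndarray,
                      mask: np.ndarray):
    """Masked-reconstruction loss (MSE on masked entries) and gradients."""
    x_in = x * (1.0 - mask)
    h, cache = _forward_encoder(params, hp, x_in)
    x_hat = h @ params["recon_D"] + params["recon_e"]
    n_masked = max(mask.sum(), 1.0)
    diff = mask * (x_hat - x)
    loss = float((diff ** 2).sum() / n_masked) + hp.sparsity_coefficient * cache["gate"].mean()
    grads: dict = {}
    d_xhat = 2.0 * diff / n_masked
    grads["recon_D"] = h.T @ d_xhat
    grads["recon_e"] = d_xhat.sum(axis=0)
    d_h = d_xhat @ params["recon_D"].T
    sparsity_grad = hp.sparsity_coefficient / cache["gate"].size
    _backward_encoder(params, hp, cache, d_h, grads, sparsity_grad)
    return loss, grads


class _Adam:
    def __init__(self, params: dict, lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / (1 - self.b1 ** self.t)
            v_hat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] = params[k] - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _weights_fingerprint(params: dict) -> str:
    digest = hashlib.sha256()
    for key in sorted(params):
        digest.update(key.encode())
        digest.update(np.ascontiguousarray(params[key]).tobytes())
    return digest.hexdigest()


@dataclass
class EncoderState:
    """Pretrained encoder weights plus provenance."""

    weights: dict
    fingerprint: str
    n_features: int
    gene_ids: list
    pretraining_config: HyperParams
    masking_fraction: float
    loss_history: list = field(default_factory=list)

    @property
    def final_loss(self) -> float:
        return self.loss_history[-1]


@dataclass
class FittedModel:
    """A trained classifier bound to the gene list it was trained on."""

    weights: dict
    hp: HyperParams
    gene_ids: list
    decision_threshold: float
    metadata: dict = field(default_factory=dict)

    @property
    def fingerprint(self) -> str:
        return _weights_fingerprint(self.weights)


def _coerce_matrix(data) -> tuple[np.ndarray, list]:
    if isinstance(data, ExpressionMatrix):
        return data.values, list(data.gene_ids)
    if isinstance(data, LabeledDataset):
        return data.features, list(data.gene_ids)
    raise TypeError("expected ExpressionMatrix or LabeledDataset")


def _check_normalized(values: np.ndarray) -> None:
    if values.size and (values.min() < -1e-9 or values.max() > 1 + 1e-9):
        raise ValueError("input must be min-max normalized to [0, 1] first")


def pretrain(unlabeled, config: HyperParams | None = None,
             masking_fraction: float = 0.5) -> EncoderState:
    """Self-supervised pretraining by masked-feature reconstruction.

    A random ``masking_fraction`` of entries is zeroed per presentation and
    the network is trained to reconstruct the original values at the masked
    positions.  Returns the encoder weights with a content fingerprint and
    the per-epoch reconstruction-loss history.
    """
    if not 0.0 < masking_fraction < 1.0:
        raise ValueError("masking_fraction must be strictly inside (0, 1)")
    values, gene_ids = _coerce_matrix(unlabeled)
    _check_normalized(values)
    if values.shape[0] < 2:
        raise ValueError("pretraining needs at least 2 samples")
    hp = config or HyperParams()
    # the gate-sparsity penalty is a supervised feature-selection device; under
    # the reconstruction objective it drives the gates into a dead all-closed
    # optimum (constant decoder), so it is disabled while pretraining
    hp = HyperParams.from_dict({**hp.to_dict(), "sparsity_coefficient": 0.0})
    rng = np.random.default_rng(hp.seed)
    params = _init_params(hp, values.shape[1], rng)
    params["recon_D"] = rng.uniform(
        -0.05, 0.05, size=(hp.decision_width, values.shape[1]))
    params["recon_e"] = np.zeros(values.shape[1])
    opt = _Adam(params, hp.learning_rate)
    n = values.shape[0]
    history = []
    for _epoch in range(hp.max_epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, hp.batch_size):
            batch = values[order[start:start + hp.batch_size]]
            mask = (rng.random(batch.shape) < masking_fraction).astype(float)
            loss, grads = _recon_loss_grads(params, hp, batch, mask)
            opt.step(params, grads)
            epoch_loss += loss
            n_batches += 1
        history.append(epoch_loss / n_batches)
    encoder_weights = {k: v.copy() for k, v in params.items()
                       if k.startswith(_ENCODER_KEYS_PREFIXES)}
    return EncoderState(
        weights=encoder_weights,
        fingerprint=_weights_fingerprint(encoder_weights),
        n_features=values.shape[1],
        gene_ids=gene_ids,
        pretraining_config=hp,
        masking_fraction=masking_fraction,
        loss_history=history,
    )


def fit(train: LabeledDataset, hp: HyperParams | None = None,
        encoder: EncoderState | None = None,
        validation: LabeledDataset | None = None,
        early_stop_metric: str = "neglog2rmsl") -> FittedModel:
    """Supervised training, optionally warm-started from a pretrained encoder.

    With a validation set, training early-stops on validation NegLog2RMSL
    (or AUC via ``early_stop_metric="auc"``) with the configured patience
    and restores the best epoch's weights.
    """
    hp = hp or HyperParams()
    counts = train.class_counts()
    if min(counts.values()) == 0:
        raise ValueError(f"training labels contain a single class: {counts}")
    if validation is not None and validation.gene_ids != train.gene_ids:
        raise ValueError("train and validation gene lists differ")
    if early_stop_metric not in ("neglog2rmsl", "auc"):
        raise ValueError("early_stop_metric must be 'neglog2rmsl' or 'auc'")
    rng = np.random.default_rng(hp.seed)
    params = _init_params(hp, train.n_genes, rng)
    if encoder is not None:
        if encoder.n_features != train.n_genes:
            raise ValueError(
                f"encoder was pretrained on {encoder.n_features} features but "
                f"training data has {train.n_genes}"
            )
        if encoder.gene_ids and encoder.gene_ids != train.gene_ids:
            raise ValueError("encoder gene list does not match training data")
        for k, v in encoder.weights.items():
            params[k] = v.copy()
    opt = _Adam(params, hp.learning_rate)
    x, y = train.features, train.labels.astype(float)
    n = x.shape[0]
    best_score, best_params, best_epoch, stale = -np.inf, None, 0, 0
    epochs_run = 0
    for epoch in range(hp.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, hp.batch_size):
            batch = order[start:start + hp.batch_size]
            _, grads = _supervised_loss_grads(params, hp, x[batch], y[batch])
            opt.step(params, grads)
        epochs_run = epoch + 1
        if validation is not None:
            p_val = _predict_values(params, hp, validation.features)
            if early_stop_metric == "auc":
                from sklearn.metrics import roc_auc_score
                score = roc_auc_score(validation.labels, p_val)
            else:
                score = neglog2_rmsl(validation.labels, p_val)
            if score > best_score:
                best_score, best_epoch, stale = score, epoch, 0
                best_params = {k: v.copy() for k, v in params.items()}
            else:
                stale += 1
                if stale > hp.early_stop_patience:
                    break
    if best_params is not None:
        params = best_params
    return FittedModel(
        weights=params,
        hp=hp,
        gene_ids=list(train.gene_ids),
        decision_threshold=0.5,
        metadata={
            "epochs_run": epochs_run,
            "best_epoch": best_epoch if validation is not None else None,
            "best_val_score": float(best_score) if validation is not None else None,
            "early_stop_metric": early_stop_metric if validation is not None else None,
            "seed": hp.seed,
            "training_sample_ids": list(train.sample_ids),
            "pretrained": encoder.fingerprint if encoder is not None else None,
        },
    )


def _predict_values(params: dict, hp: HyperParams, values: np.ndarray) -> np.ndarray:
    h, _ = _forward_encoder(params, hp, values)
    return _sigmoid(h @ params["head_w"] + params["head_b"])


def predict_proba(model: FittedModel, data) -> np.ndarray:
    """Probability of *sensitive* per sample; columns realigned by gene name."""
    values, gene_ids = _coerce_matrix(data)
    _check_normalized(values)
    extra = sorted(set(gene_ids) - set(model.gene_ids))
    missing = sorted(set(model.gene_ids) - set(gene_ids))
    if extra or missing:
        raise ValueError(
            f"gene list mismatch; unknown genes: {extra}, missing genes: {missing}"
        )
    if gene_ids != model.gene_ids:
        index = {g: j for j, g in enumerate(gene_ids)}
        values = values[:, [index[g] for g in model.gene_ids]]
    return _predict_values(model.weights, model.hp, values)


BASELINE_PANEL = (
    "logistic_regression",
    "random_forest",
    "gradient_boosting",
    "svm_rbf",
    "knn",
    "naive_bayes",
)


def _build_baseline(name: str, seed: int):
    from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC

    if name == "logistic_regression":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    if name == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed)
    if name == "svm_rbf":
        return SVC(kernel="rbf", probability=True, random_state=seed)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "naive_bayes":
        return GaussianNB()
    raise ValueError(f"unknown baseline {name!r}; choose from {BASELINE_PANEL}")


def fit_baselines(train: LabeledDataset, validation: LabeledDataset,
                  panel=BASELINE_PANEL, seed: int = 0) -> dict:
    """Train a panel of conventional classifiers and report the metric suite.

    Each baseline runs with fixed default settings and the given seed;
    duplicate panel entries are de-duplicated with a warning.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    deduped = list(dict.fromkeys(panel))
    if len(deduped) != len(panel):
        warnings.warn("duplicate baseline identifiers de-duplicated", stacklevel=2)
    reports: dict[str, MetricReport] = {}
    for name in deduped:
        clf = _build_baseline(name, seed)
        clf.fit(train.features, train.labels)
        proba = clf.predict_proba(validation.features)[:, list(clf.classes_).index(1)]
        reports[name] = metric_suite(validation.labels, proba)
    return reports


_FORMAT_VERSION = 1


def save_model(model: FittedModel, directory) -> None:
    """Write weights plus a JSON sidecar (gene list, config, metadata)."""
    os.makedirs(directory, exist_ok=True)
    np.savez(os.path.join(directory, "weights.npz"), **model.weights)
    sidecar = {
        "format_version": _FORMAT_VERSION,
        "hyperparams": model.hp.to_dict(),
        "gene_ids": model.gene_ids,
        "decision_threshold": model.decision_threshold,
        "metadata": model.metadata,
        "fingerprint": model.fingerprint,
    }
    with open(os.path.join(directory, "model.json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_model(directory) -> FittedModel:
    with open(os.path.join(directory, "model.json")) as fh:
        sidecar = json.load(fh)
    if sidecar.get("format_version") != _FORMAT_VERSION:
        raise ValueError("unsupported model format version")
    with np.load(os.path.join(directory, "weights.npz")) as npz:
        weights = {k: npz[k].copy() for k in npz.files}
    model = FittedModel(
        weights=weights,
        hp=HyperParams.from_dict(sidecar["hyperparams"]),
        gene_ids=list(sidecar["gene_ids"]),
        decision_threshold=float(sidecar["decision_threshold"]),
        metadata=sidecar["metadata"],
    )
    if model.fingerprint != sidecar["fingerprint"]:
        raise ValueError("weight fingerprint mismatch; model files corrupted")
    return model
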