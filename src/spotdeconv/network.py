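"""The proportion-regression network and its training/evaluation wrappers.

The model is a fully connected feed-forward network mapping a normalised
expression vector to a cell-type composition: hidden layers with
ReLU/PReLU activations and inverted dropout, and a softmax output head
so every prediction lies on the probability simplex by construction.
Training minimises the KL divergence between true and predicted
compositions (MSE and MAE are available alternatives) with Adam,
mini-batches, and early stopping on a held-out validation split.

Everything is plain numpy with explicit forward/backward passes, which
keeps training deterministic for a fixed seed and makes exact input
gradients available to the attribution module.

:class:`ProportionRegressor` follows scikit-learn estimator conventions
(``fit``/``predict``, ``get_params``/``set_params``, trailing-underscore
fitted attributes) and composes with sklearn model selection.
:class:`DeconvolutionModel` binds a fitted regressor to its data
contract — gene space, cell-type order and normalisation — so it can be
applied to raw count matrices on any gene set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .datasets import NormalizationSpec, normalize, subset_to_gene_space
from .simulate import MixtureSet
from . import metrics as _metrics

__all__ = [
    "ModelConfig",
    "ProportionRegressor",
    "DeconvolutionModel",
    "EvaluationReport",
    "train",
    "evaluate",
    "uniform_predictor_loss",
]

_LOSSES = ("kl_divergence", "mse", "mae")
_EPS = 1e-12


@dataclass
class ModelConfig:
    """Hyperparameters of the deconvolution network.

    Defaults: two hidden layers of 200 ReLU units, dropout 0.25, softmax
    head trained with KL divergence, AdamW (learning rate 1e-3, weight
    decay 1e-4 on the weight matrices), batches of 64, up to 60 epochs
    with early stopping (patience 10) on validation loss.
    """

    hidden_sizes: tuple[int, ...] = (200, 200)
    activation: str = "relu"
    dropout: float = 0.25
    input_dropout: float = 0.0
    loss: str = "kl_divergence"
    batch_size: int = 64
    max_epochs: int = 60
    early_stop_patience: int = 10
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if not self.hidden_sizes or any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden_sizes must be non-empty and positive")
        if self.activation not in ("relu", "prelu"):
            raise ValueError("activation must be 'relu' or 'prelu'")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if not 0 <= self.input_dropout < 1:
            raise ValueError("input_dropout must lie in [0, 1)")
        if self.loss not in _LOSSES:
            raise ValueError(f"loss must be one of {_LOSSES}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden_sizes"] = list(self.hidden_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**{**d, "hidden_sizes": tuple(d["hidden_sizes"])})


class ProportionRegressor(BaseEstimator):
    """Feed-forward simplex regressor: expression in, composition out.

    Parameters mirror :class:`ModelConfig`. ``fit`` expects
    ``X`` of shape (n_samples, n_genes) — already normalised — and ``y``
    of shape (n_samples, n_types) with rows on the simplex.

    Attributes (after fit)
    ----------------------
    weights_ : list of (W, b[, slope]) per layer
    history_ : list of per-epoch dicts (train/val loss)
    best_epoch_ : epoch whose validation loss was lowest
    n_features_in_, n_outputs_ : input/output dimensions
    """

    def __init__(self, hidden_sizes=(200, 200), activation="relu",
                 dropout=0.25, input_dropout=0.0, loss="kl_divergence",
                 batch_size=64,
                 max_epochs=60, early_stop_patience=10, learning_rate=1e-3,
                 weight_decay=1e-4, val_fraction=0.1, seed=0):
        self.hidden_sizes = hidden_sizes
        self.activation = activation
        self.dropout = dropout
        self.input_dropout = input_dropout
        self.loss = loss
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.val_fraction = val_fraction
        self.seed = seed

    @classmethod
    def from_config(cls, config: ModelConfig,
                    val_fraction: float = 0.1) -> "ProportionRegressor":
        return cls(hidden_sizes=config.hidden_sizes,
                   activation=config.activation, dropout=config.dropout,
                   input_dropout=config.input_dropout,
                   loss=config.loss, batch_size=config.batch_size,
                   max_epochs=config.max_epochs,
                   early_stop_patience=config.early_stop_patience,
                   learning_rate=config.learning_rate,
                   weight_decay=config.weight_decay,
                   val_fraction=val_fraction, seed=config.seed)

    # -- numerics ----------------------------------------------------------

    @staticmethod
    def _softmax(z):
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def _init_weights(self, n_in, n_out, rng):
        sizes = [n_in, *self.hidden_sizes, n_out]
        params = []
        for i in range(len(sizes) - 1):
            fan_in = sizes[i]
            W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (sizes[i], sizes[i + 1]))
            b = np.zeros(sizes[i + 1])
            layer = [W, b]
            if self.activation == "prelu" and i < len(sizes) - 2:
                layer.append(np.full(sizes[i + 1], 0.25))  # learnable slope
            params.append(layer)
        return params

    def _forward(self, X, params, train_rng=None):
        """Forward pass; returns output and per-layer caches for backprop."""
        h = X
        if train_rng is not None and self.input_dropout > 0:
            # gene dropout: spreads reliance across redundant markers and
            # hardens the model against genes missing at prediction time
            keep = (train_rng.random(h.shape) >= self.input_dropout)
            h = h * keep / (1.0 - self.input_dropout)
        caches = []
        n_layers = len(params)
        for i, layer in enumerate(params):
            W, b = layer[0], layer[1]
            z = h @ W + b
            if i < n_layers - 1:
                if self.activation == "prelu":
                    slope = layer[2]
                    a = np.where(z > 0, z, slope * z)
                else:
                    a = np.maximum(z, 0.0)
                mask = None
                if train_rng is not None and self.dropout > 0:
                    mask = (train_rng.random(a.shape) >= self.dropout)
                    a = a * mask / (1.0 - self.dropout)
                caches.append((h, z, mask))
                h = a
            else:
                caches.append((h, z, None))
                h = self._softmax(z)
        return h, caches

    def _loss_and_dlogits(self, p, y):
        """Loss value and its gradient w.r.t. the output logits."""
        n = p.shape[0]
        if self.loss == "kl_divergence":
            val = np.sum(y * (np.log(y + _EPS) - np.log(p + _EPS))) / n
            dz = (p - y) / n
        else:
            if self.loss == "mse":
                val = np.mean((p - y) ** 2)
                dp = 2.0 * (p - y) / p.size
            else:  # mae
                val = np.mean(np.abs(p - y))
                dp = np.sign(p - y) / p.size
            # softmax Jacobian: dz = p * (dp - <dp, p>)
            dz = p * (dp - np.sum(dp * p, axis=1, keepdims=True))
        return float(val), dz

    def _loss_value(self, p, y):
        if self.loss == "kl_divergence":
            return float(np.sum(y * (np.log(y + _EPS) - np.log(p + _EPS)))
                         / p.shape[0])
        if self.loss == "mse":
            return float(np.mean((p - y) ** 2))
        return float(np.mean(np.abs(p - y)))

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_samples, n_genes) and y "
                             "(n_samples, n_types) with matching rows")
        if y.shape[1] < 2:
            raise ValueError("need >= 2 cell types")
        if not np.allclose(y.sum(axis=1), 1.0, atol=1e-4):
            raise ValueError("y rows must sum to 1 (compositions)")
        cfg_check = ModelConfig(hidden_sizes=tuple(self.hidden_sizes),
                                activation=self.activation,
                                dropout=self.dropout,
                                input_dropout=self.input_dropout,
                                loss=self.loss,
                                batch_size=self.batch_size,
                                max_epochs=self.max_epochs,
                                early_stop_patience=self.early_stop_patience,
                                learning_rate=self.learning_rate,
                                weight_decay=self.weight_decay,
                                seed=self.seed)
        del cfg_check  # validation only

        rng = np.random.default_rng(self.seed)
        n = X.shape[0]
        n_val = max(1, int(round(self.val_fraction * n))) if n > 4 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xtr, ytr = X[tr_idx], y[tr_idx]
        Xval, yval = X[val_idx], y[val_idx]

        params = self._init_weights(X.shape[1], y.shape[1], rng)
        # Adam state
        m = [[np.zeros_like(p) for p in layer] for layer in params]
        v = [[np.zeros_like(p) for p in layer] for layer in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        lr = self.learning_rate

        best_val = np.inf
        best_params = None
        best_epoch = -1
        patience_left = self.early_stop_patience
        history = []

        for epoch in range(self.max_epochs):
            order = rng.permutation(len(Xtr))
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, len(Xtr), self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, yb = Xtr[idx], ytr[idx]
                p, caches = self._forward(xb, params, train_rng=rng)
                loss_val, dz = self._loss_and_dlogits(p, yb)
                if not np.isfinite(loss_val):
                    raise FloatingPointError(
                        "training loss became non-finite; try a lower "
                        "learning rate or check that inputs are normalised "
                        "(raw counts should go through the NormalizationSpec)")
                epoch_loss += loss_val
                n_batches += 1
                grads = self._grads(dz, caches, params)
                t += 1
                for li, layer in enumerate(params):
                    for pi, p_arr in enumerate(layer):
                        g = grads[li][pi]
                        m[li][pi] = beta1 * m[li][pi] + (1 - beta1) * g
                        v[li][pi] = beta2 * v[li][pi] + (1 - beta2) * g * g
                        mhat = m[li][pi] / (1 - beta1 ** t)
                        vhat = v[li][pi] / (1 - beta2 ** t)
                        p_arr -= lr * mhat / (np.sqrt(vhat) + eps)
                        if pi == 0 and self.weight_decay:
                            p_arr -= lr * self.weight_decay * p_arr

            record = {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1)}
            if n_val:
                pval, _ = self._forward(Xval, params)
                val_loss = self._loss_value(pval, yval)
                record["val_loss"] = val_loss
                if val_loss < best_val - 1e-7:
                    best_val = val_loss
                    best_params = [[p.copy() for p in layer] for layer in params]
                    best_epoch = epoch
                    patience_left = self.early_stop_patience
                else:
                    patience_left -= 1
            history.append(record)
            if n_val and patience_left <= 0:
                break

        if best_params is not None:
            params = best_params
        self.weights_ = params
        self.history_ = history
        self.best_epoch_ = best_epoch if best_epoch >= 0 else len(history) - 1
        self.n_features_in_ = X.shape[1]
        self.n_outputs_ = y.shape[1]
        return self

    def _grads(self, dz, caches, params):
        """Per-layer parameter gradients from the output-logit gradient."""
        grads = [[np.zeros_like(p) for p in layer] for layer in params]
        for i in reversed(range(len(params))):
            h, z, mask = caches[i]
            grads[i][0] = h.T @ dz
            grads[i][1] = dz.sum(axis=0)
            if i == 0:
                break
            da = dz @ params[i][0].T
            h_prev, z_prev, mask_prev = caches[i - 1]
            if mask_prev is not None:
                da = da * mask_prev / (1.0 - self.dropout)
            if self.activation == "prelu":
                slope = params[i - 1][2]
                grads[i - 1][2] = np.sum(
                    np.where(z_prev > 0, 0.0, da * z_prev), axis=0)
                dz = np.where(z_prev > 0, da, da * slope)
            else:
                dz = da * (z_prev > 0)
        return grads

    def _check_fitted(self):
        if not hasattr(self, "weights_"):
            raise NotFittedError("this ProportionRegressor is not fitted yet")

    def predict(self, X):
        """Composition for each row of ``X``; rows sum to 1 exactly."""
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        p, _ = self._forward(X, self.weights_)
        return p

    def input_gradient(self, X, target_index: int):
        """d output[target] / d input, per row of ``X`` (no dropout)."""
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        p, caches = self._forward(X, self.weights_)
        # d p_t / d logits = p_t * (e_t - p)
        pt = p[:, [target_index]]
        dz = pt * (-p)
        dz[:, target_index] += pt[:, 0]
        params = self.weights_
        for i in reversed(range(len(params))):
            da = dz @ params[i][0].T
            if i == 0:
                return da
            _, z_prev, _ = caches[i - 1]
            if self.activation == "prelu":
                slope = params[i - 1][2]
                dz = np.where(z_prev > 0, da, da * slope)
            else:
                dz = da * (z_prev > 0)
        return da


@dataclass
class EvaluationReport:
    """Per-type and overall agreement between predicted and true proportions."""

    per_type: pd.DataFrame
    overall: dict
    n_test_profiles: int

    def __str__(self) -> str:
        lines = [self.per_type.round(4).to_string(), ""]
        lines.append("overall: " + ", ".join(
            f"{k}={v:.4f}" for k, v in self.overall.items()))
        lines.append(f"n_test_profiles: {self.n_test_profiles}")
        return "\n".join(lines)


class DeconvolutionModel:
    """A fitted network plus its data contract.

    Stores the gene space (input order), cell-type order (output order)
    and the normalisation applied to every profile, so raw count
    matrices on arbitrary gene sets can be deconvoluted directly.
    """

    def __init__(self, net: ProportionRegressor, gene_space: list[str],
                 cell_type_order: list[str], norm_spec: NormalizationSpec,
                 config: ModelConfig | None = None):
        self.net = net
        self.gene_space = list(gene_space)
        self.cell_type_order = list(cell_type_order)
        self.norm_spec = norm_spec
        self.config = config or ModelConfig()

    @property
    def training_history(self) -> pd.DataFrame:
        return pd.DataFrame(self.net.history_)

    def prepare(self, counts, gene_ids: list[str]) -> np.ndarray:
        """Reindex a genes x columns count matrix to the model's input.

        Missing genes are zero-filled; requires > 0 overlap with the
        model gene space and warns below 90% (errors below 50% only if
        overlap is zero per contract; a sub-50% overlap warns strongly).
        Returns samples x genes normalised input.
        """
        present = set(gene_ids) & set(self.gene_space)
        frac = len(present) / len(self.gene_space)
        if frac == 0:
            raise ValueError("input shares no genes with the model gene space")
        if frac < 0.9:
            warnings.warn(
                f"input covers only {frac:.0%} of the model gene space "
                f"({len(self.gene_space) - len(present)} genes zero-filled)",
                UserWarning, stacklevel=2)
        sub = subset_to_gene_space(counts, gene_ids, self.gene_space)
        return normalize(sub, self.norm_spec).T

    def predict(self, counts, gene_ids: list[str]) -> np.ndarray:
        """Deconvolute raw count columns; returns columns x types simplex."""
        return self.net.predict(self.prepare(counts, gene_ids))

    def predict_mixture_set(self, mixtures: MixtureSet) -> np.ndarray:
        return self.predict(mixtures.profiles, mixtures.gene_ids)

    def evaluate(self, test_set: MixtureSet) -> EvaluationReport:
        return evaluate(self, test_set)

    # -- persistence -------------------------------------------------------

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for li, layer in enumerate(self.net.weights_):
            names = ["W", "b", "slope"]
            for pi, arr in enumerate(layer):
                arrays[f"layer{li}_{names[pi]}"] = arr
        np.savez(directory / "weights.npz", **arrays)
        contract = {
            "gene_space": self.gene_space,
            "cell_type_order": self.cell_type_order,
            "norm_spec": self.norm_spec.to_dict(),
            "config": self.config.to_dict(),
            "n_features_in": self.net.n_features_in_,
            "n_outputs": self.net.n_outputs_,
            "best_epoch": int(self.net.best_epoch_),
        }
        (directory / "contract.json").write_text(
            json.dumps(contract, indent=1))
        self.training_history.to_csv(directory / "history.csv", index=False)

    @classmethod
    def load(cls, directory) -> "DeconvolutionModel":
        directory = Path(directory)
        contract_path = directory / "contract.json"
        if not contract_path.exists():
            raise FileNotFoundError(f"missing {contract_path}")
        contract = json.loads(contract_path.read_text())
        config = ModelConfig.from_dict(contract["config"])
        net = ProportionRegressor.from_config(config)
        with np.load(directory / "weights.npz") as data:
            n_layers = 1 + max(int(k.split("_")[0][5:]) for k in data.files)
            weights = []
            for li in range(n_layers):
                layer = [data[f"layer{li}_W"], data[f"layer{li}_b"]]
                if f"layer{li}_slope" in data.files:
                    layer.append(data[f"layer{li}_slope"])
                weights.append(layer)
        net.weights_ = weights
        net.n_features_in_ = contract["n_features_in"]
        net.n_outputs_ = contract["n_outputs"]
        net.best_epoch_ = contract["best_epoch"]
        hist_path = directory / "history.csv"
        net.history_ = (pd.read_csv(hist_path).to_dict("records")
                        if hist_path.exists() else [])
        return cls(net=net, gene_space=contract["gene_space"],
                   cell_type_order=contract["cell_type_order"],
                   norm_spec=NormalizationSpec.from_dict(contract["norm_spec"]),
                   config=config)


def train(train_set: MixtureSet, norm_spec: NormalizationSpec,
          config: ModelConfig | None = None,
          val_fraction: float = 0.1) -> DeconvolutionModel:
    """Train the deconvolution network on simulated mixtures.

    Profiles are reindexed to ``norm_spec.gene_space``, normalised, and
    fed to :class:`ProportionRegressor`; a ``val_fraction`` slice of the
    training profiles is held out for early stopping.
    """
    config = config or ModelConfig()
    net = ProportionRegressor.from_config(config, val_fraction=val_fraction)
    X = normalize(subset_to_gene_space(train_set.profiles, train_set.gene_ids,
                                       norm_spec.gene_space), norm_spec).T
    net.fit(X, train_set.proportions)
    return DeconvolutionModel(net=net, gene_space=norm_spec.gene_space,
                              cell_type_order=train_set.cell_type_order,
                              norm_spec=norm_spec, config=config)


def evaluate(model: DeconvolutionModel, test_set: MixtureSet) -> EvaluationReport:
    """Score predictions on held-out mixtures, per type and overall.

    Per-type PCC/CCC/RMSE compare predicted against true proportions of
    that type across profiles; the overall means average these across
    types, and mean JSD averages the per-profile divergence between
    predicted and true composition vectors.
    """
    pred = model.predict_mixture_set(test_set)
    truth = test_set.proportions
    rows = []
    for ti, t in enumerate(model.cell_type_order):
        rows.append({
            "cell_type": t,
            "pcc": _metrics.pcc(truth[:, ti], pred[:, ti]),
            "ccc": _metrics.ccc(truth[:, ti], pred[:, ti]),
            "rmse": _metrics.rmse(truth[:, ti], pred[:, ti]),
        })
    per_type = pd.DataFrame(rows).set_index("cell_type")
    jsds = [_metrics.jsd(truth[i], pred[i]) for i in range(truth.shape[0])]
    overall = {
        "mean_pcc": float(np.nanmean(per_type["pcc"])),
        "mean_ccc": float(np.nanmean(per_type["ccc"])),
        "mean_rmse": float(np.nanmean(per_type["rmse"])),
        "mean_jsd": float(np.mean(jsds)),
    }
    return EvaluationReport(per_type=per_type, overall=overall,
                            n_test_profiles=truth.shape[0])


def uniform_predictor_loss(proportions: np.ndarray,
                           loss: str = "kl_divergence") -> float:
    """Loss of the constant uniform-composition predictor (a floor any
    trained model should beat on learnable data)."""
    y = np.asarray(proportions, dtype=float)
    p = np.full_like(y, 1.0 / y.shape[1])
    if loss == "kl_divergence":
        return float(np.sum(y * (np.log(y + _EPS) - np.log(p + _EPS)))
                     / y.shape[0])
    if loss == "mse":
        return float(np.mean((p - y) ** 2))
    return float(np.mean(np.abs(p - y)))
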