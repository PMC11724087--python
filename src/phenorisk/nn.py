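"""Multi-task proportional-hazards network over binary medical histories.

The model maps an individual's binary record vector to one log partial
hazard ("risk state") per endpoint.  Architecture: a shared stack of fully
connected layers, each followed by layer normalisation, dropout and a leaky
ReLU, topped by a linear head with one output per endpoint; a ``linear``
variant drops the hidden stack.  Training minimises an adapted Cox partial
likelihood: within each minibatch and endpoint, the negative log partial
likelihood over in-batch risk sets (Breslow ties) is averaged over that
endpoint's in-batch events, and the per-endpoint losses are summed.  The
in-batch risk set is an approximation to the full-cohort partial likelihood
whose accuracy is controlled by the batch size.

Everything is plain numpy with analytic gradients and an Adam optimiser with
decoupled weight decay; risk states are shift-invariant per endpoint, so only
score differences matter downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Mapping

import numpy as np
import scipy.sparse as sp

__all__ = [
    "ModelConfig",
    "MultitaskCoxPH",
    "MultitaskCoxPHResults",
    "RiskNetwork",
    "multitask_cox_loss",
    "train_risk_model",
    "predict_risk_states",
    "save_checkpoint",
    "load_checkpoint",
]

_LEAK = 0.01
_LN_EPS = 1e-5


@dataclass
class ModelConfig:
    """Network and optimiser settings.

    The production-scale reference uses three hidden layers of 4096 units,
    batch size 512, learning rate 6e-4 and weight decay 0.3; the desk-scale
    default narrows the layers to 128 units, keeping the shape.
    """

    n_hidden_layers: int = 3
    hidden_units: int = 128
    dropout: float = 0.1
    variant: str = "mlp"  # or "linear"
    batch_size: int = 512
    learning_rate: float = 6e-4
    weight_decay: float = 0.3
    max_epochs: int = 50
    patience: int = 5
    mask_prior_events: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.variant not in ("mlp", "linear"):
            raise ValueError("variant must be 'mlp' or 'linear'")
        if self.n_hidden_layers < 1 or self.hidden_units < 1 or self.batch_size < 1:
            raise ValueError("dimensions must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def multitask_cox_loss(
    scores: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    loss_mask: np.ndarray | None = None,
    return_grad: bool = False,
):
    """Adapted Cox partial-likelihood loss over in-batch risk sets.

    Per endpoint j the loss is the negative log partial likelihood, averaged
    over the endpoint's in-batch events i:

        L_j = -(1/E_j) sum_i [ s_ij - log sum_{k: t_kj >= t_ij} exp(s_kj) ]

    with tied event times sharing the full tied risk set (Breslow).  The
    total loss sums L_j over endpoints; an endpoint with no in-batch event
    contributes exactly zero.  ``loss_mask`` (batch x endpoints, True =
    include) drops individuals from an endpoint's likelihood entirely.

    Returns (total, per_endpoint) or (total, per_endpoint, grad) where grad
    has the shape of ``scores``.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if scores.ndim != 2:
        raise ValueError("scores must be batch x endpoints")
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite scores passed to the loss")
    if np.any(times <= 0):
        raise ValueError("times must be strictly positive")
    B, J = scores.shape
    if B < 1:
        raise ValueError("batch must contain at least one individual")
    per_endpoint = np.zeros(J)
    grad = np.zeros_like(scores) if return_grad else None

    for j in range(J):
        incl = np.ones(B, dtype=bool) if loss_mask is None else loss_mask[:, j].astype(bool)
        idx = np.flatnonzero(incl)
        if idx.size == 0:
            continue
        t, e = times[idx, j], events[idx, j]
        n_events = int(e.sum())
        if n_events == 0:
            continue
        s = scores[idx, j]
        s = s - s.max()  # shift-invariant; stabilises exp
        order = np.argsort(-t, kind="stable")  # descending time
        t_o, e_o, s_o = t[order], e[order], s[order]
        log_cum = np.logaddexp.accumulate(s_o)
        # risk set of event at time t_i = first r entries with t_o >= t_i
        r = np.searchsorted(-t_o, -t_o, side="right")
        ev = np.flatnonzero(e_o)
        lse = log_cum[r[ev] - 1]
        per_endpoint[j] = -(s_o[ev] - lse).mean()
        if return_grad:
            inv_S = np.zeros(idx.size)
            np.add.at(inv_S, r[ev] - 1, np.exp(-lse))
            R = np.cumsum(inv_S[::-1])[::-1]  # sum over events with risk set covering p
            g_o = -(e_o.astype(float) - np.exp(s_o) * R) / n_events
            g = np.zeros(idx.size)
            g[order] = g_o
            grad[idx, j] = g

    total = float(per_endpoint.sum())
    if return_grad:
        return total, per_endpoint, grad
    return total, per_endpoint


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class RiskNetwork:
    """Numpy MLP: [linear -> layer-norm -> dropout -> leaky-ReLU] x L -> linear."""

    def __init__(self, n_features: int, n_endpoints: int, config: ModelConfig):
        config.validate()
        self.config = config
        self.n_features = n_features
        self.n_endpoints = n_endpoints
        rng = np.random.default_rng([config.seed, 11])
        self.params: dict[str, np.ndarray] = {}
        dims = [n_features]
        if config.variant == "mlp":
            dims += [config.hidden_units] * config.n_hidden_layers
        dims += [n_endpoints]
        self.dims = dims
        for li in range(len(dims) - 1):
            fan_in = dims[li]
            self.params[f"W{li}"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(fan_in, dims[li + 1])
            ).astype(np.float64)
            self.params[f"b{li}"] = np.zeros(dims[li + 1])
            if li < len(dims) - 2:  # hidden layers carry layer-norm params
                self.params[f"g{li}"] = np.ones(dims[li + 1])
                self.params[f"beta{li}"] = np.zeros(dims[li + 1])

    @property
    def n_hidden(self) -> int:
        return len(self.dims) - 2

    def forward(
        self, X: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, list]:
        caches = []
        h = X
        p = self.config.dropout
        for li in range(self.n_hidden):
            z = h @ self.params[f"W{li}"] + self.params[f"b{li}"]
            mu = z.mean(axis=1, keepdims=True)
            var = z.var(axis=1, keepdims=True)
            inv = 1.0 / np.sqrt(var + _LN_EPS)
            zhat = (z - mu) * inv
            a = zhat * self.params[f"g{li}"] + self.params[f"beta{li}"]
            if train and p > 0:
                mask = (rng.random(a.shape) >= p) / (1.0 - p)
                a = a * mask
            else:
                mask = None
            out = np.where(a > 0, a, _LEAK * a)
            caches.append((h, z, zhat, inv, mask, a))
            h = out
        lf = self.n_hidden
        scores = h @ self.params[f"W{lf}"] + self.params[f"b{lf}"]
        caches.append((h,))
        return scores, caches

    def backward(self, dscores: np.ndarray, caches: list) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        lf = self.n_hidden
        (h_last,) = caches[-1]
        grads[f"W{lf}"] = h_last.T @ dscores
        grads[f"b{lf}"] = dscores.sum(axis=0)
        dh = dscores @ self.params[f"W{lf}"].T
        for li in range(self.n_hidden - 1, -1, -1):
            h_in, z, zhat, inv, mask, a = caches[li]
            da = dh * np.where(a > 0, 1.0, _LEAK)
            if mask is not None:
                da = da * mask
            grads[f"g{li}"] = (da * zhat).sum(axis=0)
            grads[f"beta{li}"] = da.sum(axis=0)
            dzhat = da * self.params[f"g{li}"]
            D = z.shape[1]
            dz = inv * (
                dzhat
                - dzhat.mean(axis=1, keepdims=True)
                - zhat * (dzhat * zhat).mean(axis=1, keepdims=True)
            )
            grads[f"W{li}"] = h_in.T @ dz
            grads[f"b{li}"] = dz.sum(axis=0)
            if li > 0:
                dh = dz @ self.params[f"W{li}"].T
        return grads

    def predict(self, X, chunk: int = 4096) -> np.ndarray:
        """Deterministic inference (dropout off); preserves row order."""
        if sp.issparse(X):
            X = np.asarray(X.todense(), dtype=np.float64)
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"record matrix has {X.shape[1]} concepts; model expects {self.n_features}"
            )
        out = np.empty((X.shape[0], self.n_endpoints))
        for start in range(0, X.shape[0], chunk):
            s, _ = self.forward(X[start : start + chunk], train=False)
            out[start : start + chunk] = s
        return out

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: Mapping[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = params[k].copy()


class _Adam:
    """Adam with decoupled weight decay on the weight matrices."""

    def __init__(self, params: dict[str, np.ndarray], lr: float, weight_decay: float):
        self.lr, self.wd = lr, weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if k.startswith("W"):
                params[k] -= self.lr * self.wd * params[k]


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

def _dense(X) -> np.ndarray:
    if sp.issparse(X):
        return np.asarray(X.todense(), dtype=np.float64)
    return np.asarray(X, dtype=np.float64)


class MultitaskCoxPH:
    """Multi-task proportional-hazards network, built from training data.

    Parameters
    ----------
    records : (n, C) binary matrix (dense or sparse) of pre-recruitment
        concepts; the model input.
    times, events : (n, J) follow-up outcomes per endpoint.
    prior_events : optional (n, J) bool; with ``mask_prior_events`` on, an
        individual's contribution to an endpoint's likelihood is dropped if
        they already carry the endpoint.  Training otherwise uses everyone
        (exclusions apply downstream, not here).
    val : optional (records, times, events[, prior_events]) tuple; when
        omitted, a seeded 10% split of the training rows is held out for
        checkpoint selection.
    """

    def __init__(
        self,
        records,
        times: np.ndarray,
        events: np.ndarray,
        config: ModelConfig | None = None,
        prior_events: np.ndarray | None = None,
        val: tuple | None = None,
    ):
        self.config = config or ModelConfig()
        self.config.validate()
        self.X = _dense(records)
        self.times = np.asarray(times, dtype=float)
        self.events = np.asarray(events, dtype=bool)
        self.prior_events = None if prior_events is None else np.asarray(prior_events, bool)
        if self.X.shape[0] != self.times.shape[0]:
            raise ValueError("records and outcomes disagree on the number of individuals")
        if val is not None:
            vX, vt, ve = val[0], val[1], val[2]
            vp = val[3] if len(val) > 3 else None
            self._val = (_dense(vX), np.asarray(vt, float), np.asarray(ve, bool), vp)
            self._train_idx = np.arange(self.X.shape[0])
        else:
            rng = np.random.default_rng([self.config.seed, 13])
            n = self.X.shape[0]
            perm = rng.permutation(n)
            n_val = max(1, int(round(0.1 * n)))
            val_idx, train_idx = perm[:n_val], perm[n_val:]
            vp = None if self.prior_events is None else self.prior_events[val_idx]
            self._val = (self.X[val_idx], self.times[val_idx], self.events[val_idx], vp)
            self._train_idx = train_idx

    def _loss_mask(self, prior: np.ndarray | None, shape) -> np.ndarray | None:
        if not self.config.mask_prior_events or prior is None:
            return None
        return ~prior

    def fit(self, verbose: bool = False) -> "MultitaskCoxPHResults":
        cfg = self.config
        net = RiskNetwork(self.X.shape[1], self.times.shape[1], cfg)
        opt = _Adam(net.params, cfg.learning_rate, cfg.weight_decay)
        rng = np.random.default_rng([cfg.seed, 17])
        Xtr = self.X[self._train_idx]
        ttr = self.times[self._train_idx]
        etr = self.events[self._train_idx]
        ptr = None if self.prior_events is None else self.prior_events[self._train_idx]
        vX, vt, ve, vp = self._val
        n = Xtr.shape[0]

        def val_loss() -> float:
            s = net.predict(vX)
            total, _ = multitask_cox_loss(s, vt, ve, self._loss_mask(vp, s.shape))
            return total

        history = {"train_loss": [], "val_loss": [], "selected_epoch": 0}
        best_val = val_loss()
        history["init_val_loss"] = best_val
        best_params = net.copy_params()
        bad_epochs = 0
        max_epochs = 1 if cfg.patience == 0 else cfg.max_epochs
        for epoch in range(1, max_epochs + 1):
            perm = rng.permutation(n)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, n, cfg.batch_size):
                bi = perm[start : start + cfg.batch_size]
                if bi.size < 2:
                    continue
                scores, caches = net.forward(Xtr[bi], train=True, rng=rng)
                mask = self._loss_mask(None if ptr is None else ptr[bi], scores.shape)
                total, _, gscores = multitask_cox_loss(
                    scores, ttr[bi], etr[bi], mask, return_grad=True
                )
                if not np.isfinite(total):
                    raise FloatingPointError(
                        f"training diverged at epoch {epoch} (non-finite loss)"
                    )
                grads = net.backward(gscores, caches)
                opt.step(net.params, grads)
                epoch_loss += total
                n_batches += 1
            vloss = val_loss()
            history["train_loss"].append(epoch_loss / max(n_batches, 1))
            history["val_loss"].append(vloss)
            if verbose:
                print(f"epoch {epoch}: train {history['train_loss'][-1]:.4f} val {vloss:.4f}")
            if vloss < best_val - 1e-9 or (cfg.patience == 0 and epoch == 1):
                best_val = vloss
                best_params = net.copy_params()
                history["selected_epoch"] = epoch
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs > cfg.patience:
                    break
        net.set_params(best_params)
        history["best_val_loss"] = best_val
        return MultitaskCoxPHResults(self, net, history)


class MultitaskCoxPHResults:
    """Fitted network: selected checkpoint, history, prediction, summary."""

    def __init__(self, model: MultitaskCoxPH, network: RiskNetwork, history: dict):
        self.model = model
        self.network = network
        self.history = history

    def predict(self, records) -> np.ndarray:
        """Risk-state matrix (log partial hazards), rows preserved."""
        return self.network.predict(records if not sp.issparse(records) else records)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Multi-task proportional-hazards network",
            "=" * 45,
            f"variant:           {cfg.variant}",
            f"input concepts:    {self.network.n_features}",
            f"endpoints:         {self.network.n_endpoints}",
            f"hidden layers:     {self.network.n_hidden} x {cfg.hidden_units}"
            if cfg.variant == "mlp"
            else "hidden layers:     none (linear)",
            f"parameters:        {sum(v.size for v in self.network.params.values()):,}",
            f"epochs run:        {len(self.history['train_loss'])}",
            f"selected epoch:    {self.history['selected_epoch']}",
            f"init val loss:     {self.history['init_val_loss']:.4f}",
            f"best val loss:     {self.history['best_val_loss']:.4f}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# spec-surface functions and checkpoints
# ---------------------------------------------------------------------------

def train_risk_model(
    config: ModelConfig, train_data: tuple, val_data: tuple
) -> tuple[MultitaskCoxPHResults, dict]:
    """Train on (records, times, events[, prior]) tuples with explicit val set."""
    model = MultitaskCoxPH(
        train_data[0],
        train_data[1],
        train_data[2],
        config=config,
        prior_events=train_data[3] if len(train_data) > 3 else None,
        val=val_data,
    )
    res = model.fit()
    return res, res.history


def predict_risk_states(results: MultitaskCoxPHResults | RiskNetwork, records) -> np.ndarray:
    net = results.network if isinstance(results, MultitaskCoxPHResults) else results
    return net.predict(records)


def save_checkpoint(
    path,
    results: MultitaskCoxPHResults,
    concept_ids: np.ndarray,
    endpoint_ids: np.ndarray,
) -> None:
    """Persist weights with config and concept/endpoint ordering."""
    net = results.network
    meta = {
        "config": asdict(results.model.config),
        "concept_ids": [str(c) for c in concept_ids],
        "endpoint_ids": [str(e) for e in endpoint_ids],
        "history": {
            k: v for k, v in results.history.items() if not isinstance(v, np.ndarray)
        },
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **net.params)


def load_checkpoint(path) -> tuple[RiskNetwork, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = ModelConfig(**meta["config"])
        net = RiskNetwork(
            n_features=len(meta["concept_ids"]),
            n_endpoints=len(meta["endpoint_ids"]),
            config=cfg,
        )
        net.set_params({k: data[k] for k in net.params})
    return net, meta
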