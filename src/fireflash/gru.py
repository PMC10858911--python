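"""GRU recurrent classifier for variable-length binary flash sequences.

The recurrent core is the standard gated recurrent unit: at each timestep the
hidden state is updated from the current input bit and the previous hidden
state through reset and update gates,

    r_t = sigmoid(W_xr x_t + W_hr h_{t-1} + b_r)
    z_t = sigmoid(W_xz x_t + W_hz h_{t-1} + b_z)
    n_t = tanh(W_xn x_t + b_xn + r_t * (W_hn h_{t-1} + b_hn))
    h_t = (1 - z_t) * n_t + z_t * h_{t-1}

Each sequence bit is fed as a one-dimensional input; no handcrafted features
enter the network. The classifier stacks two GRU layers of 128 units, applies
a LeakyReLU (negative slope 0.1) to the final hidden state and reads out
species logits through a single affine map, softmaxed into probabilities.

Training minimizes cross-entropy with Adam, global-norm gradient clipping and
early stopping on validation loss. Everything — forward, backpropagation
through time, the optimizer — is implemented here in NumPy; gradients are
verified against finite differences in the test suite. Variable-length
batches are right-padded with an explicit mask that freezes the hidden state
past each sequence's end, so batched and unbatched passes agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from fireflash.baselines import ClassifierOutput, softmax
from fireflash.sequences import FlashSequence, SequenceDataset


@dataclass
class GRUConfig:
    """Hyperparameters of the GRU classifier (defaults follow the study protocol)."""

    n_layers: int = 2
    hidden_dim: int = 128
    dropout: float = 0.0
    activation_negative_slope: float = 0.1
    batch_size: int = 8
    learning_rate: float = 1e-5
    early_stop_patience: int = 50
    grad_clip_norm: float = 0.1
    max_epochs: int = 1000
    n_species: int = 2
    seed: int = 0

    def __post_init__(self):
        for name in ("n_layers", "hidden_dim", "batch_size", "learning_rate",
                     "early_stop_patience", "grad_clip_norm", "max_epochs",
                     "n_species"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dropout != 0.0:
            raise ValueError("dropout is fixed at 0 in this architecture")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _init_params(config: GRUConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Uniform(-1/sqrt(H), 1/sqrt(H)) initialization, per-layer gate blocks (r,z,n)."""
    H = config.hidden_dim
    k = 1.0 / np.sqrt(H)
    params: dict[str, np.ndarray] = {}
    for layer in range(config.n_layers):
        d_in = 1 if layer == 0 else H
        params[f"Wx{layer}"] = rng.uniform(-k, k, size=(d_in, 3 * H))
        params[f"Wh{layer}"] = rng.uniform(-k, k, size=(H, 3 * H))
        params[f"bx{layer}"] = rng.uniform(-k, k, size=3 * H)
        params[f"bh{layer}"] = rng.uniform(-k, k, size=3 * H)
    params["Wo"] = rng.uniform(-k, k, size=(H, config.n_species))
    params["bo"] = rng.uniform(-k, k, size=config.n_species)
    return params


def _layer_forward(X: np.ndarray, mask: np.ndarray, Wx, Wh, bx, bh):
    """One GRU layer over a padded batch.

    X: (B, T, D) inputs; mask: (B, T) with 1 inside each sequence. Past a
    sequence's end the hidden state is held constant, so the state at the
    last timestep equals the state at the sequence's true end.
    """
    B, T, _ = X.shape
    H = Wh.shape[0]
    h = np.zeros((B, H))
    Gx = X @ Wx + bx  # (B, T, 3H)
    outputs = np.empty((B, T, H))
    cache = []
    for t in range(T):
        gh = h @ Wh + bh
        rx, zx, nx = Gx[:, t, :H], Gx[:, t, H:2 * H], Gx[:, t, 2 * H:]
        rh, zh, nh = gh[:, :H], gh[:, H:2 * H], gh[:, 2 * H:]
        r = _sigmoid(rx + rh)
        z = _sigmoid(zx + zh)
        n = np.tanh(nx + r * nh)
        hc = (1.0 - z) * n + z * h
        m = mask[:, t:t + 1]
        h_new = m * hc + (1.0 - m) * h
        cache.append((h, r, z, n, nh))
        outputs[:, t] = h_new
        h = h_new
    return outputs, cache


def _layer_backward(d_out: np.ndarray, X: np.ndarray, mask: np.ndarray,
                    cache, Wx, Wh):
    """Backpropagation through time for one GRU layer.

    d_out: (B, T, H) gradients w.r.t. the layer's (masked) outputs.
    Returns (dX, dWx, dWh, dbx, dbh).
    """
    B, T, H = d_out.shape
    dGx = np.zeros((B, T, 3 * H))
    dWh = np.zeros_like(Wh)
    dbh = np.zeros(3 * H)
    dh = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        dh = dh + d_out[:, t]
        h_prev, r, z, n, nh = cache[t]
        m = mask[:, t:t + 1]
        dhc = dh * m
        dh_prev = dh * (1.0 - m)
        dn = dhc * (1.0 - z)
        dz = dhc * (h_prev - n)
        dh_prev = dh_prev + dhc * z
        dan = dn * (1.0 - n * n)
        dr = dan * nh
        dnh = dan * r
        daz = dz * z * (1.0 - z)
        dar = dr * r * (1.0 - r)
        dgh = np.concatenate([dar, daz, dnh], axis=1)
        dWh += h_prev.T @ dgh
        dbh += dgh.sum(axis=0)
        dh_prev = dh_prev + dgh @ Wh.T
        dGx[:, t, :H] = dar
        dGx[:, t, H:2 * H] = daz
        dGx[:, t, 2 * H:] = dan
        dh = dh_prev
    D = X.shape[2]
    dWx = X.reshape(B * T, D).T @ dGx.reshape(B * T, 3 * H)
    dbx = dGx.sum(axis=(0, 1))
    dX = dGx @ Wx.T
    return dX, dWx, dWh, dbx, dbh


def _leaky(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


def _pad_batch(seqs: Sequence[FlashSequence]):
    lengths = np.array([len(s) for s in seqs])
    T = int(lengths.max())
    B = len(seqs)
    X = np.zeros((B, T, 1))
    mask = np.zeros((B, T))
    for i, s in enumerate(seqs):
        X[i, :len(s), 0] = s.bits
        mask[i, :len(s)] = 1.0
    return X, mask


class GRUClassifier:
    """Two-layer GRU species classifier with an sklearn-like fit/predict surface."""

    CHECKPOINT_VERSION = 1

    def __init__(self, config: GRUConfig | None = None):
        self.config = config or GRUConfig()
        self.params: dict[str, np.ndarray] | None = None
        self.label_map: dict[str, int] | None = None
        self.history: dict[str, list[float]] = {}
        self.best_epoch: int | None = None

    # ------------------------------------------------------------------ forward

    def _forward_batch(self, seqs: Sequence[FlashSequence], params=None,
                       with_cache: bool = False):
        params = params if params is not None else self.params
        X, mask = _pad_batch(seqs)
        layer_in = X
        caches = []
        inputs = []
        for layer in range(self.config.n_layers):
            inputs.append(layer_in)
            out, cache = _layer_forward(layer_in, mask,
                                        params[f"Wx{layer}"], params[f"Wh{layer}"],
                                        params[f"bx{layer}"], params[f"bh{layer}"])
            caches.append(cache)
            layer_in = out
        h_final = layer_in[:, -1]  # mask freezes h past each sequence's end
        act = _leaky(h_final, self.config.activation_negative_slope)
        logits = act @ params["Wo"] + params["bo"]
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs = e / e.sum(axis=1, keepdims=True)
        if with_cache:
            return h_final, logits, probs, (X, mask, inputs, caches, layer_in, act)
        return h_final, logits, probs

    def forward_sequence(self, seq: FlashSequence):
        """Run one sequence; returns (hidden trajectory, logits, probabilities).

        The hidden trajectory is the last layer's hidden state at every
        timestep, shape (T, hidden_dim); logits and probabilities are the
        readout of the final hidden state.
        """
        if self.params is None:
            raise ValueError("model is not trained")
        if len(seq) == 0:
            raise ValueError("sequence must be non-empty")
        X, mask = _pad_batch([seq])
        layer_in = X
        for layer in range(self.config.n_layers):
            layer_in, _ = _layer_forward(layer_in, mask,
                                         self.params[f"Wx{layer}"],
                                         self.params[f"Wh{layer}"],
                                         self.params[f"bx{layer}"],
                                         self.params[f"bh{layer}"])
        hidden_traj = layer_in[0]
        act = _leaky(hidden_traj[-1], self.config.activation_negative_slope)
        logits = act @ self.params["Wo"] + self.params["bo"]
        return hidden_traj, logits, softmax(logits)

    # ----------------------------------------------------------------- training

    def _loss_and_grads(self, seqs, labels, params):
        h_final, logits, probs, ctx = self._forward_batch(seqs, params,
                                                          with_cache=True)
        X, mask, inputs, caches, top_out, act = ctx
        B = len(seqs)
        loss = -float(np.mean(np.log(probs[np.arange(B), labels] + 1e-300)))
        dlogits = probs.copy()
        dlogits[np.arange(B), labels] -= 1.0
        dlogits /= B
        grads = {
            "Wo": act.T @ dlogits,
            "bo": dlogits.sum(axis=0),
        }
        dact = dlogits @ params["Wo"].T
        slope = self.config.activation_negative_slope
        dh_final = dact * np.where(h_final >= 0, 1.0, slope)
        d_out = np.zeros_like(top_out)
        d_out[:, -1] = dh_final
        for layer in range(self.config.n_layers - 1, -1, -1):
            dX, dWx, dWh, dbx, dbh = _layer_backward(
                d_out, inputs[layer], mask, caches[layer],
                params[f"Wx{layer}"], params[f"Wh{layer}"])
            grads[f"Wx{layer}"] = dWx
            grads[f"Wh{layer}"] = dWh
            grads[f"bx{layer}"] = dbx
            grads[f"bh{layer}"] = dbh
            d_out = dX
        return loss, grads

    @staticmethod
    def _clip_grads(grads: dict[str, np.ndarray], max_norm: float) -> float:
        total = float(np.sqrt(sum(float(np.sum(g * g)) for g in grads.values())))
        if total > max_norm and total > 0:
            scale = max_norm / total
            for g in grads.values():
                g *= scale
        return min(total, max_norm)

    def _dataset_loss(self, ds: SequenceDataset, params, chunk: int = 64) -> float:
        labels = np.array([self.label_map[s.species] for s in ds.sequences])
        total = 0.0
        for i in range(0, len(ds), chunk):
            seqs = ds.sequences[i:i + chunk]
            _, _, probs = self._forward_batch(seqs, params)
            idx = labels[i:i + chunk]
            total += -np.sum(np.log(probs[np.arange(len(seqs)), idx] + 1e-300))
        return float(total / len(ds))

    def fit(self, train: SequenceDataset, val: SequenceDataset) -> "GRUClassifier":
        """Train with Adam + cross-entropy, early-stopping on validation loss.

        Class counts are expected to be equalized upstream (see
        :func:`fireflash.experiments.stratified_folds`). Returns the model at
        the best-validation-loss epoch.
        """
        if len(train) == 0 or len(val) == 0:
            raise ValueError("train and val datasets must be non-empty")
        if train.label_map != val.label_map:
            raise ValueError("train and val must share one label map")
        cfg = self.config
        self.label_map = dict(train.label_map)
        if len(self.label_map) != cfg.n_species:
            cfg.n_species = len(self.label_map)
        rng = np.random.default_rng(cfg.seed)
        params = _init_params(cfg, rng)
        m_t = {k: np.zeros_like(v) for k, v in params.items()}
        v_t = {k: np.zeros_like(v) for k, v in params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        labels = train.labels()
        n = len(train)
        history: dict[str, list[float]] = {"train_loss": [], "val_loss": [],
                                           "grad_norm": []}
        best_val = np.inf
        best_params = {k: v.copy() for k, v in params.items()}
        best_epoch = 0
        since_best = 0
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            epoch_norm = 0.0
            n_batches = 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                seqs = [train.sequences[i] for i in idx]
                loss, grads = self._loss_and_grads(seqs, labels[idx], params)
                norm = self._clip_grads(grads, cfg.grad_clip_norm)
                step += 1
                for k in params:
                    m_t[k] = beta1 * m_t[k] + (1 - beta1) * grads[k]
                    v_t[k] = beta2 * v_t[k] + (1 - beta2) * grads[k] ** 2
                    m_hat = m_t[k] / (1 - beta1 ** step)
                    v_hat = v_t[k] / (1 - beta2 ** step)
                    params[k] -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
                epoch_loss += loss
                epoch_norm += norm
                n_batches += 1
            self.params = params
            val_loss = self._dataset_loss(val, params)
            history["train_loss"].append(epoch_loss / n_batches)
            history["val_loss"].append(val_loss)
            history["grad_norm"].append(epoch_norm / n_batches)
            if val_loss < best_val:
                best_val = val_loss
                best_params = {k: v.copy() for k, v in params.items()}
                best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
                if since_best >= cfg.early_stop_patience:
                    break
        self.params = best_params
        self.history = history
        self.best_epoch = best_epoch
        return self

    # ---------------------------------------------------------------- inference

    def predict_proba(self, ds: SequenceDataset | Sequence[FlashSequence],
                      chunk: int = 64) -> np.ndarray:
        if self.params is None:
            raise ValueError("model is not trained")
        seqs = ds.sequences if isinstance(ds, SequenceDataset) else list(ds)
        out = np.empty((len(seqs), self.config.n_species))
        for i in range(0, len(seqs), chunk):
            _, _, probs = self._forward_batch(seqs[i:i + chunk])
            out[i:i + len(probs)] = probs
        return out

    def predict(self, ds: SequenceDataset | Sequence[FlashSequence]) -> list[ClassifierOutput]:
        """Per-sequence probabilities and arg-max species; deterministic."""
        probs = self.predict_proba(ds)
        species = sorted(self.label_map, key=self.label_map.get)
        out = []
        for p in probs:
            p = p / p.sum()
            out.append(ClassifierOutput(dict(zip(species, p)),
                                        species[int(np.argmax(p))]))
        return out

    def hidden_embedding(self, ds: SequenceDataset | Sequence[FlashSequence],
                         chunk: int = 64) -> np.ndarray:
        """Final-timestep hidden state of the last GRU layer, (n, hidden_dim)."""
        if self.params is None:
            raise ValueError("model is not trained")
        seqs = ds.sequences if isinstance(ds, SequenceDataset) else list(ds)
        out = np.empty((len(seqs), self.config.hidden_dim))
        for i in range(0, len(seqs), chunk):
            h, _, _ = self._forward_batch(seqs[i:i + chunk])
            out[i:i + len(h)] = h
        return out

    # -------------------------------------------------------------- persistence

    def save(self, path) -> None:
        """Single-file .npz checkpoint: version, config, label map, params, history."""
        if self.params is None:
            raise ValueError("model is not trained")
        arrays = {f"param_{k}": v for k, v in self.params.items()}
        for k, v in self.history.items():
            arrays[f"history_{k}"] = np.asarray(v)
        np.savez(
            path,
            checkpoint_version=self.CHECKPOINT_VERSION,
            config_json=np.array(repr(asdict(self.config))),
            species=np.array(sorted(self.label_map, key=self.label_map.get)),
            best_epoch=-1 if self.best_epoch is None else self.best_epoch,
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "GRUClassifier":
        import ast

        data = np.load(path, allow_pickle=False)
        if int(data["checkpoint_version"]) != cls.CHECKPOINT_VERSION:
            raise ValueError("unsupported checkpoint version")
        config = GRUConfig(**ast.literal_eval(str(data["config_json"])))
        model = cls(config)
        model.params = {k[len("param_"):]: data[k] for k in data.files
                        if k.startswith("param_")}
        model.history = {k[len("history_"):]: list(data[k]) for k in data.files
                         if k.startswith("history_")}
        species = [str(s) for s in data["species"]]
        model.label_map = {sp: i for i, sp in enumerate(species)}
        be = int(data["best_epoch"])
        model.best_epoch = None if be < 0 else be
        return model


def train_rnn(train: SequenceDataset, val: SequenceDataset,
              config: GRUConfig | None = None) -> GRUClassifier:
    """Functional wrapper: train a :class:`GRUClassifier` and return it."""
    config = config or GRUConfig()
    if train.label_map:
        config.n_species = len(train.label_map)
    return GRUClassifier(config).fit(train, val)


def gru_forward(seq: FlashSequence, model: GRUClassifier):
    """Forward one sequence: (hidden trajectory, logits, probabilities)."""
    return model.forward_sequence(seq)


def hidden_embedding(model: GRUClassifier, ds) -> np.ndarray:
    return model.hidden_embedding(ds)


def tsne_embed(matrix: np.ndarray, perplexity: float = 30.0,
               seed: int = 0) -> np.ndarray:
    """2-D t-SNE embedding of hidden states; deterministic under a fixed seed.

    Degenerate input (all rows identical) collapses to near-identical points;
    sklearn may emit warnings in that case.
    """
    from sklearn.manifold import TSNE

    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 3 * perplexity:
        raise ValueError("need at least 3 * perplexity rows for a stable embedding")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="pca")
    return tsne.fit_transform(matrix)
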