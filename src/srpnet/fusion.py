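"""Attention-fused dual-branch risk predictor.

The network runs two branches over the same normalized feature vector
``x`` of one subject:

* **Self-attention branch.**  Each feature becomes a token via a learned
  per-feature affine embedding ``t_j = x_j * e_j + u_j`` (width ``c``);
  single-head scaled dot-product attention ``softmax(Q K^T / sqrt(d_k)) V``
  with ``Q = T W_Q``, ``K = T W_K``, ``V = T W_V`` mixes the tokens, which
  are mean-pooled and projected to the shared embedding ``H_t``.  Tokens
  are features of one subject, so inference is batch-independent.
* **Fully connected branch.**  One ReLU hidden layer
  ``ReLU(W_1 x + b_1)`` projected to the shared embedding ``H_c``.

A learned gate scores each embedding through a shared attention vector,
``s = w_a . tanh(W_g H + b_g)``, and softmaxes the two scores per subject
into coefficients ``(a_t, a_c)`` with ``a_t + a_c = 1``.  The fused
embedding ``L(a_t H_t + a_c H_c)`` feeds a linear K-way softmax head
trained with cross-entropy under Adam.

Everything is plain numpy with hand-written gradients, so training is
bit-reproducible for a fixed seed on one machine.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .data import FeatureTable, LabelVector

GateMode = Literal["learned", "fcn_only", "attention_only"]


@dataclass
class FusionConfig:
    """Hyperparameters of the dual-branch network.

    ``embed_dim`` is the token width c, ``attention_dim`` the Q/K/V width,
    ``fcn_hidden`` the hidden layer width of the fully connected branch,
    and ``fusion_dim`` the shared embedding width of H_t and H_c.
    """

    embed_dim: int = 32
    attention_dim: int = 32
    fcn_hidden: int = 64
    fusion_dim: int = 32
    n_categories: int = 5
    learning_rate: float = 0.001
    epochs: int = 100
    batch_size: int = 256
    split_fraction: float = 0.8
    seed: int = 0
    class_weighted: bool = False

    def __post_init__(self) -> None:
        for name in ("embed_dim", "attention_dim", "fcn_hidden", "fusion_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_categories < 2:
            raise ValueError("need at least two categories")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie in (0, 1)")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FusionConfig":
        return cls(**json.loads(Path(path).read_text()))


def init_params(d_features: int, config: FusionConfig, rng: np.random.Generator) -> dict:
    """Glorot-style initialization of every learnable tensor."""
    c, q = config.embed_dim, config.attention_dim
    h, f, K = config.fcn_hidden, config.fusion_dim, config.n_categories
    d = d_features

    def glorot(shape):
        fan_in, fan_out = shape[-2], shape[-1]
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=shape)

    return {
        "E": rng.normal(0.0, 1.0 / np.sqrt(c), size=(d, c)),
        "U": rng.normal(0.0, 1.0 / np.sqrt(c), size=(d, c)),
        "Wq": glorot((c, q)),
        "Wk": glorot((c, q)),
        "Wv": glorot((c, q)),
        "Wtp": glorot((q, f)),
        "btp": np.zeros(f),
        "W1": glorot((d, h)),
        "b1": np.zeros(h),
        "W2": glorot((h, f)),
        "b2": np.zeros(f),
        "Wg": glorot((f, f)),
        "bg": np.zeros(f),
        "wa": rng.normal(0.0, 1.0 / np.sqrt(f), size=f),
        "WL": glorot((f, f)),
        "bL": np.zeros(f),
        "Wo": glorot((f, K)),
        "bo": np.zeros(K),
    }


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def self_attention(Xtok: np.ndarray, params: dict) -> np.ndarray:
    """Scaled dot-product self-attention over one subject's feature tokens.

    ``Xtok`` is (n_tokens, c) for a single subject or (B, n_tokens, c)
    batched.  Returns the mean-pooled, projected embedding H_t of width
    ``fusion_dim`` (per subject).
    """
    single = Xtok.ndim == 2
    T = Xtok[None] if single else Xtok
    if T.shape[-1] != params["Wq"].shape[0]:
        raise ValueError(
            f"token width {T.shape[-1]} does not match W_Q input dim {params['Wq'].shape[0]}"
        )
    Q = T @ params["Wq"]
    K = T @ params["Wk"]
    V = T @ params["Wv"]
    dk = Q.shape[-1]
    A = _softmax(Q @ K.transpose(0, 2, 1) / np.sqrt(dk), axis=-1)
    P = (A @ V).mean(axis=1)
    Ht = P @ params["Wtp"] + params["btp"]
    return Ht[0] if single else Ht


def fcn_forward(x: np.ndarray, params: dict) -> np.ndarray:
    """Fully connected branch: ReLU hidden layer projected to fusion width."""
    single = x.ndim == 1
    X = x[None] if single else x
    if X.shape[1] != params["W1"].shape[0]:
        raise ValueError(
            f"input width {X.shape[1]} does not match W_1 input dim {params['W1'].shape[0]}"
        )
    Hd = np.maximum(X @ params["W1"] + params["b1"], 0.0)
    Hc = Hd @ params["W2"] + params["b2"]
    return Hc[0] if single else Hc


def attention_fuse(
    Ht: np.ndarray, Hc: np.ndarray, params: dict, gate_mode: GateMode = "learned"
) -> tuple[np.ndarray, np.ndarray]:
    """Gate the two branch embeddings and apply the fusion linear layer.

    Returns ``(H, gates)`` where ``gates`` is (B, 2) holding (a_t, a_c)
    per subject with a_t + a_c = 1.
    """
    single = Ht.ndim == 1
    Ht2 = Ht[None] if single else Ht
    Hc2 = Hc[None] if single else Hc
    if Ht2.shape != Hc2.shape:
        raise ValueError(f"branch embeddings differ in shape: {Ht2.shape} vs {Hc2.shape}")
    if gate_mode == "learned":
        Zt = np.tanh(Ht2 @ params["Wg"] + params["bg"])
        Zc = np.tanh(Hc2 @ params["Wg"] + params["bg"])
        st = Zt @ params["wa"]
        sc = Zc @ params["wa"]
        at = 1.0 / (1.0 + np.exp(-(st - sc)))
    elif gate_mode == "fcn_only":
        at = np.zeros(Ht2.shape[0])
    elif gate_mode == "attention_only":
        at = np.ones(Ht2.shape[0])
    else:
        raise ValueError(f"unknown gate_mode {gate_mode!r}")
    ac = 1.0 - at
    M = at[:, None] * Ht2 + ac[:, None] * Hc2
    H = M @ params["WL"] + params["bL"]
    gates = np.column_stack([at, ac])
    return (H[0], gates[0]) if single else (H, gates)


def _forward(X: np.ndarray, params: dict, gate_mode: GateMode) -> dict:
    """Full forward pass with a cache for backprop.  X is (B, d)."""
    B, d = X.shape
    T = X[:, :, None] * params["E"][None] + params["U"][None]  # (B,d,c)
    Q = T @ params["Wq"]
    K = T @ params["Wk"]
    V = T @ params["Wv"]
    dk = Q.shape[-1]
    S = Q @ K.transpose(0, 2, 1) / np.sqrt(dk)
    A = _softmax(S, axis=-1)
    O = A @ V
    P = O.mean(axis=1)
    Ht = P @ params["Wtp"] + params["btp"]

    pre1 = X @ params["W1"] + params["b1"]
    Hd = np.maximum(pre1, 0.0)
    Hc = Hd @ params["W2"] + params["b2"]

    if gate_mode == "learned":
        Zt = np.tanh(Ht @ params["Wg"] + params["bg"])
        Zc = np.tanh(Hc @ params["Wg"] + params["bg"])
        st = Zt @ params["wa"]
        sc = Zc @ params["wa"]
        at = 1.0 / (1.0 + np.exp(-(st - sc)))
    else:
        Zt = Zc = None
        at = np.zeros(B) if gate_mode == "fcn_only" else np.ones(B)
    ac = 1.0 - at
    M = at[:, None] * Ht + ac[:, None] * Hc
    Hf = M @ params["WL"] + params["bL"]
    logits = Hf @ params["Wo"] + params["bo"]
    probs = _softmax(logits, axis=-1)
    return {
        "X": X, "T": T, "Q": Q, "K": K, "V": V, "A": A, "O": O, "P": P,
        "Ht": Ht, "Hd": Hd, "Hc": Hc, "Zt": Zt, "Zc": Zc,
        "at": at, "ac": ac, "M": M, "Hf": Hf, "logits": logits, "probs": probs,
        "dk": dk,
    }


def loss_and_grads(
    params: dict,
    X: np.ndarray,
    y: np.ndarray,
    gate_mode: GateMode = "learned",
    class_weights: np.ndarray | None = None,
) -> tuple[float, dict]:
    """Mean cross-entropy and its gradient w.r.t. every parameter."""
    cache = _forward(X, params, gate_mode)
    B = X.shape[0]
    probs = cache["probs"]
    eps = 1e-12
    if class_weights is None:
        w = np.ones(B)
    else:
        w = class_weights[y]
    wsum = w.sum()
    loss = float(-(w * np.log(probs[np.arange(B), y] + eps)).sum() / wsum)

    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits *= (w / wsum)[:, None]

    g: dict[str, np.ndarray] = {}
    Hf, M = cache["Hf"], cache["M"]
    g["Wo"] = Hf.T @ dlogits
    g["bo"] = dlogits.sum(axis=0)
    dHf = dlogits @ params["Wo"].T
    g["WL"] = M.T @ dHf
    g["bL"] = dHf.sum(axis=0)
    dM = dHf @ params["WL"].T

    Ht, Hc, at, ac = cache["Ht"], cache["Hc"], cache["at"], cache["ac"]
    dHt = at[:, None] * dM
    dHc = ac[:, None] * dM
    if gate_mode == "learned":
        dat = (dM * (Ht - Hc)).sum(axis=1)
        dst = dat * at * ac  # sigmoid'(st - sc)
        dsc = -dst
        Zt, Zc = cache["Zt"], cache["Zc"]
        g["wa"] = Zt.T @ dst + Zc.T @ dsc
        dZt = dst[:, None] * params["wa"][None]
        dZc = dsc[:, None] * params["wa"][None]
        dpre_t = dZt * (1.0 - Zt**2)
        dpre_c = dZc * (1.0 - Zc**2)
        g["Wg"] = Ht.T @ dpre_t + Hc.T @ dpre_c
        g["bg"] = dpre_t.sum(axis=0) + dpre_c.sum(axis=0)
        dHt = dHt + dpre_t @ params["Wg"].T
        dHc = dHc + dpre_c @ params["Wg"].T
    else:
        g["wa"] = np.zeros_like(params["wa"])
        g["Wg"] = np.zeros_like(params["Wg"])
        g["bg"] = np.zeros_like(params["bg"])

    # fully connected branch
    Hd, Xin = cache["Hd"], cache["X"]
    g["W2"] = Hd.T @ dHc
    g["b2"] = dHc.sum(axis=0)
    dHd = dHc @ params["W2"].T
    dpre1 = dHd * (Hd > 0)
    g["W1"] = Xin.T @ dpre1
    g["b1"] = dpre1.sum(axis=0)

    # attention branch
    P = cache["P"]
    g["Wtp"] = P.T @ dHt
    g["btp"] = dHt.sum(axis=0)
    dP = dHt @ params["Wtp"].T
    d = Xin.shape[1]
    dO = np.repeat(dP[:, None, :] / d, d, axis=1)
    A, V, Q, K = cache["A"], cache["V"], cache["Q"], cache["K"]
    dA = dO @ V.transpose(0, 2, 1)
    dV = A.transpose(0, 2, 1) @ dO
    dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
    sq = np.sqrt(cache["dk"])
    dQ = dS @ K / sq
    dK = dS.transpose(0, 2, 1) @ Q / sq
    T = cache["T"]
    g["Wq"] = np.einsum("bdc,bdq->cq", T, dQ)
    g["Wk"] = np.einsum("bdc,bdq->cq", T, dK)
    g["Wv"] = np.einsum("bdc,bdq->cq", T, dV)
    dT = dQ @ params["Wq"].T + dK @ params["Wk"].T + dV @ params["Wv"].T
    g["E"] = np.einsum("bd,bdc->dc", Xin, dT)
    g["U"] = dT.sum(axis=0)
    return loss, g


class _Adam:
    """Adam with bias correction; default betas/eps."""

    def __init__(self, params: dict, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, gk in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gk**2
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def stratified_split(
    y: np.ndarray, frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-category shuffled split; errors if a category misses the train side."""
    train, test = [], []
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        k = int(round(frac * idx.size))
        if k == 0:
            raise ValueError(
                f"category {cls} has too few subjects ({idx.size}) for a "
                f"{frac:.0%} training split"
            )
        train.append(idx[:k])
        test.append(idx[k:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


@dataclass
class TrainTrace:
    """Per-epoch mean training loss and held-out micro precision."""

    losses: list[float] = field(default_factory=list)
    heldout_precision: list[float] = field(default_factory=list)


class FusionClassifier:
    """Dual-branch attention-fusion model for a normalized cohort.

    Parameters
    ----------
    table : FeatureTable
        Normalized table restricted to the selected features.
    labels : LabelVector
        Risk category per subject.
    config : FusionConfig, optional
        Network and training hyperparameters; ``n_categories`` is aligned
        to the label vector automatically.
    gate_mode : {"learned", "fcn_only", "attention_only"}
        "fcn_only" forces a_t = 0 (ablates the attention branch);
        "attention_only" forces a_c = 0.

    Examples
    --------
    >>> model = FusionClassifier(table, labels, FusionConfig(epochs=50, seed=1))
    >>> res = model.fit()
    >>> res.summary()  # doctest: +SKIP
    """

    def __init__(
        self,
        table: FeatureTable,
        labels: LabelVector,
        config: FusionConfig | None = None,
        gate_mode: GateMode = "learned",
    ) -> None:
        if not table.normalized:
            raise ValueError("FusionClassifier expects a normalized table")
        if len(labels) != table.n_subjects:
            raise ValueError("table and labels disagree on the number of subjects")
        config = config or FusionConfig()
        if config.n_categories != labels.n_categories:
            config = FusionConfig(**{**asdict(config), "n_categories": labels.n_categories})
        self.table = table
        self.labels = labels
        self.config = config
        self.gate_mode: GateMode = gate_mode

    def fit(self, *, verbose: bool = False) -> "FusionResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        X = self.table.values
        y = self.labels.codes
        train_idx, test_idx = stratified_split(y, cfg.split_fraction, rng)
        Xtr, ytr = X[train_idx], y[train_idx]
        Xte, yte = X[test_idx], y[test_idx]

        params = init_params(X.shape[1], cfg, rng)
        opt = _Adam(params, cfg.learning_rate)
        weights = None
        if cfg.class_weighted:
            counts = np.bincount(ytr, minlength=cfg.n_categories).astype(float)
            weights = counts.sum() / np.maximum(counts, 1.0) / cfg.n_categories

        trace = TrainTrace()
        n = Xtr.shape[0]
        best_params = {k: v.copy() for k, v in params.items()}
        best_precision = -np.inf
        best_epoch = 0
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                loss, grads = loss_and_grads(
                    params, Xtr[batch], ytr[batch], self.gate_mode, weights
                )
                if not np.isfinite(loss):
                    raise FloatingPointError(f"non-finite loss at epoch {epoch}")
                opt.step(params, grads)
                epoch_loss += loss * batch.size
            trace.losses.append(epoch_loss / n)
            pred = _forward(Xte, params, self.gate_mode)["probs"].argmax(axis=1)
            trace.heldout_precision.append(float(np.mean(pred == yte)))
            # 100 is the maximum epoch count: the reported model is the
            # best held-out checkpoint seen along the way (ties -> earlier)
            if trace.heldout_precision[-1] > best_precision:
                best_precision = trace.heldout_precision[-1]
                best_params = {k: v.copy() for k, v in params.items()}
                best_epoch = epoch
            if verbose:
                print(
                    f"epoch {epoch + 1:3d}  loss {trace.losses[-1]:.4f}  "
                    f"held-out precision {trace.heldout_precision[-1]:.4f}"
                )
        return FusionResults(
            model=self, params=best_params, trace=trace,
            train_idx=train_idx, test_idx=test_idx, best_epoch=best_epoch,
        )


class FusionResults:
    """Fitted parameters, training trace, and prediction/evaluation helpers."""

    def __init__(
        self,
        model: FusionClassifier,
        params: dict,
        trace: TrainTrace,
        train_idx: np.ndarray,
        test_idx: np.ndarray,
        best_epoch: int = -1,
    ) -> None:
        self.model = model
        self.params = params
        self.trace = trace
        self.train_idx = train_idx
        self.test_idx = test_idx
        self.best_epoch = best_epoch

    @property
    def config(self) -> FusionConfig:
        return self.model.config

    @property
    def feature_names(self) -> list[str]:
        return self.model.table.feature_names

    def _check_table(self, table: FeatureTable) -> np.ndarray:
        if not table.normalized:
            raise ValueError("predict expects a table normalized with training statistics")
        if table.feature_names != self.feature_names:
            raise ValueError("table columns do not match the fitted features")
        return table.values

    def predict_proba(self, table: FeatureTable) -> np.ndarray:
        """Per-subject category probabilities (rows sum to 1)."""
        X = self._check_table(table)
        return _forward(X, self.params, self.model.gate_mode)["probs"]

    def predict(self, table: FeatureTable) -> np.ndarray:
        """Argmax category codes; ties resolve to the lowest index."""
        return self.predict_proba(table).argmax(axis=1)

    def gates(self, table: FeatureTable) -> np.ndarray:
        """Per-subject gate coefficients (a_t, a_c)."""
        X = self._check_table(table)
        cache = _forward(X, self.params, self.model.gate_mode)
        return np.column_stack([cache["at"], cache["ac"]])

    def heldout_table(self) -> tuple[FeatureTable, LabelVector]:
        """The 20% held-out rows of the training cohort."""
        t = self.model.table
        sub = FeatureTable(
            values=t.values[self.test_idx],
            feature_names=list(t.feature_names),
            feature_kinds=list(t.feature_kinds),
            normalized=True,
        )
        labs = LabelVector(
            codes=self.model.labels.codes[self.test_idx],
            category_names=list(self.model.labels.category_names),
        )
        return sub, labs

    def evaluate(self, table: FeatureTable | None = None, labels: LabelVector | None = None):
        """EvalReport on the given cohort (default: the held-out split)."""
        from .metrics import evaluate_predictions

        if table is None or labels is None:
            table, labels = self.heldout_table()
        probs = self.predict_proba(table)
        return evaluate_predictions(labels, probs, labels.category_names)

    @property
    def heldout_precision(self) -> float:
        """Held-out micro precision of the selected (best-epoch) checkpoint."""
        if not self.trace.heldout_precision:
            return float("nan")
        return self.trace.heldout_precision[self.best_epoch]

    def summary(self) -> str:
        cfg = self.config
        n_params = sum(v.size for v in self.params.values())
        heldout = self.heldout_precision
        lines = [
            "Attention-fusion risk classifier",
            "=" * 48,
            f"{'subjects (train/test)':30s} {self.train_idx.size}/{self.test_idx.size}",
            f"{'features':30s} {len(self.feature_names)}",
            f"{'categories':30s} {cfg.n_categories}",
            f"{'gate mode':30s} {self.model.gate_mode}",
            f"{'parameters':30s} {n_params}",
            f"{'epochs':30s} {cfg.epochs}",
            f"{'learning rate (Adam)':30s} {cfg.learning_rate}",
            f"{'selected epoch':30s} {self.best_epoch + 1}",
            f"{'final training loss':30s} {self.trace.losses[-1]:.4f}",
            f"{'held-out micro precision':30s} {heldout:.4f}",
            "=" * 48,
        ]
        return "\n".join(lines)

    def plot_trace(self, ax=None):
        """Loss / held-out precision curves (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        epochs = np.arange(1, len(self.trace.losses) + 1)
        ax.plot(epochs, self.trace.losses, label="training loss")
        ax2 = ax.twinx()
        ax2.plot(epochs, self.trace.heldout_precision, color="C1", label="held-out precision")
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss")
        ax2.set_ylabel("micro precision")
        return ax

    def save(self, checkpoint: str | Path) -> None:
        """Persist parameters (.npz) with a JSON sidecar of the configuration."""
        checkpoint = Path(checkpoint)
        np.savez(checkpoint, **self.params)
        sidecar = checkpoint.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "config": asdict(self.config),
                    "gate_mode": self.model.gate_mode,
                    "feature_names": self.feature_names,
                    "category_names": self.model.labels.category_names,
                },
                indent=2,
            )
        )

    @staticmethod
    def load_params(checkpoint: str | Path) -> tuple[dict, dict]:
        """Load (params, sidecar metadata) from a saved checkpoint."""
        checkpoint = Path(checkpoint)
        with np.load(checkpoint.with_suffix(".npz") if checkpoint.suffix != ".npz" else checkpoint) as z:
            params = {k: z[k] for k in z.files}
        meta = json.loads(checkpoint.with_suffix(".json").read_text())
        return params, meta
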