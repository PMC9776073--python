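"""Multi-band graph-convolution fusion classifier.

The model runs, per frequency band, a shallow and a deep Chebyshev graph
convolution over that band's binary causal adjacency, then fuses the four
band branches node-wise with learned non-negative weights constrained to
the probability simplex (softmax over four logits, so the constraint
holds exactly after every optimizer step):

    X_FS = p_theta X_S(theta) + p_alpha X_S(alpha) + p_beta X_S(beta) + p_gamma X_S(gamma)

with an independent weight vector for the deep branch.  Each fused tensor
passes ReLU and a dense layer to a common width; the shallow and deep
dense features are concatenated, mapped to class scores and normalized by
softmax, trained with cross-entropy.  Ablation variants use only the
shallow branch, only the deep branch, or replace the weighted fusion by a
plain concatenation of the band branches ("cascade").

The network is small (tens of thousands of parameters), so the forward
and backward passes are written directly in numpy and optimized with
Adam; the analytic gradients are validated against central finite
differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .graphcore import cheb_basis, laplacian, symmetrize
from .pipeline import GraphDataset


class FusionError(ValueError):
    pass


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    depth selects which graph branches feed the dense head: "shallow"
    (first convolution only), "deep" (second only) or "both"
    (concatenated).  fusion selects learned simplex weights ("fused") or
    band concatenation ("cascade").  The defaults give the full fused
    shallow+deep model.
    """

    cheb_K: int = 2
    d1: int = 16
    d2: int = 16
    fc1_dim: int = 32
    n_classes: int | None = None
    lr: float = 1e-3
    epochs: int = 100
    batch_size: int = 64
    seed: int = 0
    depth: str = "both"  # shallow | deep | both
    fusion: str = "fused"  # fused | cascade
    per_node_fusion: bool = False
    symmetrize_adjacency: str = "none"  # none | mean | binary
    lambda_max: float | str = "auto"
    standardize: bool = True
    weight_decay: float = 0.0

    def __post_init__(self) -> None:
        if self.depth not in {"shallow", "deep", "both"}:
            raise FusionError("depth must be shallow|deep|both")
        if self.fusion not in {"fused", "cascade"}:
            raise FusionError("fusion must be fused|cascade")
        if min(self.d1, self.d2, self.fc1_dim) <= 0 or self.cheb_K < 0:
            raise FusionError("dimensions must be positive and cheb_K >= 0")


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class FusionGCN:
    """Model object: a graph dataset plus a configuration.

    Built statsmodels-style: construct from data, call :meth:`fit` to get
    a :class:`FusionGCNResults` carrying the trained parameters,
    histories and evaluation helpers.
    """

    def __init__(self, dataset: GraphDataset, config: ModelConfig | None = None):
        self.dataset = dataset
        self.config = config or ModelConfig()
        if self.config.n_classes is None:
            self.config = replace(self.config, n_classes=dataset.n_classes)
        self.B = dataset.n_bands
        self.N = dataset.n_channels
        if self.config.fusion == "fused" and self.B != 4:
            raise FusionError(
                f"the fused variants require exactly 4 bands, got {self.B}"
            )
        self._T = self._cheb_tensors()

    # ---------------------------------------------------------------- setup
    def _cheb_tensors(self) -> np.ndarray:
        """T_k(L~) per (sample, band): shape (S, B, K+1, N, N)."""
        cfg = self.config
        S = len(self.dataset)
        out = np.empty((S, self.B, cfg.cheb_K + 1, self.N, self.N))
        for s in range(S):
            for b in range(self.B):
                A = self.dataset.adjacency[s, b]
                if cfg.symmetrize_adjacency != "none":
                    A = symmetrize(A, cfg.symmetrize_adjacency)
                bundle = laplacian(A, cfg.lambda_max)
                out[s, b] = cheb_basis(bundle.L_tilde, cfg.cheb_K)
        return out

    def prepare_inputs(
        self,
        idx: np.ndarray | None = None,
        mu: np.ndarray | None = None,
        sd: np.ndarray | None = None,
    ) -> dict:
        """Standardized node features premultiplied by the Chebyshev basis.

        Returns a dict with Spre (S,B,K+1,N,1), Tm (S,B,K+1,N,N) and
        labels y; mu/sd are per (band, channel) standardization constants
        (identity if the config disables standardization).
        """
        idx = np.arange(len(self.dataset)) if idx is None else np.asarray(idx)
        X = self.dataset.node_values[idx]  # (S, B, N)
        if mu is None:
            mu = np.zeros((self.B, self.N))
            sd = np.ones((self.B, self.N))
        Xz = ((X - mu) / sd)[..., None]  # (S, B, N, 1)
        Tm = self._T[idx]
        Spre = np.einsum("sbkmn,sbnf->sbkmf", Tm, Xz)
        return {"Spre": Spre, "Tm": Tm, "y": self.dataset.labels[idx]}

    def standardization(self, train_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = self.dataset.node_values[train_idx]
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        return mu, sd

    def init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        cfg = self.config
        B, N, K = self.B, self.N, cfg.cheb_K
        Fin = 1

        def glorot(*shape):
            fan_in, fan_out = shape[-2], shape[-1]
            s = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-s, s, size=shape)

        p: dict[str, np.ndarray] = {
            "thetaS": rng.normal(0.0, 1.0 / np.sqrt(K + 1), size=(B, K + 1)),
            "WS": glorot(B, Fin, cfg.d1),
        }
        use_deep = cfg.depth in {"deep", "both"}
        use_shallow_head = cfg.depth in {"shallow", "both"}
        if use_deep:
            p["thetaD"] = rng.normal(0.0, 1.0 / np.sqrt(K + 1), size=(B, K + 1))
            p["WD"] = glorot(B, cfg.d1, cfg.d2)
        if cfg.fusion == "fused":
            shape = (B, N) if cfg.per_node_fusion else (B,)
            if use_shallow_head:
                p["qS"] = np.zeros(shape)
            if use_deep:
                p["qD"] = np.zeros(shape)
        mult = 1 if cfg.fusion == "fused" else B
        if use_shallow_head:
            p["W1S"] = glorot(N * cfg.d1 * mult, cfg.fc1_dim)
            p["b1S"] = np.zeros(cfg.fc1_dim)
        if use_deep:
            p["W1D"] = glorot(N * cfg.d2 * mult, cfg.fc1_dim)
            p["b1D"] = np.zeros(cfg.fc1_dim)
        heads = (1 if cfg.depth != "both" else 2) * cfg.fc1_dim
        p["W2"] = glorot(heads, cfg.n_classes)
        p["b2"] = np.zeros(cfg.n_classes)
        return p

    # -------------------------------------------------------------- forward
    def _fuse(self, params, key, Xb):
        """Weighted simplex fusion or band concatenation of (s,b,n,d)."""
        cfg = self.config
        if cfg.fusion == "cascade":
            s, b, n, d = Xb.shape
            return Xb.transpose(0, 2, 1, 3).reshape(s, n, b * d), None
        q = params[key]
        if cfg.per_node_fusion:
            pw = _softmax(q, axis=0)  # (B, N)
            return np.einsum("bn,sbnd->snd", pw, Xb), pw
        pw = _softmax(q)  # (B,)
        return np.einsum("b,sbnd->snd", pw, Xb), pw

    def forward(self, params: dict, inputs: dict) -> tuple[np.ndarray, dict]:
        """Class probabilities and a cache of intermediates for backprop."""
        cfg = self.config
        Spre, Tm = inputs["Spre"], inputs["Tm"]
        cache: dict = {}
        U = np.einsum("bk,sbkmf->sbmf", params["thetaS"], Spre)
        XS = np.einsum("sbmf,bfd->sbmd", U, params["WS"])
        cache.update(U=U, XS=XS)
        use_deep = cfg.depth in {"deep", "both"}
        use_shallow_head = cfg.depth in {"shallow", "both"}
        feats = []
        if use_shallow_head:
            XFS, pS = self._fuse(params, "qS", XS)
            HS = _relu(XFS)
            hs = HS.reshape(HS.shape[0], -1)
            FS = hs @ params["W1S"] + params["b1S"]
            cache.update(XFS=XFS, pS=pS, hs=hs)
            feats.append(FS)
        if use_deep:
            TXS = np.einsum("sbkmn,sbnd->sbkmd", Tm, XS)
            V = np.einsum("bk,sbkmd->sbmd", params["thetaD"], TXS)
            XD = np.einsum("sbmd,bde->sbme", V, params["WD"])
            XFD, pD = self._fuse(params, "qD", XD)
            HD = _relu(XFD)
            hd = HD.reshape(HD.shape[0], -1)
            FD = hd @ params["W1D"] + params["b1D"]
            cache.update(TXS=TXS, V=V, XD=XD, XFD=XFD, pD=pD, hd=hd)
            feats.append(FD)
        head = np.concatenate(feats, axis=1) if len(feats) > 1 else feats[0]
        Z = head @ params["W2"] + params["b2"]
        probs = _softmax(Z, axis=1)
        cache.update(head=head, probs=probs)
        return probs, cache

    def loss(self, params: dict, inputs: dict) -> float:
        probs, _ = self.forward(params, inputs)
        y = inputs["y"]
        ll = -np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None)).mean()
        if self.config.weight_decay > 0:
            for key in ("WS", "WD", "W1S", "W1D", "W2"):
                if key in params:
                    ll += self.config.weight_decay * float(np.sum(params[key] ** 2))
        return float(ll)

    # ------------------------------------------------------------- backward
    def _fuse_backward(self, params, key, Xb, pw, dXF):
        """Gradients of the fusion step: (dXb, dq or None)."""
        cfg = self.config
        if cfg.fusion == "cascade":
            s, n, bd = dXF.shape
            b = self.B
            dXb = dXF.reshape(s, n, b, bd // b).transpose(0, 2, 1, 3)
            return dXb, None
        if cfg.per_node_fusion:
            dp = np.einsum("sbnd,snd->bn", Xb, dXF)
            dXb = np.einsum("bn,snd->sbnd", pw, dXF)
            dq = pw * (dp - (pw * dp).sum(axis=0, keepdims=True))
        else:
            dp = np.einsum("sbnd,snd->b", Xb, dXF)
            dXb = np.einsum("b,snd->sbnd", pw, dXF)
            dq = pw * (dp - float(pw @ dp))
        return dXb, dq

    def loss_and_grads(self, params: dict, inputs: dict) -> tuple[float, dict]:
        cfg = self.config
        Spre, Tm, y = inputs["Spre"], inputs["Tm"], inputs["y"]
        nb = len(y)
        probs, c = self.forward(params, inputs)
        loss = -np.log(np.clip(probs[np.arange(nb), y], 1e-12, None)).mean()

        grads = {k: np.zeros_like(v) for k, v in params.items()}
        dZ = probs.copy()
        dZ[np.arange(nb), y] -= 1.0
        dZ /= nb
        grads["W2"] = c["head"].T @ dZ
        grads["b2"] = dZ.sum(axis=0)
        dhead = dZ @ params["W2"].T

        use_deep = cfg.depth in {"deep", "both"}
        use_shallow_head = cfg.depth in {"shallow", "both"}
        f1 = cfg.fc1_dim
        if cfg.depth == "both":
            dFS, dFD = dhead[:, :f1], dhead[:, f1:]
        elif cfg.depth == "shallow":
            dFS, dFD = dhead, None
        else:
            dFS, dFD = None, dhead

        dXS = np.zeros_like(c["XS"])
        if use_shallow_head:
            grads["W1S"] = c["hs"].T @ dFS
            grads["b1S"] = dFS.sum(axis=0)
            dhs = dFS @ params["W1S"].T
            dXFS = dhs.reshape(c["XFS"].shape) * (c["XFS"] > 0)
            dXS_f, dqS = self._fuse_backward(params, "qS", c["XS"], c["pS"], dXFS)
            dXS += dXS_f
            if dqS is not None:
                grads["qS"] = dqS
        if use_deep:
            grads["W1D"] = c["hd"].T @ dFD
            grads["b1D"] = dFD.sum(axis=0)
            dhd = dFD @ params["W1D"].T
            dXFD = dhd.reshape(c["XFD"].shape) * (c["XFD"] > 0)
            dXD, dqD = self._fuse_backward(params, "qD", c["XD"], c["pD"], dXFD)
            if dqD is not None:
                grads["qD"] = dqD
            grads["WD"] = np.einsum("sbmd,sbme->bde", c["V"], dXD)
            dV = np.einsum("sbme,bde->sbmd", dXD, params["WD"])
            grads["thetaD"] = np.einsum("sbkmd,sbmd->bk", c["TXS"], dV)
            dXS += np.einsum("bk,sbkmn,sbmd->sbnd", params["thetaD"], Tm, dV)

        grads["WS"] = np.einsum("sbmf,sbmd->bfd", c["U"], dXS)
        dU = np.einsum("sbmd,bfd->sbmf", dXS, params["WS"])
        grads["thetaS"] = np.einsum("sbkmf,sbmf->bk", Spre, dU)

        if cfg.weight_decay > 0:
            for key in ("WS", "WD", "W1S", "W1D", "W2"):
                if key in params:
                    loss += cfg.weight_decay * float(np.sum(params[key] ** 2))
                    grads[key] += 2.0 * cfg.weight_decay * params[key]
        return float(loss), grads

    # ------------------------------------------------------------------ fit
    def fit(
        self,
        train_idx: np.ndarray | None = None,
        val_idx: np.ndarray | None = None,
    ) -> "FusionGCNResults":
        """Train with Adam; deterministic given the config seed.

        Returns a results object carrying the trained parameters, the
        per-epoch loss, the fusion-weight trajectory recorded after every
        optimizer step, and (if ``val_idx`` is given) validation accuracy.
        """
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        train_idx = np.arange(len(self.dataset)) if train_idx is None else np.asarray(train_idx)
        if cfg.standardize:
            mu, sd = self.standardization(train_idx)
        else:
            mu = np.zeros((self.B, self.N))
            sd = np.ones((self.B, self.N))
        inputs = self.prepare_inputs(train_idx, mu, sd)
        params = self.init_params(rng)

        m = {k: np.zeros_like(v) for k, v in params.items()}
        v = {k: np.zeros_like(v_) for k, v_ in params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        n = len(train_idx)
        loss_history, weight_history = [], []
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, cfg.batch_size):
                sel = order[start : start + cfg.batch_size]
                batch = {
                    "Spre": inputs["Spre"][sel],
                    "Tm": inputs["Tm"][sel],
                    "y": inputs["y"][sel],
                }
                loss, grads = self.loss_and_grads(params, batch)
                step += 1
                for key in params:
                    g = grads[key]
                    m[key] = b1 * m[key] + (1 - b1) * g
                    v[key] = b2 * v[key] + (1 - b2) * g * g
                    mhat = m[key] / (1 - b1**step)
                    vhat = v[key] / (1 - b2**step)
                    params[key] -= cfg.lr * mhat / (np.sqrt(vhat) + eps)
                epoch_losses.append(loss)
                weight_history.append(
                    {
                        key: _softmax(params[q], axis=0 if cfg.per_node_fusion else -1)
                        for key, q in (("shallow", "qS"), ("deep", "qD"))
                        if q in params
                    }
                )
            loss_history.append(float(np.mean(epoch_losses)))
        return FusionGCNResults(
            model=self,
            params=params,
            mu=mu,
            sd=sd,
            train_idx=train_idx,
            val_idx=None if val_idx is None else np.asarray(val_idx),
            loss_history=np.array(loss_history),
            weight_history=weight_history,
        )


@dataclass
class FusionGCNResults:
    """Fitted parameters plus prediction and reporting helpers."""

    model: FusionGCN
    params: dict[str, np.ndarray]
    mu: np.ndarray
    sd: np.ndarray
    train_idx: np.ndarray
    val_idx: np.ndarray | None
    loss_history: np.ndarray
    weight_history: list[dict[str, np.ndarray]]

    def predict_proba(self, idx: np.ndarray | None = None) -> np.ndarray:
        inputs = self.model.prepare_inputs(idx, self.mu, self.sd)
        probs, _ = self.model.forward(self.params, inputs)
        return probs

    def predict(self, idx: np.ndarray | None = None) -> np.ndarray:
        return self.predict_proba(idx).argmax(axis=1)

    def score(self, idx: np.ndarray | None = None) -> float:
        """Accuracy in percent on the given indices (default: all samples)."""
        labels = self.model.dataset.labels if idx is None else self.model.dataset.labels[np.asarray(idx)]
        return 100.0 * float((self.predict(idx) == labels).mean())

    @property
    def fusion_weights(self) -> dict[str, np.ndarray]:
        """Current simplex weights per depth (band order theta, alpha, beta, gamma)."""
        out = {}
        for key, q in (("shallow", "qS"), ("deep", "qD")):
            if q in self.params:
                out[key] = _softmax(
                    self.params[q], axis=0 if self.model.config.per_node_fusion else -1
                )
        return out

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Multi-band graph fusion classifier",
            "=" * 42,
            f"samples (train): {len(self.train_idx)}    nodes: {self.model.N}"
            f"    bands: {self.model.B}",
            f"variant: depth={cfg.depth}, fusion={cfg.fusion}, K={cfg.cheb_K}",
            f"parameters: {self.n_params}    epochs: {cfg.epochs}    lr: {cfg.lr}",
            f"final training loss: {self.loss_history[-1]:.4f}",
            f"training accuracy: {self.score(self.train_idx):.2f}%",
        ]
        if self.val_idx is not None:
            lines.append(f"validation accuracy: {self.score(self.val_idx):.2f}%")
        for depth, p in self.fusion_weights.items():
            if p.ndim == 1:
                bands = self.model.dataset.band_ids
                ptxt = ", ".join(f"p_{b}={w:.3f}" for b, w in zip(bands, p))
                lines.append(f"{depth} fusion weights: {ptxt}")
        return "\n".join(lines)

    def save(self, path) -> None:
        """Checkpoint the trained parameters and standardization constants."""
        np.savez(
            path,
            mu=self.mu,
            sd=self.sd,
            loss_history=self.loss_history,
            **{f"param_{k}": v for k, v in self.params.items()},
        )

    @classmethod
    def load(cls, path, model: FusionGCN) -> "FusionGCNResults":
        """Restore a checkpoint against a compatible model object."""
        with np.load(path) as data:
            params = {
                k[len("param_") :]: data[k] for k in data.files if k.startswith("param_")
            }
            return cls(
                model=model,
                params=params,
                mu=data["mu"],
                sd=data["sd"],
                train_idx=np.arange(len(model.dataset)),
                val_idx=None,
                loss_history=data["loss_history"],
                weight_history=[],
            )

    def plot_training(self, ax=None):
        """Loss curve and fusion-weight trajectory (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.loss_history, label="training loss")
        ax.set_xlabel("epoch")
        ax.set_ylabel("cross-entropy loss")
        if self.weight_history and "shallow" in self.weight_history[0]:
            w = np.array([h["shallow"] for h in self.weight_history])
            if w.ndim == 2:
                ax2 = ax.twinx()
                for bi, b in enumerate(self.model.dataset.band_ids):
                    ax2.plot(
                        np.linspace(0, len(self.loss_history), len(w)),
                        w[:, bi],
                        ls="--",
                        label=f"p_{b}",
                    )
                ax2.set_ylabel("shallow fusion weight")
                ax2.legend(loc="center right", fontsize=8)
        ax.legend(loc="upper right", fontsize=8)
        return ax


@dataclass
class EvalReport:
    """Cross-validated accuracies, formatted as in the comparison tables."""

    fold_accuracies: np.ndarray  # percent
    confusion: np.ndarray
    fusion_weights: list[dict[str, np.ndarray]]
    fold_test_indices: list[np.ndarray] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1)) if len(self.fold_accuracies) > 1 else 0.0

    def summary(self) -> str:
        return f"{self.mean:.2f} ± {self.std:.2f}"


def cross_validate(
    dataset: GraphDataset,
    config: ModelConfig | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> EvalReport:
    """Stratified segment-level k-fold evaluation (default 5 folds).

    Fold assignment is deterministic given the seed; every class must be
    present in every training fold.
    """
    from sklearn.metrics import confusion_matrix
    from sklearn.model_selection import StratifiedKFold

    config = config or ModelConfig()
    if n_folds < 2:
        raise FusionError("need at least 2 folds")
    y = dataset.labels
    classes = np.unique(y)
    if len(classes) < 2:
        raise FusionError("need at least 2 classes")
    counts = np.bincount(y)
    if counts[counts > 0].min() < n_folds:
        raise FusionError("too few segments per class for the requested folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs, weights, fold_idx = [], [], []
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        if len(np.unique(y[train_idx])) < len(classes) or len(np.unique(y[test_idx])) < len(classes):
            raise FusionError("a fold is missing a class")
        model = FusionGCN(dataset, config)
        res = model.fit(train_idx, test_idx)
        accs.append(res.score(test_idx))
        weights.append(res.fusion_weights)
        fold_idx.append(test_idx)
        conf += confusion_matrix(y[test_idx], res.predict(test_idx), labels=classes)
    return EvalReport(np.array(accs), conf, weights, fold_idx)


#: Table-3-style ablation grid: (label, depth, fusion).
ABLATION_VARIANTS: tuple[tuple[str, str, str], ...] = (
    ("shallow-cascade", "shallow", "cascade"),
    ("shallow-fused", "shallow", "fused"),
    ("deep-cascade", "deep", "cascade"),
    ("deep-fused", "deep", "fused"),
    ("shallow+deep-cascade", "both", "cascade"),
    ("shallow+deep-fused", "both", "fused"),
)


def ablate(
    dataset: GraphDataset,
    base_config: ModelConfig | None = None,
    variants: tuple[tuple[str, str, str], ...] = ABLATION_VARIANTS,
    n_folds: int = 5,
    seed: int = 0,
    baseline_datasets: dict[str, GraphDataset] | None = None,
) -> pd.DataFrame:
    """Cross-validate the depth/fusion variants (and optional alternative
    adjacency datasets) on identical folds; one row per variant."""
    base_config = base_config or ModelConfig()
    rows = []
    for label, depth, fusion in variants:
        cfg = replace(base_config, depth=depth, fusion=fusion)
        rep = cross_validate(dataset, cfg, n_folds=n_folds, seed=seed)
        rows.append({"variant": label, "mean": rep.mean, "std": rep.std, "accuracy": rep.summary()})
    for name, ds in (baseline_datasets or {}).items():
        rep = cross_validate(ds, base_config, n_folds=n_folds, seed=seed)
        rows.append(
            {"variant": f"adjacency={name}", "mean": rep.mean, "std": rep.std, "accuracy": rep.summary()}
        )
    return pd.DataFrame(rows)


def paired_ttest(acc_a: np.ndarray, acc_b: np.ndarray) -> float:
    """Two-sided paired-samples t-test p-value for per-fold accuracies.

    Raises on zero-variance differences (the t statistic is undefined),
    e.g. identical accuracy vectors.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise FusionError("need two equal-length vectors with >= 2 folds")
    d = a - b
    if np.std(d, ddof=1) == 0:
        raise FusionError("zero-variance differences: paired t-test undefined")
    return float(sps.ttest_rel(a, b).pvalue)
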