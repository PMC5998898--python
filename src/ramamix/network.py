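"""Per-residue cluster-probability classifier.

A small 1-D convolutional residual network maps the (L, 66) feature matrix
of a protein to an (L, K) matrix of cluster-membership probabilities.  The
architecture follows the residual design summarised as
``n_blocks - n_filters - half_window`` (default 5-100-3): an input
convolution, ``n_blocks`` residual blocks of two convolutions with ReLU
activations and an identity skip, and a softmax (logistic-regression)
output layer.  Every convolution sees a window of 2*half_window+1
residues, so torsion angles depend on their sequence neighbourhood.

Training maximises the penalised log-likelihood

    max_theta  log P_theta(Y | X) - lambda ||theta||^2

i.e. minimises mean cross-entropy over labelled residues plus an L2
penalty on the weights (biases are not penalised), with Adam.  The
implementation is plain numpy with explicit backpropagation, seeded and
fully deterministic; any object exposing ``predict_probs`` can stand in
for it elsewhere in the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .features import N_FEATURES, validate_features

__all__ = ["Architecture", "ResidualConvClassifier", "train",
           "ensemble_probs", "examples_from_proteins",
    "TrainingDivergedError"]


class TrainingDivergedError(RuntimeError):
    """The training objective became non-finite."""


@dataclass(frozen=True)
class Architecture:
    n_blocks: int = 5
    n_filters: int = 100
    half_window: int = 3

    @property
    def window(self) -> int:
        return 2 * self.half_window + 1


def _windows(x: np.ndarray, hw: int) -> np.ndarray:
    """(B, L, C) -> (B, L, win*C) sliding windows, zero-padded at the ends."""
    B, L, C = x.shape
    xp = np.pad(x, ((0, 0), (hw, hw), (0, 0)))
    w = np.lib.stride_tricks.sliding_window_view(xp, 2 * hw + 1, axis=1)
    # (B, L, C, win) -> (B, L, win, C) -> flat, window-offset major
    return np.ascontiguousarray(w.transpose(0, 1, 3, 2)).reshape(
        B, L, (2 * hw + 1) * C)


def _fold(dxw: np.ndarray, hw: int, C: int) -> np.ndarray:
    """Adjoint of :func:`_windows`: scatter window gradients back to positions."""
    B, L, _ = dxw.shape
    win = 2 * hw + 1
    dxw = dxw.reshape(B, L, win, C)
    dxp = np.zeros((B, L + 2 * hw, C))
    for o in range(win):
        dxp[:, o:o + L] += dxw[:, :, o]
    return dxp[:, hw:hw + L]


class ResidualConvClassifier:
    """Trained model: architecture, K, parameter arrays, seed."""

    def __init__(self, arch: Architecture, K: int, params: dict, seed: int,
                 lam: float = 1e-4, objective_history: list | None = None):
        self.arch = arch
        self.K = int(K)
        self.params = params
        self.seed = int(seed)
        self.lam = float(lam)
        self.objective_history = objective_history or []

    # -- inference ---------------------------------------------------------

    def _forward(self, X: np.ndarray, mask: np.ndarray, caches: list | None = None):
        """X: (B, L, 66); mask: (B, L) floats in {0, 1}.  Returns logits."""
        hw = self.arch.half_window
        m = mask[..., None]
        p = self.params
        x = X * m

        def conv(inp, W, b):
            xw = _windows(inp, hw)
            if caches is not None:
                caches.append(xw)
            return xw @ W + b

        h_pre = conv(x, p["W_in"], p["b_in"])
        h = np.maximum(h_pre, 0.0) * m
        if caches is not None:
            caches.append(("in", h_pre, h))
        for i in range(self.arch.n_blocks):
            a_pre = conv(h, p[f"W{i}a"], p[f"b{i}a"])
            a = np.maximum(a_pre, 0.0) * m
            b_pre = conv(a, p[f"W{i}b"], p[f"b{i}b"])
            s_pre = h + b_pre
            h_new = np.maximum(s_pre, 0.0) * m
            if caches is not None:
                caches.append((i, a_pre, s_pre, h))
            h = h_new
        logits = h @ p["W_out"] + p["b_out"]
        if caches is not None:
            caches.append(("out", h))
        return logits

    def predict_probs(self, features) -> np.ndarray:
        """(L, 66) features -> (L, K) rows on the probability simplex."""
        X = validate_features(features)
        logits = self._forward(X[None], np.ones((1, X.shape[0])))[0]
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint with embedded architecture spec and seed."""
        meta = {"arch": asdict(self.arch), "K": self.K, "seed": self.seed,
                "lam": self.lam, "objective_history": self.objective_history}
        with open(path, "wb") as fh:
            np.savez(fh, __meta__=np.frombuffer(
                json.dumps(meta).encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path) -> "ResidualConvClassifier":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            params = {k: z[k] for k in z.files if k != "__meta__"}
        return cls(Architecture(**meta["arch"]), meta["K"], params,
                   meta["seed"], meta["lam"], meta["objective_history"])


def _init_params(arch: Architecture, K: int, rng) -> dict:
    """He-normal initialisation sized by fan-in."""
    win = arch.window
    F = arch.n_filters

    def he(fan_in, shape):
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

    p = {"W_in": he(win * N_FEATURES, (win * N_FEATURES, F)),
         "b_in": np.zeros(F)}
    for i in range(arch.n_blocks):
        p[f"W{i}a"] = he(win * F, (win * F, F))
        p[f"b{i}a"] = np.zeros(F)
        p[f"W{i}b"] = he(win * F, (win * F, F))
        p[f"b{i}b"] = np.zeros(F)
    p["W_out"] = he(F, (F, K))
    p["b_out"] = np.zeros(K)
    return p


def _batch(examples: Sequence, idx) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pad a set of proteins to a common length; returns (X, y, mask)."""
    Ls = [examples[i][0].shape[0] for i in idx]
    Lmax = max(Ls)
    B = len(idx)
    X = np.zeros((B, Lmax, N_FEATURES))
    y = np.zeros((B, Lmax), dtype=int)
    m = np.zeros((B, Lmax))
    for j, i in enumerate(idx):
        feats, labels = examples[i]
        L = feats.shape[0]
        X[j, :L] = feats
        y[j, :L] = labels
        m[j, :L] = 1.0
    return X, y, m


def _loss_and_grads(model: ResidualConvClassifier, X, y, mask, want_grads=True):
    """Mean cross-entropy over labelled residues (label 0 = ignore), plus
    gradients of (cross-entropy + lam * sum W^2) if requested."""
    hw = model.arch.half_window
    p = model.params
    caches: list | None = [] if want_grads else None
    logits = model._forward(X, mask, caches)

    w = (mask > 0) & (y > 0)
    nw = int(w.sum())
    if nw == 0:
        raise ValueError("no labelled residues in batch")
    z = logits - logits.max(axis=2, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=2, keepdims=True)
    idx = np.nonzero(w)
    ce = -np.mean(np.log(np.maximum(probs[idx[0], idx[1], y[w] - 1], 1e-300)))
    if not np.isfinite(ce):
        raise TrainingDivergedError("non-finite cross-entropy")
    if not want_grads:
        return ce, None

    grads = {k: np.zeros_like(v) for k, v in p.items()}
    dlogits = probs.copy()
    dlogits[idx[0], idx[1], y[w] - 1] -= 1.0
    dlogits *= (w[..., None] / nw)

    tag, h = caches.pop()
    assert tag == "out"
    grads["W_out"] = np.tensordot(h, dlogits, axes=([0, 1], [0, 1]))
    grads["b_out"] = dlogits.sum(axis=(0, 1))
    dh = dlogits @ p["W_out"].T

    m3 = mask[..., None]

    def conv_backward(name, dY):
        xw = caches.pop()
        grads[f"W{name}"] = np.tensordot(xw, dY, axes=([0, 1], [0, 1]))
        grads[f"b{name}"] = dY.sum(axis=(0, 1))
        dxw = dY @ p[f"W{name}"].T
        return _fold(dxw, hw, xw.shape[2] // (2 * hw + 1))

    for i in reversed(range(model.arch.n_blocks)):
        tag, a_pre, s_pre, h_in = caches.pop()
        assert tag == i
        ds = dh * (s_pre > 0) * m3
        da = conv_backward(f"{i}b", ds)
        da_pre = da * (a_pre > 0) * m3
        dh = ds + conv_backward(f"{i}a", da_pre)

    tag, h_pre, _h = caches.pop()
    assert tag == "in"
    dh_pre = dh * (h_pre > 0) * m3
    conv_backward("_in", dh_pre)  # input gradient discarded

    for k in grads:
        if k.startswith("W"):
            grads[k] += 2.0 * model.lam * p[k]
    return ce, grads


def _objective(model: ResidualConvClassifier, examples, batch_size) -> float:
    """Full-dataset penalised objective: mean CE + lam * ||W||^2."""
    tot, n = 0.0, 0
    order = np.arange(len(examples))
    for s in range(0, len(order), batch_size):
        idx = order[s:s + batch_size]
        X, y, m = _batch(examples, idx)
        ce, _ = _loss_and_grads(model, X, y, m, want_grads=False)
        nb = int(((m > 0) & (y > 0)).sum())
        tot += ce * nb
        n += nb
    pen = model.lam * sum(float((v ** 2).sum())
                          for k, v in model.params.items() if k.startswith("W"))
    return float(tot / n + pen)


def train(examples: Sequence, K: int, arch: Architecture = Architecture(),
          lam: float = 1e-4, epochs: int = 20, lr: float = 1e-3,
          batch_size: int = 8, seed: int = 0,
          track_objective: bool = True) -> ResidualConvClassifier:
    """Train the residual classifier on labelled proteins.

    ``examples`` is a sequence of ``(features, labels)`` per protein:
    features (L, 66), labels (L,) integers in 1..K with 0 marking residues
    excluded from the loss (undefined dihedrals).  Adam with the given
    learning rate; at most ``epochs`` passes (the optimisation typically
    converges within 20).  Deterministic for a fixed seed.
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    examples = [(validate_features(X), np.asarray(y, dtype=int))
                for X, y in examples]
    for X, y in examples:
        if y.min() < 0 or y.max() > K:
            raise ValueError("labels must lie in {0..K} (0 = masked)")
    rng = np.random.default_rng(seed)
    model = ResidualConvClassifier(arch, K, _init_params(arch, K, rng),
                                   seed, lam)

    mstate = {k: np.zeros_like(v) for k, v in model.params.items()}
    vstate = {k: np.zeros_like(v) for k, v in model.params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    t = 0
    for _epoch in range(epochs):
        order = rng.permutation(len(examples))
        for s in range(0, len(order), batch_size):
            idx = order[s:s + batch_size]
            X, y, m = _batch(examples, idx)
            _, grads = _loss_and_grads(model, X, y, m)
            t += 1
            for k, g in grads.items():
                mstate[k] = b1 * mstate[k] + (1 - b1) * g
                vstate[k] = b2 * vstate[k] + (1 - b2) * g * g
                mhat = mstate[k] / (1 - b1 ** t)
                vhat = vstate[k] / (1 - b2 ** t)
                model.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
        if track_objective:
            obj = _objective(model, examples, batch_size)
            if not np.isfinite(obj):
                raise TrainingDivergedError("objective became non-finite")
            model.objective_history.append(obj)
    return model


def ensemble_probs(models: Sequence[ResidualConvClassifier], features) -> np.ndarray:
    """Average the probability matrices of ensemble members, renormalised."""
    if not models:
        raise ValueError("need at least one model")
    Ks = {m.K for m in models}
    if len(Ks) != 1:
        raise ValueError(f"inconsistent K across ensemble members: {sorted(Ks)}")
    P = np.mean([m.predict_probs(features) for m in models], axis=0)
    return P / P.sum(axis=1, keepdims=True)


def examples_from_proteins(proteins, cluster_model):
    """Build (features, labels) training pairs: each residue with both
    dihedrals defined gets the 1-based label of its nearest cluster center;
    masked residues get label 0."""
    out = []
    for prot in proteins:
        ok = prot.pair_mask()
        y = np.zeros(len(prot), dtype=int)
        if ok.any():
            y[ok] = cluster_model.assign(prot.phi[ok], prot.psi[ok])
        out.append((validate_features(prot.features), y))
    return out
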