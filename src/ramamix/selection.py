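"""Choosing the number of Ramachandran clusters.

Two criteria are computed over a grid of K:

* entropy loss  EL = H(P0) - (1/N) sum_i H(P_i)  — the mean information
  gain of the per-residue predicted cluster distributions P_i over the
  background distribution P0 (natural log, units: nats);
* mixture log-likelihood  LL = (1/N) sum_i log sum_k p_ik f_k(phi_i, psi_i)
  with bivariate von Mises components f_k fitted to the training clusters.

``select_k`` applies a plateau rule: the smallest K whose entropy loss is
within epsilon of the best.  The shipped default for downstream work is
K = 20.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from . import clustering
from .bvm import mixture_loglik

__all__ = ["entropy", "entropy_loss", "KScanRow", "k_scan", "select_k",
           "write_scan_tsv"]

DEFAULT_K_GRID = tuple(range(10, 101, 10))
DEFAULT_EPSILON = 0.05


def entropy(p) -> float:
    """Shannon entropy -sum p log p in nats, with 0 log 0 = 0."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("input must be a probability vector")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def entropy_loss(P0, probs) -> float:
    """Mean entropy reduction H(P0) - mean_i H(P_i), in nats."""
    P0 = np.asarray(P0, dtype=float)
    P = np.atleast_2d(np.asarray(probs, dtype=float))
    if P.shape[1] != P0.size:
        raise ValueError("P0 length must equal probs column count")
    h0 = entropy(P0)
    hi = np.array([entropy(row) for row in P])
    return float(h0 - hi.mean())


@dataclass(frozen=True)
class KScanRow:
    K: int
    entropy_loss: float
    loglik: float
    seed: int


def k_scan(train, val, ks: Sequence[int],
           train_classifier: Callable, seed: int = 0,
           n_init: int = 10) -> list[KScanRow]:
    """Score each K on held-out data with both criteria.

    Parameters
    ----------
    train, val
        Sequences of proteins (see :class:`ramamix.protein.Protein`): the
        clustering and the classifier are fitted on ``train``; EL and LL
        are evaluated on ``val``.
    ks
        Grid of cluster counts, scanned in increasing order.
    train_classifier
        Callable ``(proteins, cluster_model, seed) -> model`` returning an
        object with ``predict_probs(features) -> (L, K)``; the pluggable
        classifier recipe.
    """
    ks = sorted(set(int(k) for k in ks))
    if not ks:
        raise ValueError("K grid must be nonempty")

    rows = []
    for K in ks:
        try:
            rows.append(_scan_one(train, val, K, train_classifier, seed, n_init))
        except Exception as exc:
            raise RuntimeError(f"k_scan failed at K={K}: {exc}") from exc
    return rows


def _scan_one(train, val, K, train_classifier, seed, n_init) -> KScanRow:
    tr_phi, tr_psi = _pooled_pairs(train)
    model = clustering.fit(tr_phi, tr_psi, K=K, seed=seed, n_init=n_init)
    clf = train_classifier(train, model, seed)

    probs_rows = []
    va_phi, va_psi = [], []
    for prot in val:
        P = clf.predict_probs(prot.features)
        ok = prot.pair_mask()
        probs_rows.append(P[ok])
        va_phi.append(prot.phi[ok])
        va_psi.append(prot.psi[ok])
    P = np.vstack(probs_rows)
    va_phi = np.concatenate(va_phi)
    va_psi = np.concatenate(va_psi)

    el = entropy_loss(model.background, P)
    params = model.bvm_params
    if any(p is None for p in params):
        ll = float("nan")
    else:
        ll = mixture_loglik(va_phi, va_psi, P, params)
    return KScanRow(K=K, entropy_loss=el, loglik=ll, seed=seed)


def _pooled_pairs(proteins):
    phi, psi = [], []
    for p in proteins:
        ok = p.pair_mask()
        phi.append(p.phi[ok])
        psi.append(p.psi[ok])
    return np.concatenate(phi), np.concatenate(psi)


def select_k(rows: Sequence[KScanRow], epsilon: float = DEFAULT_EPSILON) -> int:
    """Smallest K whose entropy loss is within ``epsilon`` of the maximum."""
    if not rows:
        raise ValueError("need at least one scan row")
    best = max(r.entropy_loss for r in rows)
    for r in sorted(rows, key=lambda r: r.K):
        if r.entropy_loss >= best - epsilon:
            return r.K
    return rows[-1].K  # unreachable: the max itself always qualifies


def write_scan_tsv(rows: Sequence[KScanRow], path) -> None:
    with open(path, "w") as fh:
        fh.write("K\tentropy_loss\tloglik\tseed\n")
        for r in rows:
            fh.write(f"{r.K}\t{r.entropy_loss!r}\t{r.loglik!r}\t{r.seed}\n")
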