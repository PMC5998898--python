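"""K-means clustering of dihedral angle pairs on the trigonometric embedding.

Angle pairs are embedded as 4-vectors (cos phi, sin phi, cos psi, sin psi)
and clustered with ordinary Euclidean k-means.  The raw centers are then
renormalized pairwise so each becomes a valid angle representation; every
training pair is assigned the "true" label of its nearest normalized
center.  Per cluster the model stores the background probability (label
frequency), circular means and variances of phi and psi (the variances
drive per-residue confidence), and a fitted bivariate von Mises component
(used for the mixture log-likelihood model-selection criterion).

Cluster labels are 1-based and ordered by descending background
probability, so label 1 is always the most populated basin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from . import geometry
from .bvm import BvmParams, estimate_params, InsufficientDataError

__all__ = ["ClusterModel", "fit", "circular_stats", "background_frequencies"]

DEFAULT_K = 20


def circular_stats(phi, psi):
    """Circular means (degrees) and periodic variances (degrees^2).

    The mean is the direction of the summed unit vectors; the variance is
    the mean squared periodicity-corrected deviation from that mean, so it
    is directly comparable to squared angular errors.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if phi.size == 0 or psi.size == 0:
        raise ValueError("circular_stats requires at least one member")
    out = []
    for theta in (phi, psi):
        t = np.deg2rad(theta)
        mean = geometry.wrap_angle(
            np.rad2deg(np.arctan2(np.sin(t).mean(), np.cos(t).mean())))
        dev = geometry.angular_difference(theta, mean)
        out.append((float(mean), float(np.mean(dev ** 2))))
    (mphi, vphi), (mpsi, vpsi) = out
    return mphi, mpsi, vphi, vpsi


def background_frequencies(labels, K: int) -> np.ndarray:
    """Empirical cluster frequencies of 1-based labels; sums to 1."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("labels must be nonempty")
    if labels.min() < 1 or labels.max() > K:
        raise ValueError("labels must lie in {1..K}")
    counts = np.bincount(labels - 1, minlength=K).astype(float)
    return counts / counts.sum()


@dataclass
class ClusterModel:
    """A fitted angle-pair clustering with per-cluster statistics."""

    K: int
    raw_centers: np.ndarray        # (K, 4) k-means centers before renormalization
    centers: np.ndarray            # (K, 4) pairwise-normalized centers
    center_phi: np.ndarray         # (K,) degrees
    center_psi: np.ndarray         # (K,) degrees
    background: np.ndarray         # (K,) label frequencies, sums to 1
    circ_mean_phi: np.ndarray      # (K,) degrees
    circ_mean_psi: np.ndarray      # (K,) degrees
    var_phi: np.ndarray            # (K,) degrees^2
    var_psi: np.ndarray            # (K,) degrees^2
    bvm_params: list = field(default_factory=list)  # K BvmParams (or None)
    seed: int = 0

    def assign(self, phi, psi):
        """1-based label of the nearest normalized center (Euclidean in 4-D).

        Ties break to the lowest label.  Accepts scalars or arrays.
        """
        v = geometry.to_vector(phi, psi)
        v = np.atleast_2d(v)
        d2 = ((v[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        lab = d2.argmin(axis=1) + 1
        return int(lab[0]) if np.isscalar(phi) else lab

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "K": self.K,
            "seed": self.seed,
            "raw_centers": self.raw_centers.tolist(),
            "centers": self.centers.tolist(),
            "center_phi": self.center_phi.tolist(),
            "center_psi": self.center_psi.tolist(),
            "background": self.background.tolist(),
            "circ_mean_phi": self.circ_mean_phi.tolist(),
            "circ_mean_psi": self.circ_mean_psi.tolist(),
            "var_phi": self.var_phi.tolist(),
            "var_psi": self.var_psi.tolist(),
            "bvm_params": [p.to_dict() if p is not None else None
                           for p in self.bvm_params],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ClusterModel":
        doc = json.loads(text)
        return cls(
            K=doc["K"],
            seed=doc["seed"],
            raw_centers=np.array(doc["raw_centers"], dtype=float),
            centers=np.array(doc["centers"], dtype=float),
            center_phi=np.array(doc["center_phi"], dtype=float),
            center_psi=np.array(doc["center_psi"], dtype=float),
            background=np.array(doc["background"], dtype=float),
            circ_mean_phi=np.array(doc["circ_mean_phi"], dtype=float),
            circ_mean_psi=np.array(doc["circ_mean_psi"], dtype=float),
            var_phi=np.array(doc["var_phi"], dtype=float),
            var_psi=np.array(doc["var_psi"], dtype=float),
            bvm_params=[BvmParams.from_dict(p) if p is not None else None
                        for p in doc["bvm_params"]],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "ClusterModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def fit(phi, psi, K: int = DEFAULT_K, seed: int = 0, n_init: int = 10) -> ClusterModel:
    """Fit a K-cluster model to defined angle pairs (degrees).

    Runs seeded k-means++ (best of ``n_init`` restarts) on the 4-D
    embedding, renormalizes centers pairwise, orders clusters by descending
    population, and computes background probabilities, circular statistics
    and von Mises components per cluster.
    """
    phi = np.asarray(phi, dtype=float).ravel()
    psi = np.asarray(psi, dtype=float).ravel()
    if phi.size != psi.size:
        raise ValueError("phi and psi must have equal length")
    if K < 1:
        raise ValueError("K must be >= 1")
    if phi.size < K:
        raise ValueError(f"need at least K={K} angle pairs, got {phi.size}")

    V = geometry.to_vector(phi, psi)
    km = KMeans(n_clusters=K, init="k-means++", n_init=n_init,
                random_state=seed)
    km.fit(V)
    raw = km.cluster_centers_.copy()

    # a center whose (cos, sin) pair cancelled to ~zero has no direction:
    # re-seed it from a random member point of that cluster
    rng = np.random.default_rng(seed)
    for k in range(K):
        n1 = np.hypot(raw[k, 0], raw[k, 1])
        n2 = np.hypot(raw[k, 2], raw[k, 3])
        if n1 < geometry.DEGENERATE_NORM or n2 < geometry.DEGENERATE_NORM:
            members = np.flatnonzero(km.labels_ == k)
            pick = members[rng.integers(members.size)] if members.size else \
                rng.integers(V.shape[0])
            raw[k] = V[pick]

    centers = geometry.normalize_pairs(raw)

    # "true" labels: nearest *normalized* center
    d2 = ((V[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels0 = d2.argmin(axis=1)

    counts = np.bincount(labels0, minlength=K)
    order = np.argsort(-counts, kind="stable")  # label 1 = largest cluster
    raw = raw[order]
    centers = centers[order]
    relabel = np.empty(K, dtype=int)
    relabel[order] = np.arange(K)
    labels0 = relabel[labels0]

    background = np.bincount(labels0, minlength=K).astype(float) / labels0.size
    cphi, cpsi = geometry.to_angles(centers)

    mphi = np.empty(K); mpsi = np.empty(K)
    vphi = np.empty(K); vpsi = np.empty(K)
    params: list = []
    for k in range(K):
        sel = labels0 == k
        if not sel.any():
            # empty cluster: fall back to its center with zero spread
            mphi[k], mpsi[k] = cphi[k], cpsi[k]
            vphi[k] = vpsi[k] = 0.0
            params.append(None)
            continue
        mphi[k], mpsi[k], vphi[k], vpsi[k] = circular_stats(phi[sel], psi[sel])
        try:
            params.append(estimate_params(phi[sel], psi[sel]))
        except InsufficientDataError:
            params.append(None)

    return ClusterModel(
        K=K, raw_centers=raw, centers=centers,
        center_phi=cphi, center_psi=cpsi, background=background,
        circ_mean_phi=mphi, circ_mean_psi=mpsi,
        var_phi=vphi, var_psi=vpsi, bvm_params=params, seed=seed,
    )
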