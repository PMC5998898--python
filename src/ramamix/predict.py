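"""Real-valued angle reconstruction from predicted cluster probabilities.

Given a residue's predicted cluster distribution P = (p_1..p_K) and the
normalized cluster centers C~_k, the predicted angle pair comes from the
probability-weighted mean embedding

    v_hat = sum_k p_k C~_k,

renormalized pairwise (cos_hat(phi) = v0 / sqrt(v0^2 + v1^2), etc.) and
mapped back to degrees.  The per-residue confidence is the standard
deviation of the mixture using in-cluster variances only:

    var(theta) = sum_k p_k sigma_k^2(theta),   theta in {phi, psi}.

If the weighted mean embedding cancels to (near) zero for one angle the
direction is undefined; the residue falls back to the argmax cluster's
center and the record is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import geometry
from .clustering import ClusterModel

__all__ = ["PredictionRecord", "mix_to_angles", "top_r_mix", "confidence",
           "predict_protein", "write_prediction_tsv"]

_SIMPLEX_TOL = 1e-9


@dataclass
class PredictionRecord:
    """One residue's prediction: angles, confidence, top cluster."""

    position: int            # 1-based
    phi: float               # degrees, NaN if undefined
    psi: float
    std_phi: float           # degrees
    std_psi: float
    top_label: int           # 1-based cluster label
    top_prob: float
    degenerate: bool = False  # weighted mean cancelled; argmax fallback used


def _check_row(p, K: int) -> np.ndarray:
    p = np.asarray(p, dtype=float).ravel()
    if p.size != K:
        raise ValueError(f"probability row has length {p.size}, model K={K}")
    if np.any(p < -_SIMPLEX_TOL) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("probability row is not on the simplex")
    return p


def mix_to_angles(p, model: ClusterModel):
    """Probability-weighted angle reconstruction for one residue.

    Returns ``(phi, psi, degenerate)``; on pairwise cancellation of the
    weighted embedding the affected angle falls back to the argmax
    cluster's center and ``degenerate`` is True.
    """
    p = _check_row(p, model.K)
    v = p @ model.centers
    top = int(p.argmax())
    phi = psi = None
    degenerate = False
    n1 = float(np.hypot(v[0], v[1]))
    n2 = float(np.hypot(v[2], v[3]))
    if n1 < geometry.DEGENERATE_NORM:
        phi = float(model.center_phi[top])
        degenerate = True
    if n2 < geometry.DEGENERATE_NORM:
        psi = float(model.center_psi[top])
        degenerate = True
    if phi is None:
        phi = float(geometry.wrap_angle(np.rad2deg(np.arctan2(v[1], v[0]))))
    if psi is None:
        psi = float(geometry.wrap_angle(np.rad2deg(np.arctan2(v[3], v[2]))))
    return phi, psi, degenerate


def top_r_mix(p, model: ClusterModel, R: int):
    """Mix using only the R most probable clusters, renormalized.

    Ties at the cut rank resolve to the lower cluster label.  R = K is
    identical to :func:`mix_to_angles`; R = 1 returns the argmax center.
    """
    p = _check_row(p, model.K)
    if not 1 <= R <= model.K:
        raise ValueError(f"R must be in 1..K={model.K}, got {R}")
    if R == model.K:
        return mix_to_angles(p, model)
    # stable sort on (-p, index): lower label wins ties
    order = np.lexsort((np.arange(p.size), -p))[:R]
    q = np.zeros_like(p)
    q[order] = p[order]
    s = q.sum()
    if s <= 0:
        q[order] = 1.0 / R
    else:
        q /= s
    return mix_to_angles(q, model)


def confidence(p, model: ClusterModel):
    """Per-residue standard deviations sqrt(sum_k p_k sigma_k^2) in degrees."""
    p = _check_row(p, model.K)
    return (float(np.sqrt(p @ model.var_phi)),
            float(np.sqrt(p @ model.var_psi)))


def predict_protein(model: ClusterModel, probs,
                    mask: Optional[np.ndarray] = None) -> list[PredictionRecord]:
    """One :class:`PredictionRecord` per residue from an (L, K) probability
    matrix.  Residues where ``mask`` is False emit records with NaN angles
    and stds (the dihedral does not exist structurally)."""
    P = np.atleast_2d(np.asarray(probs, dtype=float))
    if P.shape[1] != model.K:
        raise ValueError(f"probability matrix K={P.shape[1]} does not match "
                         f"cluster model K={model.K}")
    if mask is None:
        mask = np.ones(P.shape[0], dtype=bool)
    records = []
    for i, row in enumerate(P):
        if not mask[i]:
            records.append(PredictionRecord(
                position=i + 1, phi=float("nan"), psi=float("nan"),
                std_phi=float("nan"), std_psi=float("nan"),
                top_label=0, top_prob=float("nan")))
            continue
        phi, psi, degen = mix_to_angles(row, model)
        sphi, spsi = confidence(row, model)
        top = int(row.argmax())
        records.append(PredictionRecord(
            position=i + 1, phi=phi, psi=psi, std_phi=sphi, std_psi=spsi,
            top_label=top + 1, top_prob=float(row[top]), degenerate=degen))
    return records


def write_prediction_tsv(records, sequence: str, path) -> None:
    """Write per-residue predictions; masked values appear as NA."""
    with open(path, "w") as fh:
        fh.write("# pos aa phi psi std_phi std_psi top_label top_prob\n")
        for rec, aa in zip(records, sequence):
            if np.isnan(rec.phi) and np.isnan(rec.psi) and rec.top_label == 0:
                fh.write(f"{rec.position}\t{aa}\tNA\tNA\tNA\tNA\tNA\tNA\n")
                continue
            fh.write(f"{rec.position}\t{aa}\t{rec.phi:.2f}\t{rec.psi:.2f}\t"
                     f"{rec.std_phi:.2f}\t{rec.std_psi:.2f}\t"
                     f"{rec.top_label}\t{rec.top_prob:.4f}\n")
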