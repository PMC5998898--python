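"""Periodicity-aware dihedral angle arithmetic and the 4-D trigonometric embedding.

A backbone dihedral angle pair (phi, psi) lives on the torus: 179 deg and
-179 deg are 2 deg apart, not 358.  All clustering and averaging in this
package therefore happens on the embedding

    v = (cos phi, sin phi, cos psi, sin psi)

which removes the wrap-around discontinuity.  Angles are degrees everywhere
in the public API, canonicalised to the half-open interval [-180, 180);
+180 maps to -180 so every angle has a single representative.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_angle",
    "to_vector",
    "to_angles",
    "normalize_pairs",
    "angular_difference",
    "DegenerateVectorError",
]

#: tolerance on |(c0,c1)| = 1 for a vector to count as a valid embedding
UNIT_TOL = 1e-6

#: pair norms below this are treated as degenerate (direction undefined)
DEGENERATE_NORM = 1e-8


class DegenerateVectorError(ValueError):
    """A (cos, sin) pair had near-zero norm, so its angle is undefined."""


def wrap_angle(theta):
    """Map angles in degrees onto the canonical interval [-180, 180)."""
    return (np.asarray(theta, dtype=float) + 180.0) % 360.0 - 180.0


def to_vector(phi, psi):
    """Embed angle pairs (degrees) as (cos phi, sin phi, cos psi, sin psi).

    Accepts scalars or arrays of shape (n,); returns shape (4,) or (n, 4).
    Undefined (NaN) angles are rejected: the embedding only exists for
    residues where the dihedral is structurally defined.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if np.any(~np.isfinite(phi)) or np.any(~np.isfinite(psi)):
        raise ValueError("undefined (non-finite) angle passed to to_vector")
    pr, sr = np.deg2rad(phi), np.deg2rad(psi)
    v = np.stack([np.cos(pr), np.sin(pr), np.cos(sr), np.sin(sr)], axis=-1)
    return v


def to_angles(vec):
    """Invert the embedding: (cos phi, sin phi, cos psi, sin psi) -> (phi, psi).

    ``vec`` must satisfy the unit-pair invariant within a small tolerance;
    use :func:`normalize_pairs` first for raw (e.g. averaged) vectors.
    Returns angles in degrees in [-180, 180).
    """
    v = np.asarray(vec, dtype=float)
    n1 = np.hypot(v[..., 0], v[..., 1])
    n2 = np.hypot(v[..., 2], v[..., 3])
    if np.any(np.abs(n1 - 1.0) > UNIT_TOL) or np.any(np.abs(n2 - 1.0) > UNIT_TOL):
        raise ValueError("vector does not satisfy the unit-pair invariant; "
                         "call normalize_pairs first")
    phi = wrap_angle(np.rad2deg(np.arctan2(v[..., 1], v[..., 0])))
    psi = wrap_angle(np.rad2deg(np.arctan2(v[..., 3], v[..., 2])))
    return phi, psi


def normalize_pairs(raw):
    """Rescale each (c0, c1) and (c2, c3) pair of a raw 4-vector to unit norm.

    This is how averaged embeddings (k-means centers, probability-weighted
    mixtures) are mapped back onto valid angle representations:
    c0/sqrt(c0^2+c1^2) etc.

    Raises
    ------
    DegenerateVectorError
        if either pair norm is below 1e-8 (the direction is undefined and
        the caller must decide a fallback).
    """
    v = np.asarray(raw, dtype=float)
    n1 = np.hypot(v[..., 0], v[..., 1])
    n2 = np.hypot(v[..., 2], v[..., 3])
    if np.any(n1 < DEGENERATE_NORM) or np.any(n2 < DEGENERATE_NORM):
        raise DegenerateVectorError("near-zero (cos, sin) pair norm")
    out = np.empty_like(v)
    out[..., 0] = v[..., 0] / n1
    out[..., 1] = v[..., 1] / n1
    out[..., 2] = v[..., 2] / n2
    out[..., 3] = v[..., 3] / n2
    return out


def angular_difference(a, b):
    """Periodicity-corrected absolute difference min(d, 360 - d) in [0, 180].

    The standard error measure for dihedral angles: the difference between
    -179 and 179 is 2 degrees, not 358.
    """
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.minimum(d, 360.0 - d)
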