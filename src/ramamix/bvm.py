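"""Bivariate von Mises (cosine model) density on the torus.

The density for an angle pair (phi, psi), in radians, is

    f(phi, psi) = (1/C) exp{ k1 cos(phi - mu) + k2 cos(psi - nu)
                             + k3 cos(phi - mu - psi + nu) }

with location (mu, nu), marginal concentrations k1, k2 >= 0 and an
interaction concentration k3 that couples the two angles.  The
normalizing integral over the torus has the Bessel-series form

    C = (2 pi)^2 { I0(k1) I0(k2) I0(k3) + 2 sum_{p>=1} Ip(k1) Ip(k2) Ip(k3) }

where Ip is the modified Bessel function of the first kind.  Each
Ramachandran cluster is modelled by one such density; the mixture
log-likelihood over clusters scores a clustering.

Parameters are estimated by the method of moments: circular means for the
locations, and inversion of A(k) = I1(k)/I0(k) = Rbar on mean resultant
lengths for the concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import ive

from .geometry import wrap_angle

__all__ = [
    "BvmParams",
    "log_norm_const",
    "log_density",
    "density",
    "estimate_params",
    "mixture_loglik",
    "sample_bvm",
    "kappa_from_rbar",
    "InsufficientDataError",
]

#: concentration cap: beyond this the density is numerically a point mass
KAPPA_MAX = 700.0

_SERIES_RTOL = 1e-14
_SERIES_PMAX = 10_000


class InsufficientDataError(ValueError):
    """Too few members to estimate distribution parameters."""


@dataclass(frozen=True)
class BvmParams:
    """Parameters of one cosine-model bivariate von Mises component.

    mu, nu are in degrees (phi and psi locations); kappa1, kappa2 >= 0 are
    the marginal concentrations and kappa3 (any sign) the interaction.
    """

    mu: float
    nu: float
    kappa1: float
    kappa2: float
    kappa3: float

    def __post_init__(self):
        if self.kappa1 < 0 or self.kappa2 < 0:
            raise ValueError("kappa1 and kappa2 must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BvmParams":
        return cls(**d)


def log_norm_const(kappa1: float, kappa2: float, kappa3: float) -> float:
    """Log of the integral of the unnormalized density over the torus.

    Evaluates log[(2 pi)^2 {I0(k1)I0(k2)I0(|k3|) +
    2 sum_p (+-1)^p Ip(k1)Ip(k2)Ip(|k3|)}] with exponentially scaled Bessel
    functions so concentrations up to ~700 survive.  For negative kappa3 the
    identity Ip(-k) = (-1)^p Ip(k) introduces the alternating sign.  The
    series is truncated once a term's relative contribution drops below
    1e-14 (hard cap p <= 10^4).
    """
    k1, k2, k3 = float(kappa1), float(kappa2), float(kappa3)
    if k1 < 0 or k2 < 0:
        raise ValueError("kappa1, kappa2 must be >= 0")
    a3 = abs(k3)
    sgn = -1.0 if k3 < 0 else 1.0
    if not np.isfinite(k1 + k2 + a3):
        raise FloatingPointError("non-finite concentration")

    # scaled series: ive(p, k) = Ip(k) exp(-k)
    total = ive(0, k1) * ive(0, k2) * ive(0, a3)
    block = 64
    p = 1
    while p <= _SERIES_PMAX:
        ps = np.arange(p, min(p + block, _SERIES_PMAX + 1))
        terms = 2.0 * (sgn ** ps) * ive(ps, k1) * ive(ps, k2) * ive(ps, a3)
        total += terms.sum()
        if np.abs(terms[-1]) < _SERIES_RTOL * abs(total):
            break
        p = ps[-1] + 1
    if total <= 0 or not np.isfinite(total):
        raise FloatingPointError("normalization series did not converge to a "
                                 "positive value")
    return float(np.log(total) + k1 + k2 + a3 + 2.0 * np.log(2.0 * np.pi))


def log_density(phi, psi, params: BvmParams):
    """Log density (per squared radian) at angle pairs given in degrees."""
    dphi = np.deg2rad(np.asarray(phi, dtype=float) - params.mu)
    dpsi = np.deg2rad(np.asarray(psi, dtype=float) - params.nu)
    e = (params.kappa1 * np.cos(dphi) + params.kappa2 * np.cos(dpsi)
         + params.kappa3 * np.cos(dphi - dpsi))
    return e - log_norm_const(params.kappa1, params.kappa2, params.kappa3)


def density(phi, psi, params: BvmParams):
    """Density per squared radian; integrates to 1 over the torus."""
    return np.exp(log_density(phi, psi, params))


def _newton_A_inverse(rbar: float) -> float:
    """Invert A(k) = I1(k)/I0(k) = rbar for k >= 0 by Newton iteration."""
    if rbar <= 0.0:
        return 0.0
    if rbar >= 1.0 - 1e-12:
        return KAPPA_MAX
    # Banerjee et al. closed-form start, then Newton with
    # A'(k) = 1 - A/k - A^2.
    k = rbar * (2.0 - rbar ** 2) / (1.0 - rbar ** 2)
    k = min(max(k, 1e-8), KAPPA_MAX)
    for _ in range(100):
        a = ive(1, k) / ive(0, k)
        da = 1.0 - a / k - a * a
        if da <= 0:
            break
        step = (a - rbar) / da
        k_new = k - step
        if k_new <= 0:
            k_new = k / 2.0
        if k_new >= KAPPA_MAX:
            return KAPPA_MAX
        if abs(k_new - k) < 1e-10:
            k = k_new
            break
        k = k_new
    return float(k)


def kappa_from_rbar(rbar: float) -> float:
    """Concentration whose von Mises mean resultant length equals ``rbar``."""
    return _newton_A_inverse(float(rbar))


def _circular_mean_deg(theta) -> float:
    t = np.deg2rad(np.asarray(theta, dtype=float))
    return float(wrap_angle(np.rad2deg(np.arctan2(np.sin(t).mean(),
                                                  np.cos(t).mean()))))


def estimate_params(phi, psi) -> BvmParams:
    """Method-of-moments parameter estimate from cluster members (degrees).

    mu, nu are circular means; kappa1, kappa2 come from inverting
    A(k) = Rbar on the marginal mean resultant lengths; |kappa3| from the
    same inversion on the resultant length of the deviation differences
    (phi - mu) - (psi - nu), signed by the circular correlation of the
    deviations.  Requires at least 10 members.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if phi.shape != psi.shape or phi.ndim != 1:
        raise ValueError("phi and psi must be equal-length 1-D arrays")
    if phi.size < 10:
        raise InsufficientDataError(
            f"need >= 10 members to estimate parameters, got {phi.size}")

    mu = _circular_mean_deg(phi)
    nu = _circular_mean_deg(psi)
    pr = np.deg2rad(phi)
    sr = np.deg2rad(psi)
    r1 = float(np.hypot(np.cos(pr).mean(), np.sin(pr).mean()))
    r2 = float(np.hypot(np.cos(sr).mean(), np.sin(sr).mean()))
    k1 = kappa_from_rbar(r1)
    k2 = kappa_from_rbar(r2)

    dphi = pr - np.deg2rad(mu)
    dpsi = sr - np.deg2rad(nu)
    delta = dphi - dpsi
    r3 = float(np.hypot(np.cos(delta).mean(), np.sin(delta).mean()))
    k3 = kappa_from_rbar(r3)
    corr = float(np.mean(np.sin(dphi) * np.sin(dpsi)))
    if corr < 0:
        k3 = -k3
    return BvmParams(mu=mu, nu=nu, kappa1=k1, kappa2=k2, kappa3=k3)


def mixture_loglik(phi, psi, probs, params) -> float:
    """Mean log-likelihood of angle pairs under the per-residue mixture.

    LL = (1/N) sum_i log sum_k p_ik f_k(phi_i, psi_i), evaluated with
    log-sum-exp stabilisation.  ``probs`` is an (N, K) matrix of per-residue
    cluster probabilities (rows on the simplex); ``params`` a sequence of K
    :class:`BvmParams`.  Returns -inf if some residue has zero mixture
    density (all its probability on zero-density components).
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    P = np.asarray(probs, dtype=float)
    if P.ndim != 2 or P.shape[0] != phi.size:
        raise ValueError("probs must be (n_residues, K)")
    if P.shape[1] != len(params):
        raise ValueError("probs column count does not match number of components")
    if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("probability rows must sum to 1")

    logf = np.column_stack([log_density(phi, psi, pk) for pk in params])
    with np.errstate(divide="ignore"):
        logp = np.where(P > 0, np.log(np.where(P > 0, P, 1.0)), -np.inf)
    a = logp + logf
    m = a.max(axis=1)
    ok = np.isfinite(m)
    out = np.full(phi.size, -np.inf)
    out[ok] = m[ok] + np.log(np.exp(a[ok] - m[ok, None]).sum(axis=1))
    return float(out.mean())


def sample_bvm(n: int, params: BvmParams, rng) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` exact samples by rejection from the product-of-univariate
    von Mises proposal (acceptance ratio exp(k3 cos(delta) - |k3|))."""
    if n < 0:
        raise ValueError("n must be >= 0")
    a3 = abs(params.kappa3)
    mu_r = np.deg2rad(params.mu)
    nu_r = np.deg2rad(params.nu)
    phis = np.empty(0)
    psis = np.empty(0)
    while phis.size < n:
        m = max(int(1.5 * (n - phis.size) * np.exp(min(a3, 30.0))), n - phis.size)
        m = min(m, 4 * n + 1000)
        if params.kappa1 > 0:
            p = rng.vonmises(mu_r, params.kappa1, size=m)
        else:
            p = rng.uniform(-np.pi, np.pi, size=m)
        if params.kappa2 > 0:
            s = rng.vonmises(nu_r, params.kappa2, size=m)
        else:
            s = rng.uniform(-np.pi, np.pi, size=m)
        logacc = params.kappa3 * np.cos((p - mu_r) - (s - nu_r)) - a3
        keep = np.log(rng.uniform(size=m)) < logacc
        phis = np.concatenate([phis, p[keep]])
        psis = np.concatenate([psis, s[keep]])
    phis, psis = phis[:n], psis[:n]
    return wrap_angle(np.rad2deg(phis)), wrap_angle(np.rad2deg(psis))
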