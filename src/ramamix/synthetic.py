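"""Synthetic Ramachandran-like proteins for end-to-end testing.

Angle pairs are drawn from a mixture of bivariate von Mises basins tied to
3-state secondary structure.  The shipped 5-basin default covers the
canonical dense regions of the Ramachandran plot: the alpha-helical basin,
the beta-sheet basin, polyproline II, the left-handed helical region and a
broad coil basin.  These basins are test fixtures chosen to look like real
dihedral statistics — not estimates from any structure database.

A synthetic protein is built by (i) sampling a 3-state secondary-structure
string from a first-order Markov chain, (ii) drawing each residue's
(phi, psi) from a basin conditional on its state, and (iii) emitting a
66-column feature matrix whose profile blocks are noisy basin templates —
so features are informative of basin membership by construction, with a
single ``noise`` dial controlling how informative.  The first residue's
phi and the last residue's psi are masked, as those dihedrals do not
exist.  Basin templates come from a fixed internal generator, so bundles
produced with different seeds remain feature-compatible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .bvm import BvmParams, sample_bvm
from .features import AA_ORDER, assemble_features
from .protein import Protein

__all__ = ["BasinSpec", "default_basins", "sample_ramachandran",
           "generate_protein_set", "split_proteins", "DEFAULT_SS_TRANSITIONS"]

_TEMPLATE_SEED = 424242  # fixed: templates depend on basins, not on the bundle seed

SS_STATES = ("H", "E", "C")

#: row-stochastic transition matrix over (H, E, C); diagonal dominance
#: yields realistic segment lengths (mean helix ~ 8, strand ~ 5 residues)
DEFAULT_SS_TRANSITIONS = np.array([
    [0.88, 0.02, 0.10],
    [0.02, 0.80, 0.18],
    [0.15, 0.12, 0.73],
])


@dataclass(frozen=True)
class BasinSpec:
    """One Ramachandran basin: mixture weight, density, associated SS state."""

    weight: float
    params: BvmParams
    ss_state: str

    def __post_init__(self):
        if self.ss_state not in SS_STATES:
            raise ValueError(f"ss_state must be one of {SS_STATES}")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


def default_basins() -> list[BasinSpec]:
    """The 5-basin default mixture.

    Locations and spreads follow the familiar dense regions of the
    Ramachandran plot; weights reflect typical globular-protein secondary
    structure composition (roughly 35% helix, 25% sheet, 40% coil-like).
    """
    return [
        BasinSpec(0.35, BvmParams(mu=-60.0, nu=-45.0, kappa1=25.0,
                                  kappa2=20.0, kappa3=2.0), "H"),
        BasinSpec(0.25, BvmParams(mu=-120.0, nu=135.0, kappa1=8.0,
                                  kappa2=6.0, kappa3=1.0), "E"),
        BasinSpec(0.15, BvmParams(mu=-75.0, nu=150.0, kappa1=15.0,
                                  kappa2=12.0, kappa3=0.0), "C"),
        BasinSpec(0.10, BvmParams(mu=60.0, nu=45.0, kappa1=18.0,
                                  kappa2=15.0, kappa3=0.0), "C"),
        BasinSpec(0.15, BvmParams(mu=-100.0, nu=60.0, kappa1=5.0,
                                  kappa2=3.0, kappa3=0.0), "C"),
    ]


def _check_weights(basins: Sequence[BasinSpec]) -> np.ndarray:
    w = np.array([b.weight for b in basins], dtype=float)
    if w.size == 0 or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("basin weights must be a probability vector")
    return w


def sample_ramachandran(n: int, basins: Sequence[BasinSpec] | None = None,
                        seed: int = 0):
    """Draw ``n`` i.i.d. angle pairs from the basin mixture.

    Returns ``(phi, psi, basin_truth)`` with 1-based basin indices.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    basins = list(basins) if basins is not None else default_basins()
    w = _check_weights(basins)
    rng = np.random.default_rng(seed)
    which = rng.choice(len(basins), size=n, p=w)
    phi = np.empty(n)
    psi = np.empty(n)
    for k, basin in enumerate(basins):
        sel = which == k
        if sel.any():
            phi[sel], psi[sel] = sample_bvm(int(sel.sum()), basin.params, rng)
    return phi, psi, which + 1


def _basin_templates(n_basins: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(_TEMPLATE_SEED)
    pssm_t = rng.normal(0.0, 1.5, size=(n_basins, 20))
    psfm_t = rng.normal(0.0, 1.0, size=(n_basins, 20))
    return pssm_t, psfm_t


def generate_protein_set(n_proteins: int, length_range=(50, 150),
                         basins: Sequence[BasinSpec] | None = None,
                         noise: float = 0.5, seed: int = 0,
                         transitions: np.ndarray | None = None) -> list[Protein]:
    """Generate a reproducible bundle of synthetic proteins.

    Per residue, the secondary-structure state comes from the Markov
    chain, the basin is drawn among the basins of that state (by relative
    weight) and (phi, psi) from that basin's density.  Features: the PSSM
    and PSFM blocks are the residue's basin template plus N(0, noise^2);
    the ACC block is an uninformative random simplex point; the SS block
    is a noise-softened encoding of the true state.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    lo, hi = int(length_range[0]), int(length_range[1])
    if lo < 3 or hi < lo:
        raise ValueError("length_range must satisfy 3 <= min <= max")
    basins = list(basins) if basins is not None else default_basins()
    w = _check_weights(basins)
    P = DEFAULT_SS_TRANSITIONS if transitions is None else np.asarray(transitions)
    if P.shape != (3, 3) or np.any(P < 0) or np.any(np.abs(P.sum(1) - 1) > 1e-9):
        raise ValueError("transitions must be a 3x3 row-stochastic matrix")

    by_state = {s: [k for k, b in enumerate(basins) if b.ss_state == s]
                for s in SS_STATES}
    for s, ks in by_state.items():
        if not ks:
            raise ValueError(f"no basin for secondary-structure state {s}")
    pssm_t, psfm_t = _basin_templates(len(basins))
    rng = np.random.default_rng(seed)

    proteins = []
    for i in range(n_proteins):
        L = int(rng.integers(lo, hi + 1))
        # SS chain: start from the marginal basin-weight composition
        state_w = np.array([sum(w[k] for k in by_state[s]) for s in SS_STATES])
        ss_idx = np.empty(L, dtype=int)
        ss_idx[0] = rng.choice(3, p=state_w / state_w.sum())
        for j in range(1, L):
            ss_idx[j] = rng.choice(3, p=P[ss_idx[j - 1]])
        ss = np.array([SS_STATES[j] for j in ss_idx])

        basin = np.empty(L, dtype=int)
        for j in range(L):
            ks = by_state[ss[j]]
            pw = w[ks] / w[ks].sum()
            basin[j] = int(rng.choice(ks, p=pw))
        phi = np.empty(L)
        psi = np.empty(L)
        for k in np.unique(basin):
            sel = basin == k
            phi[sel], psi[sel] = sample_bvm(int(sel.sum()),
                                            basins[int(k)].params, rng)

        sequence = "".join(rng.choice(list(AA_ORDER), size=L))
        pssm = pssm_t[basin] + noise * rng.normal(size=(L, 20))
        psfm = psfm_t[basin] + noise * rng.normal(size=(L, 20))
        acc = rng.dirichlet(np.ones(3), size=L)
        ss_onehot = np.zeros((L, 3))
        ss_onehot[np.arange(L), ss_idx] = 1.0
        ss_logits = 2.0 * ss_onehot + noise * rng.normal(size=(L, 3))
        ss_probs = np.exp(ss_logits - ss_logits.max(1, keepdims=True))
        ss_probs /= ss_probs.sum(1, keepdims=True)
        X = assemble_features(sequence, pssm, psfm, acc, ss_probs)

        phi_mask = np.ones(L, dtype=bool)
        psi_mask = np.ones(L, dtype=bool)
        phi_mask[0] = False   # N-terminal phi does not exist
        psi_mask[-1] = False  # C-terminal psi does not exist
        phi_out = phi.copy()
        psi_out = psi.copy()
        phi_out[0] = np.nan
        psi_out[-1] = np.nan

        proteins.append(Protein(
            id=f"synth{i:04d}", sequence=sequence,
            phi=phi_out, psi=psi_out,
            phi_mask=phi_mask, psi_mask=psi_mask,
            ss=ss, features=X, basin_truth=basin + 1))
    return proteins


def split_proteins(proteins: Sequence[Protein], train_fraction: float = 0.8,
                   seed: int = 0):
    """Deterministic random train/validation split of a bundle."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(proteins))
    n_train = max(1, int(round(train_fraction * len(proteins))))
    n_train = min(n_train, len(proteins) - 1)
    train = [proteins[i] for i in order[:n_train]]
    val = [proteins[i] for i in order[n_train:]]
    return train, val
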