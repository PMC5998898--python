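"""Per-protein record shared by the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["Protein"]


@dataclass
class Protein:
    """One chain: sequence, dihedral angles with validity masks, labels, features.

    ``phi``/``psi`` are degrees in [-180, 180); positions where a dihedral
    does not exist structurally (phi at the N-terminus, psi at the
    C-terminus, chain breaks) are masked out via ``phi_mask``/``psi_mask``
    (True = defined) and carry NaN in the angle arrays.
    """

    id: str
    sequence: str
    phi: np.ndarray
    psi: np.ndarray
    phi_mask: np.ndarray
    psi_mask: np.ndarray
    ss: Optional[np.ndarray] = None          # 3-state labels 'H'/'E'/'C'
    features: Optional[np.ndarray] = None    # (L, 66)
    basin_truth: Optional[np.ndarray] = None  # generator ground truth (1-based)

    def __post_init__(self):
        L = len(self.sequence)
        for name in ("phi", "psi", "phi_mask", "psi_mask"):
            arr = getattr(self, name)
            if len(arr) != L:
                raise ValueError(f"{name} length {len(arr)} != sequence length {L}")
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.phi_mask = np.asarray(self.phi_mask, dtype=bool)
        self.psi_mask = np.asarray(self.psi_mask, dtype=bool)

    def __len__(self) -> int:
        return len(self.sequence)

    def pair_mask(self) -> np.ndarray:
        """Positions where both dihedrals are defined (usable as a pair)."""
        return self.phi_mask & self.psi_mask
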