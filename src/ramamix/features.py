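"""The 66-column per-residue feature encoding.

Fixed column order (one row per residue):

    0..19   PSSM        log-odds profile from iterative sequence search
    20..39  PSFM        frequency profile from a profile-HMM alignment
    40..59  one-hot amino acid (alphabetical one-letter order A,C,D,...,Y)
    60..62  ACC         predicted solvent-accessibility class probabilities
    63..65  SS          predicted 3-state secondary-structure probabilities

Profile values are consumed as provided (no squashing); an unknown residue
gets an all-zero one-hot block with a logged warning.
"""

from __future__ import annotations

import logging

import numpy as np

__all__ = ["AA_ORDER", "N_FEATURES", "assemble_features", "validate_features",
           "feature_names", "one_hot_sequence"]

log = logging.getLogger(__name__)

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
N_FEATURES = 66


def feature_names() -> list[str]:
    """Column names of the feature matrix, in order."""
    return ([f"pssm_{a}" for a in AA_ORDER]
            + [f"psfm_{a}" for a in AA_ORDER]
            + [f"aa_{a}" for a in AA_ORDER]
            + ["acc_B", "acc_M", "acc_E"]
            + ["ss_H", "ss_E", "ss_C"])


def one_hot_sequence(sequence: str) -> np.ndarray:
    """(L, 20) one-hot encoding; non-standard residues get all zeros."""
    L = len(sequence)
    out = np.zeros((L, 20))
    for i, aa in enumerate(sequence.upper()):
        j = AA_INDEX.get(aa)
        if j is None:
            log.warning("non-standard residue %r at position %d: zero one-hot",
                        aa, i + 1)
        else:
            out[i, j] = 1.0
    return out


def assemble_features(sequence: str, pssm, psfm, acc, ss) -> np.ndarray:
    """Concatenate the five blocks into the (L, 66) feature matrix.

    ``pssm``/``psfm`` are (L, 20); ``acc``/``ss`` are (L, 3) probability
    blocks.  All block lengths must match the sequence.
    """
    L = len(sequence)
    blocks = {"pssm": (pssm, 20), "psfm": (psfm, 20),
              "acc": (acc, 3), "ss": (ss, 3)}
    arrays = {}
    for name, (block, width) in blocks.items():
        arr = np.asarray(block, dtype=float)
        if arr.shape != (L, width):
            raise ValueError(
                f"{name} block has shape {arr.shape}, expected ({L}, {width})")
        arrays[name] = arr
    X = np.hstack([arrays["pssm"], arrays["psfm"], one_hot_sequence(sequence),
                   arrays["acc"], arrays["ss"]])
    assert X.shape == (L, N_FEATURES)
    return X


def validate_features(X) -> np.ndarray:
    """Check the 66-column contract; returns the matrix as float64."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise ValueError(f"feature matrix must have {N_FEATURES} columns, "
                         f"got shape {X.shape}")
    return X
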