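"""Readers and writers for the package's on-disk formats.

Everything per-residue is tab-separated text: a 66-column feature TSV, an
angle TSV (position, residue, phi, psi, secondary structure, optional
basin truth), prediction and report TSVs, and a bundle manifest tying the
per-protein files together.  Floats are written with full ``repr``
precision so a read-back is bit-exact.  PSI-BLAST ASCII PSSM files (the
``-Q`` output dialect) are also parsed.
"""

from __future__ import annotations

import os

import numpy as np
from Bio import SeqIO

from .features import N_FEATURES, feature_names, validate_features
from .protein import Protein

__all__ = ["write_feature_tsv", "read_feature_tsv", "write_angle_tsv",
           "read_angle_tsv", "write_bundle", "read_bundle",
           "read_pssm_ascii", "read_fasta", "ParseError"]

#: residue-column order of PSI-BLAST PSSM files
PSIBLAST_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def _fmt(x: float) -> str:
    return repr(float(x))


# -- feature TSV -----------------------------------------------------------

def write_feature_tsv(X, path) -> None:
    X = validate_features(X)
    with open(path, "w") as fh:
        fh.write("\t".join(feature_names()) + "\n")
        for row in X:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def read_feature_tsv(path) -> np.ndarray:
    """Header-validated (L, 66) matrix; '#' comment lines are ignored."""
    rows = []
    expected = feature_names()
    saw_header = False
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if not saw_header:
                if parts != expected:
                    raise ParseError(
                        f"{path}:{lineno}: bad header ({len(parts)} columns, "
                        f"expected the {N_FEATURES} feature names)")
                saw_header = True
                continue
            if len(parts) != N_FEATURES:
                raise ParseError(f"{path}:{lineno}: {len(parts)} columns, "
                                 f"expected {N_FEATURES}")
            try:
                rows.append([float(v) for v in parts])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})")
    if not saw_header:
        raise ParseError(f"{path}: missing header line")
    return np.array(rows, dtype=float).reshape(len(rows), N_FEATURES)


# -- angle TSV -------------------------------------------------------------

def write_angle_tsv(protein: Protein, path) -> None:
    with open(path, "w") as fh:
        fh.write("pos\taa\tphi\tpsi\tss\tbasin\n")
        for i in range(len(protein)):
            phi = _fmt(protein.phi[i]) if protein.phi_mask[i] else "NA"
            psi = _fmt(protein.psi[i]) if protein.psi_mask[i] else "NA"
            ss = protein.ss[i] if protein.ss is not None else "NA"
            basin = (str(int(protein.basin_truth[i]))
                     if protein.basin_truth is not None else "NA")
            fh.write(f"{i + 1}\t{protein.sequence[i]}\t{phi}\t{psi}\t"
                     f"{ss}\t{basin}\n")


def read_angle_tsv(path) -> dict:
    seq, phi, psi, pm, sm, ss, basin = [], [], [], [], [], [], []
    with open(path, newline="") as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                if parts != ["pos", "aa", "phi", "psi", "ss", "basin"]:
                    raise ParseError(f"{path}:{lineno}: bad angle-file header")
                continue
            if len(parts) != 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns")
            seq.append(parts[1])
            for tok, vals, mask in ((parts[2], phi, pm), (parts[3], psi, sm)):
                if tok == "NA":
                    vals.append(np.nan)
                    mask.append(False)
                else:
                    vals.append(float(tok))
                    mask.append(True)
            ss.append(parts[4])
            basin.append(parts[5])
    return {
        "sequence": "".join(seq),
        "phi": np.array(phi), "psi": np.array(psi),
        "phi_mask": np.array(pm, dtype=bool),
        "psi_mask": np.array(sm, dtype=bool),
        "ss": None if all(s == "NA" for s in ss) else np.array(ss),
        "basin": (None if all(b == "NA" for b in basin)
                  else np.array([int(b) for b in basin])),
    }


# -- bundles ---------------------------------------------------------------

def write_bundle(proteins, directory) -> None:
    """Write a dataset bundle: manifest.tsv plus per-protein feature and
    angle files."""
    os.makedirs(directory, exist_ok=True)
    with open(os.path.join(directory, "manifest.tsv"), "w") as fh:
        fh.write("id\tlength\tfeatures\tangles\n")
        for p in proteins:
            feat = f"{p.id}.features.tsv"
            ang = f"{p.id}.angles.tsv"
            fh.write(f"{p.id}\t{len(p)}\t{feat}\t{ang}\n")
            write_feature_tsv(p.features, os.path.join(directory, feat))
            write_angle_tsv(p, os.path.join(directory, ang))


def read_bundle(directory) -> list[Protein]:
    manifest = os.path.join(directory, "manifest.tsv")
    proteins = []
    with open(manifest, newline="") as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                if parts != ["id", "length", "features", "angles"]:
                    raise ParseError(f"{manifest}:{lineno}: bad manifest header")
                continue
            pid, length, feat, ang = parts
            X = read_feature_tsv(os.path.join(directory, feat))
            a = read_angle_tsv(os.path.join(directory, ang))
            if len(a["sequence"]) != int(length) or X.shape[0] != int(length):
                raise ParseError(
                    f"{manifest}:{lineno}: inconsistent lengths for {pid}")
            proteins.append(Protein(
                id=pid, sequence=a["sequence"], phi=a["phi"], psi=a["psi"],
                phi_mask=a["phi_mask"], psi_mask=a["psi_mask"],
                ss=a["ss"], features=X, basin_truth=a["basin"]))
    return proteins


# -- external formats ------------------------------------------------------

def read_pssm_ascii(path) -> np.ndarray:
    """Parse a PSI-BLAST ASCII PSSM (the ``-Q`` dialect) into an (L, 20)
    log-odds matrix with columns remapped to alphabetical residue order."""
    rows = []
    with open(path, newline="") as fh:
        lines = fh.read().splitlines()
    if not any(line.strip() for line in lines):
        raise ParseError(f"{path}: empty PSSM file")
    remap = [PSIBLAST_AA_ORDER.index(a) for a in
             "ACDEFGHIKLMNPQRSTVWY"]
    header_seen = False
    for lineno, line in enumerate(lines, start=1):
        toks = line.split()
        if not header_seen:
            # the column-header line repeats the 20 residue letters
            if len(toks) >= 20 and all(t in PSIBLAST_AA_ORDER for t in toks[:20]):
                header_seen = True
            continue
        if len(toks) < 22:
            if rows:
                break  # trailer (K, Lambda statistics)
            continue
        if not toks[0].isdigit():
            if rows:
                break
            raise ParseError(f"{path}:{lineno}: expected residue row")
        try:
            vals = [int(t) for t in toks[2:22]]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad PSSM value ({exc})")
        rows.append([vals[j] for j in remap])
    if not header_seen or not rows:
        raise ParseError(f"{path}: no PSSM rows found")
    return np.array(rows, dtype=float)


def read_fasta(path) -> list[tuple[str, str]]:
    """(id, sequence) pairs; non-standard residues are kept (the feature
    encoder warns and zero-fills their one-hot)."""
    return [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]
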