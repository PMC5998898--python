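"""Periodicity-aware evaluation metrics and stratified reports.

MAE uses the periodicity-corrected difference min(d, 360 - d), so an
error across the -180/180 seam counts its true angular size.  Correlation
is computed between trigonometric transforms (cos or sin) of predicted
and true angles, pooled over all residues of a dataset.  Reports can be
stratified by 3-state secondary structure and by amino-acid type, and the
error-versus-standard-deviation analysis quantifies how well the
predicted confidence bounds track realised errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import angular_difference

__all__ = ["mae", "pcc_trig", "stratified_report", "write_report_tsv",
           "error_bound_fit", "error_prediction_scores", "reduce_ss8",
           "LinearFit"]

SS8_TO_SS3 = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}


def reduce_ss8(labels) -> np.ndarray:
    """8-state secondary structure to 3 states: H,G,I -> H; E,B -> E; else C."""
    return np.array([SS8_TO_SS3.get(s, "C") for s in labels])


def _masked(pred, true, mask):
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("pred and true must have equal length")
    if mask is None:
        mask = np.isfinite(pred) & np.isfinite(true)
    else:
        mask = np.asarray(mask, dtype=bool)
    return pred[mask], true[mask]


def mae(pred, true, mask=None) -> float:
    """Mean periodicity-corrected absolute error in degrees."""
    p, t = _masked(pred, true, mask)
    if p.size == 0:
        raise ValueError("no unmasked residue pairs to evaluate")
    return float(angular_difference(p, t).mean())


def pcc_trig(pred, true, fn: str = "cos", mask=None) -> float:
    """Pearson correlation between cos (or sin) of predicted and true angles."""
    if fn not in ("cos", "sin"):
        raise ValueError("fn must be 'cos' or 'sin'")
    p, t = _masked(pred, true, mask)
    if p.size < 2:
        raise ValueError("need >= 2 unmasked pairs for a correlation")
    f = np.cos if fn == "cos" else np.sin
    x, y = f(np.deg2rad(p)), f(np.deg2rad(t))
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


_METRIC_COLS = ["n_residues", "MAE_phi", "MAE_psi", "PCC_cos_phi",
                "PCC_cos_psi", "PCC_sin_phi", "PCC_sin_psi"]


def _stratum_row(pred_phi, pred_psi, true_phi, true_psi, phi_mask, psi_mask):
    row = {"n_residues": int((phi_mask | psi_mask).sum())}
    row["MAE_phi"] = mae(pred_phi, true_phi, phi_mask) if phi_mask.any() else np.nan
    row["MAE_psi"] = mae(pred_psi, true_psi, psi_mask) if psi_mask.any() else np.nan
    for fn in ("cos", "sin"):
        try:
            row[f"PCC_{fn}_phi"] = pcc_trig(pred_phi, true_phi, fn, phi_mask)
        except ValueError:
            row[f"PCC_{fn}_phi"] = np.nan
        try:
            row[f"PCC_{fn}_psi"] = pcc_trig(pred_psi, true_psi, fn, psi_mask)
        except ValueError:
            row[f"PCC_{fn}_psi"] = np.nan
    return row


def stratified_report(pred_phi, pred_psi, true_phi, true_psi,
                      phi_mask, psi_mask, ss=None, sequence=None) -> pd.DataFrame:
    """Metrics for 'all' plus per-secondary-structure and per-amino-acid strata.

    All inputs are pooled 1-D arrays over a dataset's residues; ``ss`` is a
    3-state (or 8-state, reduced automatically) label array and
    ``sequence`` a same-length iterable of one-letter amino-acid codes.
    Returns a DataFrame indexed by stratum id.
    """
    pred_phi = np.asarray(pred_phi, dtype=float)
    pred_psi = np.asarray(pred_psi, dtype=float)
    true_phi = np.asarray(true_phi, dtype=float)
    true_psi = np.asarray(true_psi, dtype=float)
    phi_mask = np.asarray(phi_mask, dtype=bool)
    psi_mask = np.asarray(psi_mask, dtype=bool)

    rows = {"all": _stratum_row(pred_phi, pred_psi, true_phi, true_psi,
                                phi_mask, psi_mask)}
    if ss is not None:
        ss = np.asarray(list(ss))
        if set(np.unique(ss)) - {"H", "E", "C"}:
            ss = reduce_ss8(ss)
        for state in ("H", "E", "C"):
            sel = ss == state
            rows[state] = _stratum_row(pred_phi, pred_psi, true_phi, true_psi,
                                       phi_mask & sel, psi_mask & sel)
    if sequence is not None:
        seq = np.asarray(list(sequence))
        for aa in sorted(set(seq)):
            sel = seq == aa
            rows[f"aa_{aa}"] = _stratum_row(pred_phi, pred_psi,
                                            true_phi, true_psi,
                                            phi_mask & sel, psi_mask & sel)
    return pd.DataFrame.from_dict(rows, orient="index")[_METRIC_COLS]


def write_report_tsv(report: pd.DataFrame, path) -> None:
    """Write the benchmark-style wide MAE row (Phi, Psi, Phi_H, ... Psi_C),
    followed by the full per-stratum table."""
    cols, vals = ["Phi", "Psi"], [report.loc["all", "MAE_phi"],
                                  report.loc["all", "MAE_psi"]]
    for state in ("H", "E", "C"):
        if state in report.index:
            cols += [f"Phi_{state}", f"Psi_{state}"]
            vals += [report.loc[state, "MAE_phi"], report.loc[state, "MAE_psi"]]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        fh.write("\t".join(f"{v:.2f}" for v in vals) + "\n")
        fh.write("\n")
        report.to_csv(fh, sep="\t", index_label="stratum", float_format="%.4f")


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    zero_sst: bool = False  # all responses equal: R^2 returned as 0 by convention


def error_bound_fit(std, err) -> LinearFit:
    """Ordinary least squares of realised error on predicted standard deviation.

    Quantifies the (approximately linear) relationship between the
    confidence bound and the actual error; R^2 = 1 - SSR/SST.
    """
    x = np.asarray(std, dtype=float)
    y = np.asarray(err, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 (std, error) points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: all std values identical")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        return LinearFit(float(slope), float(intercept), 0.0, zero_sst=True)
    r2 = 1.0 - float((resid ** 2).sum()) / sst
    return LinearFit(float(slope), float(intercept), r2)


def error_prediction_scores(predicted_err, true_err):
    """Pearson and Spearman correlations between predicted and realised
    per-residue errors, plus their mean absolute difference (MAEPE)."""
    p = np.asarray(predicted_err, dtype=float)
    t = np.asarray(true_err, dtype=float)
    if p.size != t.size or p.size < 2:
        raise ValueError("need >= 2 aligned error pairs")
    if np.std(p) == 0 or np.std(t) == 0:
        raise ValueError("zero variance: correlation undefined")
    pcc = float(stats.pearsonr(p, t).statistic)
    scc = float(stats.spearmanr(p, t).statistic)
    maepe = float(np.abs(p - t).mean())
    return pcc, scc, maepe
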