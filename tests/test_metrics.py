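import numpy as np
import pytest
from scipy import stats

from ramamix import metrics


def test_mae_seam_example():
    assert metrics.mae([-179.0], [179.0]) == 2.0


def test_mae_zero_for_exact_prediction(rng):
    x = rng.uniform(-180, 180, 50)
    assert metrics.mae(x, x) == 0


def test_mae_matches_naive_loop(rng):
    pred = rng.uniform(-360, 360, 300)
    true = rng.uniform(-360, 360, 300)
    naive = np.mean([min(d, 360 - d)
                     for d in np.abs(pred - true) % 360])
    assert metrics.mae(pred, true) == pytest.approx(naive, rel=1e-12)


def test_mae_invariant_to_adding_full_turns(rng):
    pred = rng.uniform(-180, 180, 100)
    true = rng.uniform(-180, 180, 100)
    assert metrics.mae(pred + 360, true) == pytest.approx(
        metrics.mae(pred, true), rel=1e-12)


def test_mae_respects_mask():
    pred = np.array([0.0, 100.0])
    true = np.array([10.0, 100.0])
    assert metrics.mae(pred, true, mask=np.array([True, False])) == 10


def test_mae_all_masked_raises():
    with pytest.raises(ValueError):
        metrics.mae([0.0], [1.0], mask=np.array([False]))


def test_pcc_perfect_and_antisymmetric(rng):
    true = rng.uniform(10, 170, 100)
    assert metrics.pcc_trig(true, true, "cos") == pytest.approx(1.0)
    assert metrics.pcc_trig(180 - true, true, "cos") == pytest.approx(-1.0)


def test_pcc_matches_textbook_formula(rng):
    pred = rng.uniform(-180, 180, 200)
    true = pred + rng.normal(0, 30, 200)
    x, y = np.cos(np.deg2rad(pred)), np.cos(np.deg2rad(true))
    ref = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
    assert metrics.pcc_trig(pred, true, "cos") == pytest.approx(ref, rel=1e-9)


def test_pcc_permutation_invariant(rng):
    pred = rng.uniform(-180, 180, 100)
    true = rng.uniform(-180, 180, 100)
    perm = rng.permutation(100)
    assert metrics.pcc_trig(pred[perm], true[perm], "sin") == pytest.approx(
        metrics.pcc_trig(pred, true, "sin"), rel=1e-12)


def test_pcc_zero_variance_raises():
    with pytest.raises(ValueError):
        metrics.pcc_trig([0.0, 0.0, 0.0], [10.0, 20.0, 30.0])


def test_reduce_ss8():
    out = metrics.reduce_ss8(list("HGIEBTSC-"))
    assert "".join(out) == "HHHEECCCC"


def _report_inputs(rng, n=200):
    true_phi = rng.uniform(-180, 180, n)
    true_psi = rng.uniform(-180, 180, n)
    pred_phi = true_phi + rng.normal(0, 15, n)
    pred_psi = true_psi + rng.normal(0, 25, n)
    mask = np.ones(n, dtype=bool)
    ss = rng.choice(list("HEC"), n)
    seq = rng.choice(list("ACDEFG"), n)
    return pred_phi, pred_psi, true_phi, true_psi, mask, ss, seq


def test_stratified_report_counts_sum(rng):
    pp, sp, tp, ts, mask, ss, seq = _report_inputs(rng)
    rep = metrics.stratified_report(pp, sp, tp, ts, mask, mask, ss, seq)
    assert rep.loc["all", "n_residues"] == 200
    assert sum(rep.loc[s, "n_residues"] for s in "HEC") == 200
    aa_rows = [i for i in rep.index if i.startswith("aa_")]
    assert sum(rep.loc[i, "n_residues"] for i in aa_rows) == 200


def test_stratified_report_single_stratum_equals_all(rng):
    pp, sp, tp, ts, mask, _, seq = _report_inputs(rng)
    ss = np.array(["H"] * 200)
    rep = metrics.stratified_report(pp, sp, tp, ts, mask, mask, ss)
    assert rep.loc["H", "MAE_phi"] == rep.loc["all", "MAE_phi"]


def test_stratified_report_matches_manual_partition(rng):
    pp, sp, tp, ts, mask, ss, seq = _report_inputs(rng)
    rep = metrics.stratified_report(pp, sp, tp, ts, mask, mask, ss, seq)
    sel = ss == "E"
    assert rep.loc["E", "MAE_phi"] == pytest.approx(
        metrics.mae(pp[sel], tp[sel]), rel=1e-12)
    assert rep.loc["aa_C", "MAE_psi"] == pytest.approx(
        metrics.mae(sp[seq == "C"], ts[seq == "C"]), rel=1e-12)


def test_report_writer_has_benchmark_columns(rng, tmp_path):
    pp, sp, tp, ts, mask, ss, seq = _report_inputs(rng)
    rep = metrics.stratified_report(pp, sp, tp, ts, mask, mask, ss, seq)
    path = tmp_path / "report.tsv"
    metrics.write_report_tsv(rep, path)
    header = path.read_text().splitlines()[0].split("\t")
    assert header == ["Phi", "Psi", "Phi_H", "Psi_H", "Phi_E", "Psi_E",
                      "Phi_C", "Psi_C"]


def test_error_bound_fit_collinear():
    fit = metrics.error_bound_fit([1, 2, 3], [2, 4, 6])
    assert fit.slope == pytest.approx(2)
    assert fit.intercept == pytest.approx(0, abs=1e-12)
    assert fit.r_squared == pytest.approx(1)


def test_error_bound_fit_horizontal_zero_sst():
    fit = metrics.error_bound_fit([1, 2, 3], [5, 5, 5])
    assert fit.slope == pytest.approx(0, abs=1e-12)
    assert fit.r_squared == 0 and fit.zero_sst


def test_error_bound_fit_matches_normal_equations(rng):
    x = rng.uniform(0, 50, 40)
    y = 0.8 * x + 3 + rng.normal(0, 2, 40)
    fit = metrics.error_bound_fit(x, y)
    A = np.vstack([x, np.ones_like(x)]).T
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    assert fit.slope == pytest.approx(beta[0], rel=1e-9)
    assert fit.intercept == pytest.approx(beta[1], rel=1e-9)


def test_error_bound_fit_degenerate_x():
    with pytest.raises(ValueError):
        metrics.error_bound_fit([2, 2, 2], [1, 2, 3])


def test_error_prediction_scores_identity_and_reversal(rng):
    e = rng.uniform(0, 50, 30)
    pcc, scc, maepe = metrics.error_prediction_scores(e, e)
    assert pcc == pytest.approx(1) and scc == pytest.approx(1) and maepe == 0
    ranks = np.argsort(np.argsort(e))
    rev = e[np.argsort(e)][::-1][ranks]  # reverse the ranking
    _, scc, _ = metrics.error_prediction_scores(rev, e)
    assert scc == pytest.approx(-1)


def test_spearman_matches_rank_pearson(rng):
    p = rng.uniform(0, 1, 100)
    t = rng.uniform(0, 1, 100)  # continuous: ties-free w.p. 1
    _, scc, _ = metrics.error_prediction_scores(p, t)
    ref = stats.pearsonr(stats.rankdata(p), stats.rankdata(t)).statistic
    assert scc == pytest.approx(ref, rel=1e-12)
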