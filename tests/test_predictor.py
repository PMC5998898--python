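import numpy as np
import pytest

from ramamix import clustering, geometry, predict
from ramamix.predict import confidence, mix_to_angles, predict_protein, top_r_mix


def _one_hot(k, K):
    p = np.zeros(K)
    p[k] = 1.0
    return p


def test_one_hot_reproduces_center(fitted_clusters):
    m = fitted_clusters
    for k in range(m.K):
        phi, psi, degen = mix_to_angles(_one_hot(k, m.K), m)
        assert not degen
        assert phi == pytest.approx(m.center_phi[k], abs=1e-9)
        assert psi == pytest.approx(m.center_psi[k], abs=1e-9)


def test_mix_matches_printed_formula(rng, fitted_clusters):
    """The mixture must equal the explicit v0/sqrt(v0^2+v1^2) reconstruction."""
    m = fitted_clusters
    for _ in range(1000):
        p = rng.dirichlet(np.ones(m.K))
        v = p @ m.centers
        cphi = v[0] / np.hypot(v[0], v[1])
        sphi = v[1] / np.hypot(v[0], v[1])
        cpsi = v[2] / np.hypot(v[2], v[3])
        spsi = v[3] / np.hypot(v[2], v[3])
        ref_phi = geometry.wrap_angle(np.rad2deg(np.arctan2(sphi, cphi)))
        ref_psi = geometry.wrap_angle(np.rad2deg(np.arctan2(spsi, cpsi)))
        phi, psi, _ = mix_to_angles(p, m)
        assert geometry.angular_difference(phi, ref_phi) < 1e-9
        assert geometry.angular_difference(psi, ref_psi) < 1e-9


def _two_cluster_model(phi1, phi2, psi):
    """Tiny hand-built model with two centers sharing psi."""
    centers = geometry.normalize_pairs(np.array([
        geometry.to_vector(phi1, psi), geometry.to_vector(phi2, psi)]))
    cphi, cpsi = geometry.to_angles(centers)
    return clustering.ClusterModel(
        K=2, raw_centers=centers.copy(), centers=centers,
        center_phi=cphi, center_psi=cpsi,
        background=np.array([0.5, 0.5]),
        circ_mean_phi=cphi.copy(), circ_mean_psi=cpsi.copy(),
        var_phi=np.array([100.0, 400.0]), var_psi=np.array([225.0, 225.0]),
        bvm_params=[None, None], seed=0)


def test_degenerate_phi_cancellation_falls_back():
    m = _two_cluster_model(90.0, -90.0, 30.0)  # opposite phi vectors
    phi, psi, degen = mix_to_angles(np.array([0.5, 0.5]), m)
    assert degen
    assert phi == pytest.approx(m.center_phi[0])  # argmax tie -> first cluster
    assert psi == pytest.approx(30.0, abs=1e-9)   # shared psi survives


def test_top_r_full_k_equals_plain_mixing(rng, fitted_clusters):
    m = fitted_clusters
    for _ in range(50):
        p = rng.dirichlet(np.ones(m.K))
        assert top_r_mix(p, m, m.K)[:2] == mix_to_angles(p, m)[:2]


def test_top_r_one_returns_argmax_center(rng, fitted_clusters):
    m = fitted_clusters
    p = rng.dirichlet(np.ones(m.K))
    phi, psi, _ = top_r_mix(p, m, 1)
    k = int(p.argmax())
    assert phi == pytest.approx(m.center_phi[k], abs=1e-9)
    assert psi == pytest.approx(m.center_psi[k], abs=1e-9)


def test_top_r_two_matches_hand_renormalization(fitted_clusters):
    m = fitted_clusters
    p = np.array([0.5, 0.3, 0.1, 0.06, 0.04])
    q = np.array([0.5 / 0.8, 0.3 / 0.8, 0, 0, 0])
    phi, psi, _ = top_r_mix(p, m, 2)
    ref_phi, ref_psi, _ = mix_to_angles(q, m)
    assert phi == pytest.approx(ref_phi, abs=1e-9)
    assert psi == pytest.approx(ref_psi, abs=1e-9)


def test_top_r_out_of_range(fitted_clusters):
    with pytest.raises(ValueError):
        top_r_mix(np.ones(5) / 5, fitted_clusters, 0)
    with pytest.raises(ValueError):
        top_r_mix(np.ones(5) / 5, fitted_clusters, 6)


def test_confidence_one_hot_gives_cluster_std(fitted_clusters):
    m = fitted_clusters
    for k in range(m.K):
        sphi, spsi = confidence(_one_hot(k, m.K), m)
        assert sphi == pytest.approx(np.sqrt(m.var_phi[k]))
        assert spsi == pytest.approx(np.sqrt(m.var_psi[k]))


def test_confidence_shared_variance_fixed_point(rng):
    m = _two_cluster_model(-60.0, 60.0, 30.0)
    m.var_phi = np.array([49.0, 49.0])
    m.var_psi = np.array([49.0, 49.0])
    for _ in range(10):
        p = rng.dirichlet(np.ones(2))
        assert confidence(p, m) == (pytest.approx(7.0), pytest.approx(7.0))


def test_confidence_matches_weighted_sum(rng, fitted_clusters):
    m = fitted_clusters
    for _ in range(100):
        p = rng.dirichlet(np.ones(m.K))
        sphi, spsi = confidence(p, m)
        assert sphi == pytest.approx(np.sqrt(np.dot(p, m.var_phi)), rel=1e-12)
        assert spsi == pytest.approx(np.sqrt(np.dot(p, m.var_psi)), rel=1e-12)


def test_confidence_bounded_by_cluster_stds(rng, fitted_clusters):
    m = fitted_clusters
    lo, hi = np.sqrt(m.var_phi.min()), np.sqrt(m.var_phi.max())
    for _ in range(100):
        sphi, _ = confidence(rng.dirichlet(np.ones(m.K)), m)
        assert lo - 1e-12 <= sphi <= hi + 1e-12


def test_mix_equivariant_under_rigid_phi_rotation(rng, fitted_clusters):
    """Rotating every center's phi by 90 degrees rotates the mixed phi by 90."""
    m = fitted_clusters
    rot = _rotated_model(m, 90.0)
    for _ in range(50):
        p = rng.dirichlet(np.ones(m.K))
        phi, psi, _ = mix_to_angles(p, m)
        phi_r, psi_r, _ = mix_to_angles(p, rot)
        assert geometry.angular_difference(phi_r, phi + 90.0) < 1e-9
        assert geometry.angular_difference(psi_r, psi) < 1e-9


def _rotated_model(m, delta_phi):
    cphi = geometry.wrap_angle(m.center_phi + delta_phi)
    centers = geometry.to_vector(cphi, m.center_psi)
    import copy
    rot = copy.deepcopy(m)
    rot.centers = centers
    rot.center_phi = cphi
    return rot


def test_predict_protein_records(fitted_clusters, rng):
    m = fitted_clusters
    L = 8
    P = rng.dirichlet(np.ones(m.K), size=L)
    mask = np.ones(L, dtype=bool)
    mask[0] = False
    recs = predict_protein(m, P, mask=mask)
    assert len(recs) == L
    assert np.isnan(recs[0].phi) and recs[0].top_label == 0
    assert recs[3].position == 4
    one_hot = np.zeros(m.K); one_hot[2] = 1
    rec = predict_protein(m, one_hot[None])[0]
    assert rec.phi == pytest.approx(m.center_phi[2], abs=1e-9)
    assert rec.std_phi == pytest.approx(np.sqrt(m.var_phi[2]))
    assert rec.top_label == 3


def test_predict_protein_k_mismatch(fitted_clusters, rng):
    with pytest.raises(ValueError):
        predict_protein(fitted_clusters, rng.dirichlet(np.ones(7), size=4))


def test_prediction_tsv_writer(fitted_clusters, rng, tmp_path):
    m = fitted_clusters
    P = rng.dirichlet(np.ones(m.K), size=3)
    mask = np.array([False, True, True])
    recs = predict_protein(m, P, mask=mask)
    path = tmp_path / "pred.tsv"
    predict.write_prediction_tsv(recs, "ACD", path)
    lines = path.read_text().splitlines()
    assert lines[0].startswith("# pos aa phi")
    assert lines[1].split("\t")[2] == "NA"
    assert len(lines) == 4
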