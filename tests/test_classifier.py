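import numpy as np
import pytest

from ramamix import features, network, synthetic
from ramamix.network import Architecture


def test_assemble_features_has_66_ordered_columns(rng):
    L = 7
    seq = "ACDEFGH"
    X = features.assemble_features(
        seq, rng.normal(size=(L, 20)), rng.normal(size=(L, 20)),
        rng.dirichlet(np.ones(3), L), rng.dirichlet(np.ones(3), L))
    assert X.shape == (L, 66)
    assert features.feature_names()[0] == "pssm_A"
    assert features.feature_names()[40] == "aa_A"


def test_one_hot_alphabetical_convention():
    oh = features.one_hot_sequence("AY")
    assert oh[0, 0] == 1 and oh[0].sum() == 1
    assert oh[1, 19] == 1


def test_unknown_residue_zero_one_hot(caplog):
    oh = features.one_hot_sequence("X")
    assert oh.sum() == 0


def test_assemble_features_length_mismatch():
    with pytest.raises(ValueError):
        features.assemble_features("ACD", np.zeros((2, 20)), np.zeros((3, 20)),
                                   np.zeros((3, 3)), np.zeros((3, 3)))


def _toy_examples(n=12, L=30, K=3, noise=0.0, seed=0):
    """Linearly separable toy proteins: one informative block per class."""
    rng = np.random.default_rng(seed)
    templates = rng.normal(0, 2.0, size=(K, 20))
    out = []
    for _ in range(n):
        y = rng.integers(1, K + 1, size=L)
        pssm = templates[y - 1] + noise * rng.normal(size=(L, 20))
        seq = "".join(rng.choice(list(features.AA_ORDER), size=L))
        X = features.assemble_features(
            seq, pssm, np.zeros((L, 20)), np.full((L, 3), 1 / 3),
            np.full((L, 3), 1 / 3))
        out.append((X, y))
    return out


SMALL = Architecture(n_blocks=1, n_filters=16, half_window=2)


def test_train_reaches_high_accuracy_on_separable_data():
    ex = _toy_examples()
    clf = network.train(ex, K=3, arch=SMALL, epochs=15, seed=0)
    correct = total = 0
    for X, y in ex:
        pred = clf.predict_probs(X).argmax(1) + 1
        correct += (pred == y).sum()
        total += y.size
    assert correct / total > 0.9


def test_train_objective_non_increasing():
    ex = _toy_examples()
    clf = network.train(ex, K=3, arch=SMALL, epochs=10, seed=1)
    h = np.array(clf.objective_history)
    assert np.all(np.diff(h) <= 1e-6)


def test_train_deterministic_given_seed():
    ex = _toy_examples()
    a = network.train(ex, K=3, arch=SMALL, epochs=3, seed=7)
    b = network.train(ex, K=3, arch=SMALL, epochs=3, seed=7)
    for k in a.params:
        np.testing.assert_array_equal(a.params[k], b.params[k])


def test_huge_regularization_shrinks_to_background():
    """With lambda = 1e6 the weights collapse and the free biases learn the
    class background frequencies."""
    rng = np.random.default_rng(3)
    ex = []
    for _ in range(8):
        L = 40
        y = rng.choice([1, 2, 3], size=L, p=[0.6, 0.3, 0.1])
        X = rng.normal(size=(L, 66))
        ex.append((X, y))
    clf = network.train(ex, K=3, arch=SMALL, lam=1e6, epochs=60, lr=0.1,
                        batch_size=2, seed=0, track_objective=False)
    pred = np.vstack([clf.predict_probs(X) for X, _ in ex]).mean(axis=0)
    labels = np.concatenate([y for _, y in ex])
    bg = np.bincount(labels - 1, minlength=3) / labels.size
    assert np.abs(pred - bg).sum() / 2 < 0.05  # total variation


def test_predict_probs_rows_on_simplex(rng):
    ex = _toy_examples(n=4)
    clf = network.train(ex, K=3, arch=SMALL, epochs=2, seed=0,
                        track_objective=False)
    P = clf.predict_probs(ex[0][0])
    np.testing.assert_allclose(P.sum(axis=1), 1, atol=1e-9)
    assert np.all(P >= 0)


def test_predict_probs_stateless_across_calls():
    ex = _toy_examples(n=4)
    clf = network.train(ex, K=3, arch=SMALL, epochs=2, seed=0,
                        track_objective=False)
    P1 = clf.predict_probs(ex[0][0])
    clf.predict_probs(ex[1][0])
    P2 = clf.predict_probs(ex[0][0])
    np.testing.assert_array_equal(P1, P2)


def test_predict_probs_rejects_wrong_column_count(rng):
    ex = _toy_examples(n=4)
    clf = network.train(ex, K=3, arch=SMALL, epochs=1, seed=0,
                        track_objective=False)
    with pytest.raises(ValueError):
        clf.predict_probs(rng.normal(size=(10, 65)))


def test_checkpoint_round_trip(tmp_path):
    ex = _toy_examples(n=4)
    clf = network.train(ex, K=3, arch=SMALL, epochs=2, seed=0)
    path = tmp_path / "clf.npz"
    clf.save(path)
    loaded = network.ResidualConvClassifier.load(path)
    assert loaded.arch == clf.arch and loaded.K == clf.K
    np.testing.assert_array_equal(loaded.predict_probs(ex[0][0]),
                                  clf.predict_probs(ex[0][0]))


def test_ensemble_single_member_identity():
    ex = _toy_examples(n=4)
    clf = network.train(ex, K=3, arch=SMALL, epochs=1, seed=0,
                        track_objective=False)
    np.testing.assert_allclose(network.ensemble_probs([clf], ex[0][0]),
                               clf.predict_probs(ex[0][0]), atol=1e-12)


def test_ensemble_averages_members():
    ex = _toy_examples(n=4)
    m1 = network.train(ex, K=3, arch=SMALL, epochs=1, seed=0,
                       track_objective=False)
    m2 = network.train(ex, K=3, arch=SMALL, epochs=1, seed=1,
                       track_objective=False)
    P = network.ensemble_probs([m1, m2], ex[0][0])
    ref = (m1.predict_probs(ex[0][0]) + m2.predict_probs(ex[0][0])) / 2
    ref /= ref.sum(axis=1, keepdims=True)
    np.testing.assert_allclose(P, ref, atol=1e-12)


def test_ensemble_rejects_inconsistent_k():
    ex = _toy_examples(n=4)
    m1 = network.train(ex, K=3, arch=SMALL, epochs=1, seed=0,
                       track_objective=False)
    ex4 = [(X, y) for X, y in ex]
    m2 = network.train(ex4, K=4, arch=SMALL, epochs=1, seed=0,
                       track_objective=False)
    with pytest.raises(ValueError):
        network.ensemble_probs([m1, m2], ex[0][0])


def test_held_out_basin_accuracy_on_synthetic_proteins(small_bundle,
                                                       fitted_clusters):
    """Full-pipeline classification on well-separated synthetic basins:
    argmax accuracy on held-out proteins beats 0.8 for each of 3 seeds."""
    train, val = synthetic.split_proteins(small_bundle, 0.75, seed=2)
    for seed in (0, 1, 2):
        ex = network.examples_from_proteins(train, fitted_clusters)
        clf = network.train(ex, fitted_clusters.K,
                            arch=Architecture(n_blocks=2, n_filters=32),
                            epochs=10, seed=seed, track_objective=False)
        correct = total = 0
        for p in val:
            ok = p.pair_mask()
            ytrue = fitted_clusters.assign(p.phi[ok], p.psi[ok])
            pred = clf.predict_probs(p.features).argmax(1)[ok] + 1
            correct += (pred == ytrue).sum()
            total += ytrue.size
        assert correct / total > 0.8
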