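"""Motor-imagery decoding tests: CSP against closed forms and brute-force
oracles, LDA against the textbook solution, and the CSSP/FBCSP/BSSFO
variants on synthetic band-limited data."""

import numpy as np
import pytest
import scipy.linalg

from tribci.containers import ContinuousEEG, EpochSet, LabelBlock
from tribci.mi import (
    CSPModel, CSSPModel, FBCSPModel, MIMethodConfig, delay_embed, fit_bssfo,
    fit_csp, fit_cssp, fit_lda, logvar_features, make_model,
    mutual_information_binned, crossvalidate_mi, online_decode_mi,
)

from .conftest import make_epochs


def toy_epochs(rng, n_trials=40, n_channels=4, n_samples=100, fs=100.0, gain=3.0):
    """Two classes separable by variance: class 1 boosts ch0, class 2 ch1."""
    y = np.r_[np.ones(n_trials // 2, int), 2 * np.ones(n_trials // 2, int)]
    data = rng.standard_normal((n_trials, n_channels, n_samples))
    data[y == 1, 0] *= gain
    data[y == 2, 1] *= gain
    time_ms = np.arange(n_samples) / fs * 1000.0
    return EpochSet(data, time_ms, LabelBlock.from_y_dec(y, ["a", "b"]), fs)


def class_covariances(ep):
    """Reference implementation: trace-normalized average class covariances."""
    out = []
    for code in (1, 2):
        idx = np.flatnonzero(ep.labels.y_dec == code)
        acc = np.zeros((ep.n_channels, ep.n_channels))
        for i in idx:
            X = ep.data[i] - ep.data[i].mean(axis=1, keepdims=True)
            C = X @ X.T
            acc += C / np.trace(C)
        out.append(acc / idx.size)
    return out


def brute_force_csp_eigvals(ep):
    """Whitening-based oracle for the CSP eigenvalues."""
    S1, S2 = class_covariances(ep)
    Sc = S1 + S2
    d, V = np.linalg.eigh(Sc)
    W = V @ np.diag(d ** -0.5) @ V.T
    return np.linalg.eigvalsh(W @ S1 @ W.T)


class TestCSP:
    def test_analytic_two_channel_case(self, rng):
        """Orthogonal single-channel classes give eigenvalues {1, 0} and
        axis-aligned filters."""
        n, s = 30, 200
        y = np.r_[np.ones(n // 2, int), 2 * np.ones(n // 2, int)]
        data = np.zeros((n, 2, s))
        data[y == 1, 0] = rng.standard_normal((n // 2, s))
        data[y == 2, 1] = rng.standard_normal((n // 2, s))
        ep = EpochSet(data, np.arange(s) * 10.0, LabelBlock.from_y_dec(y, ["a", "b"]), 100.0)
        bank = fit_csp(ep, m=1)
        np.testing.assert_allclose(np.sort(bank.eigvals), [0.0, 1.0], atol=1e-12)
        # first filter (eigenvalue 1) has no weight on channel 1 and vice versa
        assert abs(bank.W[1, 0]) < 1e-10
        assert abs(bank.W[0, 1]) < 1e-10

    def test_eigvals_in_unit_interval_and_descending(self, rng):
        bank = fit_csp(toy_epochs(rng), m=2)
        assert np.all(bank.eigvals >= 0) and np.all(bank.eigvals <= 1)
        assert np.all(np.diff(bank.eigvals) <= 1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            ep = toy_epochs(rng, n_trials=16, n_channels=5, n_samples=60,
                            gain=rng.uniform(1.0, 4.0))
            bank = fit_csp(ep, m=2)
            oracle = brute_force_csp_eigvals(ep)
            np.testing.assert_allclose(np.sort(bank.eigvals), np.sort(oracle),
                                       atol=1e-8)

    def test_composite_normalization(self, rng):
        ep = toy_epochs(rng)
        bank = fit_csp(ep, m=2)
        S1, S2 = class_covariances(ep)
        q = bank.W.T @ (S1 + S2) @ bank.W
        np.testing.assert_allclose(q, np.eye(ep.n_channels), atol=1e-10)

    def test_label_swap_duality(self, rng):
        """Swapping class labels maps each eigenvalue to 1 - lambda."""
        ep = toy_epochs(rng)
        swapped = EpochSet(ep.data, ep.time_ms,
                           LabelBlock.from_y_dec(3 - ep.labels.y_dec, ["b", "a"]),
                           ep.fs)
        a = np.sort(fit_csp(ep, 2).eigvals)
        b = np.sort(fit_csp(swapped, 2).eigvals)
        np.testing.assert_allclose(a, np.sort(1.0 - b), atol=1e-10)

    def test_invariant_to_orthogonal_mixing(self, rng):
        """Eigenvalues are unchanged by orthogonal re-referencing (which
        preserves the per-trial covariance traces used for normalization)."""
        ep = toy_epochs(rng)
        A, _ = np.linalg.qr(rng.standard_normal((ep.n_channels, ep.n_channels)))
        mixed = EpochSet(np.einsum("dc,tcs->tds", A, ep.data), ep.time_ms,
                         ep.labels, ep.fs)
        np.testing.assert_allclose(np.sort(fit_csp(ep, 2).eigvals),
                                   np.sort(fit_csp(mixed, 2).eigvals), atol=1e-8)

    def test_selected_filters_are_extremes(self, rng):
        bank = fit_csp(toy_epochs(rng, n_channels=6), m=2)
        np.testing.assert_array_equal(bank.selected, [0, 1, 4, 5])

    def test_needs_two_trials_per_class(self, rng):
        ep = toy_epochs(rng, n_trials=40).subset([0, 1, 2, 20])
        with pytest.raises(ValueError, match="2 trials"):
            fit_csp(ep)

    def test_too_few_channels_rejected(self, rng):
        with pytest.raises(ValueError, match="channels"):
            fit_csp(toy_epochs(rng, n_channels=3), m=2)


class TestLogvar:
    def test_feature_identity(self, rng):
        ep = toy_epochs(rng)
        bank = fit_csp(ep, 2)
        F = logvar_features(ep, bank)
        assert F.shape == (ep.n_trials, 4)
        Z = np.einsum("tcs,cf->tfs", ep.data, bank.W[:, bank.selected])
        np.testing.assert_allclose(F, np.log(Z.var(axis=2)), atol=1e-12)

    def test_zero_variance_floored_with_warning(self, rng):
        ep = toy_epochs(rng)
        bank = fit_csp(ep, 2)
        ep.data[:] = 0.0
        with pytest.warns(UserWarning, match="zero-variance"):
            F = logvar_features(ep, bank)
        assert np.all(np.isfinite(F))


class TestLDA:
    def test_matches_closed_form(self, rng):
        X = rng.standard_normal((200, 3)) @ np.diag([1.0, 2.0, 0.5])
        y = np.r_[np.ones(100, int), 2 * np.ones(100, int)]
        X[y == 2] += [1.0, -0.5, 2.0]
        clf = fit_lda(X, y)
        X1, X2 = X[y == 1], X[y == 2]
        mu1, mu2 = X1.mean(0), X2.mean(0)
        Xc = np.vstack([X1 - mu1, X2 - mu2])
        S = Xc.T @ Xc / (len(X) - 2)
        w = np.linalg.solve(S, mu2 - mu1)
        np.testing.assert_allclose(clf.w, w, atol=1e-10)
        # midpoint of the class means lies on the decision boundary
        assert clf.decision_values((mu1 + mu2) / 2) == pytest.approx(0.0, abs=1e-10)
        assert np.mean(clf.predict(X) == y) > 0.8

    def test_label_swap_antisymmetry(self, rng):
        X = rng.standard_normal((80, 4))
        y = np.r_[np.ones(40, int), 2 * np.ones(40, int)]
        X[y == 2] += 1.0
        a = fit_lda(X, y)
        b = fit_lda(X, 3 - y)
        np.testing.assert_allclose(a.decision_values(X), -b.decision_values(X),
                                   atol=1e-9)
        np.testing.assert_array_equal(a.predict(X), 3 - b.predict(X))

    def test_singular_covariance_raises_and_shrinkage_fixes(self, rng):
        X = rng.standard_normal((10, 40))  # more features than samples
        y = np.r_[np.ones(5, int), 2 * np.ones(5, int)]
        with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
            fit_lda(X, y)
        clf = fit_lda(X, y, shrinkage="auto")
        assert 0.0 < clf.shrinkage <= 1.0

    def test_full_shrinkage_is_mean_difference_direction(self, rng):
        X = rng.standard_normal((60, 3))
        y = np.r_[np.ones(30, int), 2 * np.ones(30, int)]
        X[y == 2] += [2.0, 0.0, 0.0]
        clf = fit_lda(X, y, shrinkage=1.0)
        mu_diff = X[y == 2].mean(0) - X[y == 1].mean(0)
        cos = clf.w @ mu_diff / np.linalg.norm(clf.w) / np.linalg.norm(mu_diff)
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_requires_two_classes(self, rng):
        with pytest.raises(ValueError, match="2 classes"):
            fit_lda(rng.standard_normal((10, 2)), np.ones(10))


class TestCSPModel:
    def test_separable_data_perfect(self, rng):
        ep = toy_epochs(rng, n_trials=60, gain=4.0)
        te = toy_epochs(rng, n_trials=40, gain=4.0)
        model = CSPModel().fit(ep)
        assert np.mean(model.predict(te) == te.labels.y_dec) == 1.0

    def test_predictions_use_1based_codes(self, rng):
        ep = toy_epochs(rng)
        pred = CSPModel().fit(ep).predict(ep)
        assert set(np.unique(pred)) <= {1, 2}


class TestDelayEmbedAndCSSP:
    def test_delay_embed_geometry(self, rng):
        ep = make_epochs(rng, n_channels=3, n_samples=50)
        out = delay_embed(ep, 4)
        assert out.n_channels == 6
        assert out.n_samples == 46
        np.testing.assert_array_equal(out.data[0, 0], ep.data[0, 0, 4:])
        np.testing.assert_array_equal(out.data[0, 3], ep.data[0, 0, :-4])
        assert out.channel_names[3].endswith("-d4")

    def test_delay_out_of_range(self, rng):
        ep = make_epochs(rng, n_samples=10)
        with pytest.raises(ValueError):
            delay_embed(ep, 10)

    def test_cssp_tau_from_grid_and_deterministic(self, rng):
        ep = toy_epochs(rng, n_trials=24, n_samples=60)
        bank1, tau1 = fit_cssp(ep, m=1, delay_grid=(1, 3), seed=5)
        bank2, tau2 = fit_cssp(ep, m=1, delay_grid=(1, 3), seed=5)
        assert tau1 in (1, 3)
        assert tau1 == tau2
        np.testing.assert_array_equal(bank1.W, bank2.W)

    def test_cssp_tie_breaks_to_smallest(self, rng):
        """With a single delay the choice is forced; with duplicate entries
        the smallest is returned."""
        ep = toy_epochs(rng, n_trials=24, n_samples=60)
        _, tau = fit_cssp(ep, m=1, delay_grid=(2, 2), seed=0)
        assert tau == 2

    def test_cssp_model_end_to_end(self, rng):
        tr = toy_epochs(rng, n_trials=40, gain=4.0)
        te = toy_epochs(rng, n_trials=20, gain=4.0)
        model = CSSPModel(n_pairs=1, delay_grid=(1, 2)).fit(tr)
        assert np.mean(model.predict(te) == te.labels.y_dec) >= 0.9


def band_epochs(rng, f_signal=10.0, n_trials=40, n_channels=4, fs=100.0,
                n_samples=200, gain=3.0):
    """Class 1 carries a strong sinusoid at ``f_signal`` on channel 0."""
    y = np.r_[np.ones(n_trials // 2, int), 2 * np.ones(n_trials // 2, int)]
    data = rng.standard_normal((n_trials, n_channels, n_samples))
    t = np.arange(n_samples) / fs
    phases = rng.uniform(0, 2 * np.pi, n_trials)
    tone = np.sin(2 * np.pi * f_signal * t[None, :] + phases[:, None])
    data[y == 1, 0] += gain * tone[y == 1]
    return EpochSet(data, t * 1000.0, LabelBlock.from_y_dec(y, ["a", "b"]), fs)


class TestMutualInformation:
    def test_perfectly_informative_feature(self):
        y = np.r_[np.zeros(50), np.ones(50)]
        f = y * 10.0 + np.linspace(0, 1, 100)
        assert mutual_information_binned(f, y, bins=4) == pytest.approx(1.0, abs=0.05)

    def test_independent_feature_near_zero(self, rng):
        y = rng.integers(0, 2, 2000)
        f = rng.standard_normal(2000)
        assert mutual_information_binned(f, y, bins=4) < 0.01

    def test_nonnegative(self, rng):
        for _ in range(20):
            f = rng.standard_normal(60)
            y = rng.integers(0, 2, 60)
            assert mutual_information_binned(f, y) >= 0.0


class TestFBCSP:
    def test_recovers_discriminative_band(self, rng):
        ep = band_epochs(rng, f_signal=10.0, gain=4.0)
        model = FBCSPModel(n_pairs=1, k=2).fit(ep)
        # the single most informative feature must come from the band
        # containing the 10 Hz class difference
        top = int(np.argmax(model.feature_mi))
        lo, hi = model.band_of_feature(top)
        assert lo <= 10.0 <= hi, (lo, hi)
        assert top in model.selected_features

    def test_band_of_feature_layout(self):
        model = FBCSPModel(n_pairs=2)
        assert model.band_of_feature(0) == (4.0, 8.0)
        assert model.band_of_feature(3) == (4.0, 8.0)
        assert model.band_of_feature(4) == (8.0, 12.0)

    def test_k_bounds_checked(self, rng):
        ep = band_epochs(rng)
        with pytest.raises(ValueError, match="k exceeds"):
            FBCSPModel(bands=((4.0, 8.0), (8.0, 12.0)), n_pairs=1, k=10).fit(ep)

    def test_end_to_end_accuracy(self, rng):
        tr = band_epochs(rng, gain=4.0)
        te = band_epochs(rng, gain=4.0)
        model = FBCSPModel(n_pairs=1, k=2).fit(tr)
        assert np.mean(model.predict(te) == te.labels.y_dec) >= 0.9


class TestBSSFO:
    def test_deterministic_given_seed(self, rng):
        ep = band_epochs(rng, n_trials=24, n_samples=120)
        m1 = fit_bssfo(ep, n_particles=6, n_iter=2, seed=3, m=1)
        m2 = fit_bssfo(ep, n_particles=6, n_iter=2, seed=3, m=1)
        assert m1.band == m2.band

    def test_band_covers_signal_frequency(self, rng):
        ep = band_epochs(rng, f_signal=10.0, gain=4.0, n_trials=40, n_samples=160)
        model = fit_bssfo(ep, n_particles=10, n_iter=4, seed=0, m=1)
        lo, hi = model.band
        assert lo <= 10.0 <= hi
        te = band_epochs(rng, f_signal=10.0, gain=4.0)
        assert np.mean(model.predict(te) == te.labels.y_dec) >= 0.9


class TestCrossValidation:
    def test_matches_naive_loop_oracle(self, rng):
        from sklearn.model_selection import StratifiedKFold
        ep = toy_epochs(rng, n_trials=30)
        cfg = MIMethodConfig(method="csp", n_pairs=1)
        mean, sd, accs = crossvalidate_mi(ep, cfg, folds=3, repeats=2, seed=9)
        # replicate the exact seeding scheme
        y = ep.labels.y_dec
        expected = []
        for rep_seed in np.random.SeedSequence(9).generate_state(2):
            skf = StratifiedKFold(n_splits=3, shuffle=True,
                                  random_state=int(rep_seed % (2 ** 31)))
            for tr, te in skf.split(np.zeros(len(y)), y):
                model = make_model(cfg).fit(ep.subset(tr))
                expected.append(np.mean(model.predict(ep.subset(te)) == y[te]))
        np.testing.assert_allclose(accs, expected, atol=1e-12)
        assert mean == pytest.approx(np.mean(expected))
        assert sd == pytest.approx(np.std(expected, ddof=1))

    def test_fold_count(self, rng):
        ep = toy_epochs(rng, n_trials=30)
        _, _, accs = crossvalidate_mi(ep, MIMethodConfig(n_pairs=1),
                                      folds=5, repeats=3, seed=0)
        assert accs.size == 15


class TestOnlineDecoding:
    def test_window_count_and_coords(self, rng):
        tr = toy_epochs(rng, n_trials=40, gain=4.0)
        model = CSPModel(n_pairs=1).fit(tr)
        stream = ContinuousEEG(signal=rng.standard_normal((1000, 4)), fs=100.0)
        out = online_decode_mi(stream, model, band_hz=(8.0, 30.0),
                               window_s=1.5, step_s=0.5)
        # (1000 - 150) // 50 + 1 = 18 windows
        assert out["values"].size == 18
        assert out["times_s"][0] == pytest.approx(1.5)
        assert out["times_s"][-1] == pytest.approx(10.0)
        assert np.all(np.abs(out["coords"]) <= 1.0)

    def test_stream_shorter_than_window_rejected(self, rng):
        tr = toy_epochs(rng)
        model = CSPModel(n_pairs=1).fit(tr)
        stream = ContinuousEEG(signal=rng.standard_normal((100, 4)), fs=100.0)
        with pytest.raises(ValueError, match="shorter"):
            online_decode_mi(stream, model, window_s=1.5)


def test_make_model_dispatch():
    assert isinstance(make_model(MIMethodConfig(method="csp")), CSPModel)
    assert isinstance(make_model(MIMethodConfig(method="cssp")), CSSPModel)
    assert isinstance(make_model(MIMethodConfig(method="fbcsp")), FBCSPModel)
    with pytest.raises(ValueError, match="unknown"):
        make_model(MIMethodConfig(method="nope"))
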