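import numpy as np
import pytest

from scatac_counts import vae
from scatac_counts.synthetic import generate

from conftest import make_matrix


def tiny_model(likelihood="poisson", n_peaks=7, seed=3, dropout=0.0):
    cfg = vae.VAEConfig(n_latent=2, n_hidden=5, dropout_rate=dropout,
                        likelihood=likelihood, seed=seed)
    return vae.VAEModel(n_peaks, ["a", "b"], cfg)


def poisson_batch(rng, n=3, p=7):
    X = rng.poisson(2.0, size=(n, p)).astype(float)
    X[X.sum(1) == 0, 0] = 1
    return X, np.log(X.sum(1))


class TestGradients:
    """The hand-written backward pass must match finite differences."""

    @pytest.mark.parametrize("likelihood", ["poisson", "bernoulli"])
    def test_gradient_matches_finite_differences(self, likelihood, rng):
        model = tiny_model(likelihood)
        if likelihood == "poisson":
            X, offsets = poisson_batch(rng)
        else:
            X = (rng.random((3, 7)) < 0.4).astype(float)
            X[X.sum(1) == 0, 0] = 1
            X[X.sum(1) == 7, 0] = 0
            frac = X.mean(1)
            offsets = np.log(frac / (1 - frac))
        S = model.one_hot(np.array([0, 1, 0]))
        _, grads, _ = vae._loss_forward(model, X, S, offsets, sample=False,
                                        rng=None, train=False, want_grad=True)
        for name, g in grads.items():
            p = model.params[name]
            flat = np.argsort(rng.random(p.size))[:8]
            for k in flat:
                idx = np.unravel_index(k, p.shape)
                h = 1e-6 * max(1.0, abs(p[idx]))
                orig = p[idx]
                p[idx] = orig + h
                lp, _, _ = vae._loss_forward(model, X, S, offsets, sample=False,
                                             rng=None, train=False, want_grad=False)
                p[idx] = orig - h
                lm, _, _ = vae._loss_forward(model, X, S, offsets, sample=False,
                                             rng=None, train=False, want_grad=False)
                p[idx] = orig
                fd = (lp - lm) / (2 * h)
                assert abs(fd - g[idx]) <= 1e-5 * max(1.0, abs(fd)), name


class TestEncode:
    def test_zero_row_is_finite_with_positive_sigma(self):
        model = tiny_model()
        mu, sigma = vae.encode(np.zeros(7), model)
        assert np.all(np.isfinite(mu)) and np.all(sigma > 0)

    def test_deterministic(self, rng):
        model = tiny_model()
        x = rng.poisson(1.0, size=7).astype(float)
        a = vae.encode(x, model)
        b = vae.encode(x, model)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_sigma_in_sane_range_at_init(self, rng):
        model = tiny_model()
        _, sigma = vae.encode(rng.poisson(2.0, size=7).astype(float), model)
        assert np.all(sigma > 0) and np.all(sigma < 100)

    def test_nonfinite_input_rejected(self):
        model = tiny_model()
        with pytest.raises(ValueError, match="finite"):
            vae.encode(np.array([np.nan] + [0.0] * 6), model)


class TestDecode:
    def test_poisson_rates_sum_to_depth(self, rng):
        """Softmax construction conserves the observed total count."""
        model = tiny_model()
        lam = vae.decode_poisson(rng.standard_normal(2), 0, model,
                                 l_c=np.log(100.0))
        assert lam.min() >= 0
        assert abs(lam.sum() - 100.0) / 100.0 < 1e-4

    def test_poisson_uniform_when_logits_constant(self):
        model = tiny_model()
        for k in model.params:
            model.params[k] = np.zeros_like(model.params[k])
        lam = vae.decode_poisson(np.zeros(2), 0, model, l_c=np.log(70.0))
        assert np.allclose(lam, 70.0 / 7, rtol=1e-9)

    def test_binary_offset_identity(self):
        """With rho = r = 0, theta equals the cell's mean accessibility."""
        model = tiny_model(likelihood="bernoulli")
        for k in model.params:
            model.params[k] = np.zeros_like(model.params[k])
        mean_acc = 0.1
        ltilde = np.log(mean_acc / (1 - mean_acc))
        theta = vae.decode_binary(np.zeros(2), 0, model, ltilde)
        assert np.allclose(theta, mean_acc, atol=1e-6)

    def test_binary_theta_strictly_inside_unit_interval(self, rng):
        model = tiny_model(likelihood="bernoulli")
        theta = vae.decode_binary(rng.standard_normal(2), 1, model, -2.0)
        assert np.all(theta > 0) and np.all(theta < 1)

    def test_unknown_batch_code_rejected(self, rng):
        model = tiny_model()
        with pytest.raises(KeyError):
            vae.decode_poisson(rng.standard_normal(2), 5, model, 1.0)


class TestElboLoss:
    def test_kl_zero_for_standard_normal_posterior(self):
        mu = np.zeros((2, 3))
        logsig = np.zeros((2, 3))
        assert np.allclose(vae._kl_gaussian(mu, logsig), 0.0)

    def test_poisson_logpmf_at_zero_count(self):
        u = np.log(np.array([[0.2, 0.8]]))  # softmax gives w = (0.2, 0.8)
        X = np.zeros((1, 2))
        l_c = np.array([np.log(5.0)])
        nll, _ = vae._poisson_nll_and_grad(u, X, l_c)
        # NLL of all-zero row is sum(lambda) = exp(l_c)
        assert np.allclose(nll, 5.0)

    def test_minibatch_equals_mean_of_singletons(self, rng):
        model = tiny_model()
        X, offsets = poisson_batch(rng, n=5)
        codes = np.array([0, 1, 0, 1, 0])
        batched = vae.elbo_loss(model, X, codes, offsets)
        singles = [vae.elbo_loss(model, X[i:i + 1], codes[i:i + 1],
                                 offsets[i:i + 1]) for i in range(5)]
        assert batched == pytest.approx(np.mean(singles), rel=1e-12)


@pytest.fixture(scope="module")
def trained(request):
    cm, _ = generate(n_cells=500, n_peaks=300, n_types=3, seed=11)
    cfg = vae.VAEConfig(n_latent=5, max_epochs=50, patience=50, seed=0)
    model, log = vae.train(cm, cfg)
    return cm, model, log


@pytest.fixture(scope="module")
def trained_small():
    cm, _ = generate(n_cells=300, n_peaks=120, n_types=2, seed=21)
    cfg = vae.VAEConfig(n_latent=4, max_epochs=15, seed=1)
    model, log = vae.train(cm, cfg)
    return cm, model, log


class TestTraining:
    def test_validation_loss_improves(self, trained):
        _, _, log = trained
        best = min(log.val_recon_loss)
        assert best < log.val_recon_loss[0]

    def test_split_proportions(self, trained):
        cm, _, log = trained
        n = len(log.train_idx) + len(log.val_idx) + len(log.test_idx)
        assert n == cm.n_cells - log.n_dropped_cells
        assert len(log.train_idx) == round(0.8 * n)
        assert len(log.val_idx) == round(0.1 * n)

    def test_same_seed_reproduces_losses(self):
        cm, _ = generate(n_cells=120, n_peaks=60, seed=3)
        cfg = vae.VAEConfig(n_latent=3, max_epochs=5, seed=9)
        _, log1 = vae.train(cm, cfg)
        _, log2 = vae.train(cm, cfg)
        assert log1.train_loss == log2.train_loss
        assert log1.val_recon_loss == log2.val_recon_loss

    def test_reads_matrix_rejected_with_guidance(self, rng):
        cm = make_matrix(rng.poisson(1.0, size=(50, 10)), kind="reads")
        with pytest.raises(ValueError, match="fragment counts, but not read"):
            vae.train(cm, vae.VAEConfig(max_epochs=1))

    def test_zero_depth_cells_dropped(self, rng):
        dense = rng.poisson(2.0, size=(60, 10))
        dense[5] = 0
        cm = make_matrix(dense)
        _, log = vae.train(cm, vae.VAEConfig(n_latent=2, max_epochs=2, seed=0))
        assert log.n_dropped_cells == (dense.sum(1) == 0).sum()


class TestModelDerivedQuantities:
    def test_total_count_conservation(self, trained_small):
        trained = trained_small  # noqa: local alias
        """sum_p lambda_cp = observed depth for every cell (softmax identity)."""
        cm, model, _ = trained
        lam = vae.predict_rates(model, cm)
        totals = cm.row_totals().astype(float)
        rel = np.abs(lam.sum(axis=1) - totals) / totals
        assert rel.max() < 1e-4

    def test_latent_shape_and_duplicate_rows(self, trained_small):
        cm, model, _ = trained_small
        emb = vae.get_latent(model, cm)
        assert emb.shape == (cm.n_cells, 4)
        # duplicate cell -> identical embedding row
        import scipy.sparse as sp
        from scatac_counts.core import CellTable, CountMatrix
        dup = sp.vstack([cm.values[0], cm.values[0]]).tocsr()
        cells = CellTable(np.array(["x", "y"], dtype=object),
                          np.array([cm.cells.batch[0]] * 2, dtype=object))
        dup_cm = CountMatrix(dup, cm.kind, cells, cm.peaks).with_totals()
        demb = vae.get_latent(model, dup_cm)
        assert np.array_equal(demb[0], demb[1])

    def test_latent_permutation_equivariance(self, trained_small):
        cm, model, _ = trained_small
        emb = vae.get_latent(model, cm)
        perm = np.random.default_rng(4).permutation(cm.n_cells)
        emb_perm = vae.get_latent(model, cm.subset_cells(perm))
        assert np.allclose(emb[perm], emb_perm)

    def test_normalized_accessibility_sums_to_median_depth(self, trained_small):
        cm, model, _ = trained_small
        norm = vae.normalized_accessibility(model, cm)
        med = np.median(cm.row_totals())
        assert np.allclose(norm.sum(axis=1), med, rtol=1e-6)
        assert norm.min() >= 0

    def test_normalized_accessibility_ignores_depth(self, trained_small):
        """Two cells with identical counts but the model seeing different
        depths produce identical normalized rows (offset replaced by a
        constant)."""
        cm, model, _ = trained_small
        norm = vae.normalized_accessibility(model, cm)
        emb = vae.get_latent(model, cm)
        # same embedding row implies same normalized row
        i, j = 0, 1
        if np.allclose(emb[i], emb[j]):
            assert np.allclose(norm[i], norm[j])

    def test_peak_subset_restriction(self, trained_small):
        cm, model, _ = trained_small
        sub = vae.normalized_accessibility(model, cm, peak_subset=[3, 5])
        full = vae.normalized_accessibility(model, cm)
        assert np.allclose(sub, full[:, [3, 5]])


class TestTransforms:
    def test_poisson_rate_to_bernoulli_closed_forms(self):
        assert vae.poisson_rate_to_bernoulli(0.0) == 0.0
        assert vae.poisson_rate_to_bernoulli(np.log(2.0)) == pytest.approx(0.5)

    def test_monotone_and_bounded(self):
        # below ~36 the transform is strictly increasing in float64;
        # far beyond that 1 - exp(-lam) rounds to exactly 1
        lam = np.linspace(0, 30, 200)
        theta = vae.poisson_rate_to_bernoulli(lam)
        assert np.all(np.diff(theta) > 0)
        assert theta.min() == 0 and theta.max() < 1

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            vae.poisson_rate_to_bernoulli(-0.1)


class TestSweep:
    def test_single_grid_value(self):
        cm, _ = generate(n_cells=150, n_peaks=60, seed=5)
        cfg = vae.VAEConfig(n_latent=3, max_epochs=3, seed=0)
        best, scores = vae.sweep_latent_dims(cm, cfg, grid=[4])
        assert best == 4 and set(scores) == {4}

    def test_tie_goes_to_smallest(self, monkeypatch):
        cm, _ = generate(n_cells=150, n_peaks=60, seed=5)
        cfg = vae.VAEConfig(max_epochs=1, seed=0)
        monkeypatch.setattr(
            "scatac_counts.evaluation.average_precision",
            lambda *_: 0.5)
        best, _ = vae.sweep_latent_dims(cm, cfg, grid=[6, 4, 8])
        assert best == 4


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, rng):
        model = tiny_model()
        x = rng.poisson(1.0, size=7).astype(float)
        before = vae.encode(x, model)
        path = tmp_path / "model.npz"
        vae.save_model(model, str(path))
        loaded = vae.load_model(str(path))
        after = vae.encode(x, loaded)
        assert np.array_equal(before[0], after[0])
        assert loaded.config.likelihood == model.config.likelihood


class TestDepthRobustness:
    """Cells sharing an accessibility profile but differing 5x in depth must
    embed closer to each other than to cells of other types, for both
    likelihoods: the precomputed offset absorbs depth."""

    @pytest.mark.parametrize("likelihood", ["poisson", "bernoulli"])
    def test_same_profile_different_depth_cells_cluster(self, likelihood):
        r = np.random.default_rng(13)
        n_types, n_cells, n_peaks = 3, 300, 200
        profiles = r.dirichlet(np.full(n_peaks, 0.3), size=n_types)
        types = np.arange(n_cells) % n_types
        depth = np.where(np.arange(n_cells) % 2 == 0, 400.0, 2000.0)
        x = r.poisson(depth[:, None] * profiles[types])
        cm = make_matrix(x)
        cfg = vae.VAEConfig(n_latent=8, max_epochs=60, patience=60, seed=0,
                            likelihood=likelihood)
        model, _ = vae.train(cm if likelihood == "poisson" else cm.binarize(),
                             cfg)
        emb = vae.get_latent(model, cm if likelihood == "poisson"
                             else cm.binarize())
        from scipy.spatial.distance import cdist
        d = cdist(emb, emb)
        margins = []
        for i in range(n_cells):
            same = (types == types[i]) & (depth != depth[i])
            other = types != types[i]
            margins.append(np.median(d[i, other]) - np.median(d[i, same]))
        assert np.median(margins) > 0
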