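import numpy as np
import pytest

from ramantrap import chemometrics as cm
from ramantrap import instrument as vi
from ramantrap.spectra import Band, PreprocessConfig, preprocess


# ---------------------------------------------------------------------------
# GMM


class TestGmm:
    def test_separated_point_masses(self):
        x = np.array([0.0] * 50 + [10.0] * 50)
        fit = cm.gmm2_em(x)
        np.testing.assert_allclose(fit.weights, [0.5, 0.5], atol=1e-6)
        np.testing.assert_allclose(fit.means, [0.0, 10.0], atol=1e-6)
        assert fit.variance_floored  # zero within-component spread hits the floor

    def test_mixture_fraction_recovered(self):
        rng = np.random.default_rng(17)
        n = 828
        labels = rng.random(n) < 0.56
        x = np.where(labels, rng.normal(60.0, 5.0, n), rng.normal(30.0, 5.0, n))
        fit = cm.gmm2_em(x)
        frac_low = np.mean(fit.labels == 0)
        se = np.sqrt(0.44 * 0.56 / n)
        assert abs(frac_low - 0.44) <= 3 * se

    def test_single_em_step_increases_likelihood(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0, 1, 50), rng.normal(6, 1, 50)])
        fit = cm.gmm2_em(x, tol=0.0, max_iter=1)
        ll_after = cm.gmm_log_likelihood(x, fit.weights, fit.means, fit.variances)
        assert ll_after >= fit.log_likelihood[0]

    def test_likelihood_trace_non_decreasing(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            x = np.concatenate(
                [rng.normal(0, 1, 60), rng.normal(rng.uniform(1.5, 8.0), 1.5, 90)]
            )
            fit = cm.gmm2_em(x)
            diffs = np.diff(fit.log_likelihood)
            assert np.all(diffs >= -1e-7 * np.abs(fit.log_likelihood[:-1]))

    def test_component_one_is_lower_mean(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(50, 2, 40), rng.normal(10, 2, 40)])
        fit = cm.gmm2_em(x)
        assert fit.means[0] < fit.means[1]

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cm.gmm2_em(np.full(10, 3.0))
        with pytest.raises(ValueError, match=">= 4"):
            cm.gmm2_em([1.0, 2.0])

    def test_weight_recovery_across_seeds(self):
        # 4-sigma separation: estimated weight within 3 multinomial s.e.
        failures = 0
        n = 400
        for seed in range(100):
            rng = np.random.default_rng(seed)
            w = 0.35
            labels = rng.random(n) < (1 - w)
            x = np.where(labels, rng.normal(8.0, 1.0, n), rng.normal(4.0, 1.0, n))
            fit = cm.gmm2_em(x)
            se = np.sqrt(w * (1 - w) / n)
            if abs(fit.weights[0] - w) > 3 * se + 0.02:
                failures += 1
        assert failures <= 5


# ---------------------------------------------------------------------------
# PCA


class TestPca:
    def test_identical_rows_zero_scores(self):
        x = np.tile(np.linspace(0, 1, 30), (8, 1))
        model = cm.pca(x, 2)
        np.testing.assert_allclose(model.scores, 0.0, atol=1e-10)
        np.testing.assert_allclose(model.explained_variance, 0.0, atol=1e-10)

    def test_rank_one_two_class_structure(self):
        rng = np.random.default_rng(8)
        contrast = np.zeros(100)
        contrast[40:50] = 1.0
        labels = rng.random(60) < 0.5
        x = np.outer(np.where(labels, 2.0, -2.0), contrast)
        x += rng.normal(0, 0.01, x.shape)
        model = cm.pca(x, 2)
        assert model.explained_variance_ratio[0] > 0.99
        scores = model.scores[:, 0]
        assert (scores[labels] > 0).all() != (scores[~labels] > 0).all()  # bimodal split

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(40, 25))
        model = cm.pca(x, 5)
        gram = model.loadings @ model.loadings.T
        assert np.max(np.abs(gram - np.eye(5))) < 1e-8

    def test_sign_convention(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(30, 12))
        model = cm.pca(x, 3)
        for row in model.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_transform_matches_scores(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=(20, 10))
        model = cm.pca(x, 3)
        np.testing.assert_allclose(model.transform(x), model.scores, atol=1e-10)


# ---------------------------------------------------------------------------
# Ward clustering with brute-force oracle


def ward_oracle(points):
    """O(n^3) Ward agglomeration computed directly from cluster members.

    Merge cost is sqrt(2 * (ESS(A u B) - ESS(A) - ESS(B))), evaluated from
    raw coordinates at every step — independent of the Lance-Williams
    recurrence used by the implementation.
    """
    points = np.asarray(points, dtype=float)
    clusters = [[i] for i in range(len(points))]
    merges = []

    def ess(idx):
        sub = points[idx]
        return float(np.sum((sub - sub.mean(axis=0)) ** 2))

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                cost = np.sqrt(
                    2.0 * (ess(clusters[i] + clusters[j]) - ess(clusters[i]) - ess(clusters[j]))
                )
                if best is None or cost < best[0] - 1e-12:
                    best = (cost, i, j)
        cost, i, j = best
        merges.append((set(clusters[i]), set(clusters[j]), cost))
        clusters = (
            [c for k, c in enumerate(clusters) if k not in (i, j)]
            + [clusters[i] + clusters[j]]
        )
    return merges


def partition_at(merges, n, k):
    clusters = [{i} for i in range(n)]
    for a, b, _ in merges[: n - k]:
        merged = a | b
        clusters = [c for c in clusters if not (c <= merged)] + [merged]
    return {frozenset(c) for c in clusters}


class TestWard:
    def test_two_separated_groups_perfect_cut(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 1, (20, 3)), rng.normal(12, 1, (20, 3))])
        tree = cm.ward_cluster(x, 2)
        labels = tree.labels
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(30, 4))
        tree = cm.ward_cluster(x, 3)
        assert np.all(np.diff(tree.heights) >= -1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        x = rng.normal(size=(n, 3))
        oracle = ward_oracle(x)
        tree = cm.ward_cluster(x, 2)
        np.testing.assert_allclose(
            sorted(tree.heights), sorted(m[2] for m in oracle), rtol=1e-8
        )
        for k in (2, 3):
            want = partition_at(oracle, n, k)
            got_labels = cm.ward_cluster(x, k).labels
            got = {
                frozenset(np.flatnonzero(got_labels == lab)) for lab in set(got_labels)
            }
            assert got == want

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ValueError):
            cm.ward_cluster(np.zeros((3, 2)), 4)

    def test_unclassified_mask_flags_outliers(self):
        rng = np.random.default_rng(12)
        # a point midway between the groups gets absorbed into one cluster
        # but sits far from every centroid -> "not classified"
        x = np.concatenate(
            [rng.normal(0, 0.5, (40, 2)), rng.normal(10, 0.5, (40, 2)), [[5.0, 5.0]]]
        )
        tree = cm.ward_cluster(x, 2)
        mask = cm.unclassified_mask(x, tree)
        assert mask[-1]
        assert mask.mean() < 0.1


# ---------------------------------------------------------------------------
# PLS-DA


def two_class_matrix(rng, n_per=60, n_channels=80, separation=1.0, noise=0.05):
    contrast = np.zeros(n_channels)
    contrast[30:40] = 1.0
    base = np.abs(np.sin(np.linspace(0, 3, n_channels))) + 0.5
    a = base + 0.0 * contrast + rng.normal(0, noise, (n_per, n_channels))
    b = base + separation * contrast + rng.normal(0, noise, (n_per, n_channels))
    x = np.vstack([val for pair in zip(a, b) for val in pair])  # interleaved order
    labels = np.array([lab for _ in range(n_per) for lab in ("A", "B")])
    return x, labels


class TestPlsda:
    def test_separable_classes_full_cv_sensitivity(self, rng):
        x, labels = two_class_matrix(rng)
        model = cm.plsda_train(x, labels, n_lv=2)
        np.testing.assert_allclose(model.cv_sensitivity, [1.0, 1.0])
        np.testing.assert_allclose(model.cv_specificity, [1.0, 1.0])

    def test_training_predictions_perfect_on_separable(self, rng):
        x, labels = two_class_matrix(rng)
        model = cm.plsda_train(x, labels, n_lv=2)
        predictions = cm.plsda_predict(model, x)
        assert (predictions == labels).all()

    def test_coefficients_match_least_squares_on_latent_scores(self, rng):
        # oracle: regress the centred response on the latent scores directly
        x, labels = two_class_matrix(rng)
        y = (labels == "B").astype(float)
        xc = x - x.mean(axis=0)
        yc = y - y.mean()
        model = cm.plsda_train(x, labels, n_lv=3)
        w, p = model.weights, model.x_loadings
        rotation = w.T @ np.linalg.inv(p @ w.T)  # X scores T = Xc @ rotation
        scores = xc @ rotation
        beta, *_ = np.linalg.lstsq(scores, yc, rcond=None)
        oracle_pred = scores @ beta
        model_pred = xc @ model.coefficients
        np.testing.assert_allclose(model_pred, oracle_pred, atol=1e-8)

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(77)
        x, labels = two_class_matrix(rng, n_per=50)
        permuted = rng.permutation(labels)
        model = cm.plsda_train(x, permuted, n_lv=2)
        balanced = 0.5 * (model.cv_sensitivity[0] + model.cv_sensitivity[1])
        assert balanced < 0.70

    def test_permutation_guard_across_seeds(self):
        exceeded = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            x, labels = two_class_matrix(rng, n_per=30, n_channels=40)
            model = cm.plsda_train(x, rng.permutation(labels), n_lv=2)
            balanced = 0.5 * (model.cv_sensitivity[0] + model.cv_sensitivity[1])
            if balanced > 0.65:
                exceeded += 1
        assert exceeded <= 2  # no-information guard: ~95% of seeds stay below

    def test_single_class_rejected(self, rng):
        x = rng.normal(size=(30, 10))
        with pytest.raises(ValueError):
            cm.plsda_train(x, np.array(["A"] * 30))

    def test_venetian_blinds_assignment(self):
        folds = cm.venetian_blinds_folds(25, 10)
        np.testing.assert_array_equal(folds[:12], [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 0, 1])


# ---------------------------------------------------------------------------
# Band-area ratios and time-trend check


class TestBandAreaRatio:
    def test_identical_groups_ratio_one(self, physics, library):
        cfg = vi.StreamConfig(seed=3, shot_noise=False)
        particle = vi.ParticleSpec(200.0, {"pdms": 1.0})
        group = [vi.render_spectrum(particle, 1.0, 10.0, cfg, physics, library)]
        bands = [Band("pdms490", 490.0, 15.0), Band("pdms709", 709.0, 15.0)]
        assert cm.band_area_ratio(group, group, bands) == pytest.approx(1.0)

    def test_theoretical_ratio_from_printed_weight_percentages(self):
        # integer weight percentages 83 and 70 -> quotient 0.843
        aba = round(vi.aba_pdms_fraction() * 100)
        aba_heparin = round(vi.aba_heparin_pdms_fraction() * 100)
        assert round(aba_heparin / aba, 3) == pytest.approx(0.843)

    def test_simulated_polymersome_ratio_near_theory(self, physics, library):
        cfg = vi.StreamConfig(
            seed=19, shot_noise=False, baseline_amplitude=0.0,
            background_amplitude=0.0, perchlorate_amplitude=0.0,
        )
        prep_cfg = PreprocessConfig(normalize=True)

        def group(composition):
            particle = vi.ParticleSpec(200.0, composition)
            raw = vi.render_spectrum(particle, 1.0, 10.0, cfg, physics, library)
            return [preprocess(raw, prep_cfg).spectrum]

        fracs = vi.component_weight_fractions(
            {
                "aba": (75.0, vi.ABA_BLOCK_MASSES_KDA),
                "heparin_copolymer": (25.0, vi.PDMS_HEPARIN_BLOCK_MASSES_KDA),
            }
        )
        aba = {"pdms": vi.aba_pdms_fraction(), "pmoxa": 1.0 - vi.aba_pdms_fraction()}
        aba_heparin = {
            "pdms": fracs["pdms"],
            "pmoxa": fracs["pmoxa_a"] + fracs["pmoxa_b"],
            "heparin": fracs["heparin"],
        }
        bands = [Band("pdms490", 490.0, 15.0), Band("pdms709", 709.0, 15.0)]
        ratio = cm.band_area_ratio(group(aba), group(aba_heparin), bands)
        assert ratio == pytest.approx(0.843, rel=0.05)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            cm.band_area_ratio([], [], [Band("x", 490.0, 15.0)])


class TestScoreTimeTrend:
    def test_null_no_trend(self, rng):
        scores = rng.normal(size=120)
        result = cm.score_time_trend(scores, np.arange(120))
        assert not result.trend_detected
        assert abs(result.correlation) < 0.25

    def test_linear_trend_detected(self):
        idx = np.arange(50)
        result = cm.score_time_trend(idx.astype(float), idx)
        assert result.trend_detected and result.correlation == pytest.approx(1.0)

    def test_balanced_mixture_stream_mostly_trendless(self):
        detections = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            labels = rng.random(100) < 0.5  # random class draw over time
            scores = np.where(labels, 1.0, -1.0) + rng.normal(0, 0.3, 100)
            if cm.score_time_trend(scores, np.arange(100), seed=seed).trend_detected:
                detections += 1
        assert detections <= 2  # no-trend in >= 90% of seeds
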