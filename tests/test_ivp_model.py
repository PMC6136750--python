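import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from bayesvar import (
    InsufficientTrainingDataError,
    InvalidInputError,
    IVPModel,
    SamplerError,
    TrainingSet,
    build_training_set,
    effective_counts,
    fit_pg_logistic,
    gene_distance,
    predict_distribution,
    select_predictors,
)

SCORE_COLS = ["x1", "x2"]


def _panel(rows):
    """rows: (variant_id, gene, consensus_class, x1, x2)."""
    df = pd.DataFrame(rows, columns=["variant_id", "gene", "consensus_class", "x1", "x2"])
    df["y"] = df["consensus_class"].map(
        {"benign": 0.0, "VLB": 0.0, "VLP": 1.0, "pathogenic": 1.0}
    )
    return df


def _training_set(X, y, names=None):
    names = names or [f"p{i}" for i in range(X.shape[1])]
    return TrainingSet(
        gene="G",
        variant_ids=[str(i) for i in range(len(y))],
        X=np.asarray(X, dtype=float),
        y=np.asarray(y, dtype=float),
        predictor_names=list(names),
        n_negative=float((np.asarray(y) == 0).sum()),
        n_positive=float((np.asarray(y) == 1).sum()),
    )


class TestEffectiveCounts:
    def test_weighting(self):
        n_neg, n_pos = effective_counts(
            ["benign", "benign", "VLB", "pathogenic", "VLP", "VLP", "VUS"]
        )
        assert n_neg == 2.5
        assert n_pos == 2.0


class TestGeneDistance:
    def test_identical_scores_zero(self):
        panel = _panel(
            [("a", "G", "benign", 0.2, 0.4), ("b", "H", "pathogenic", 0.2, 0.4)]
        )
        assert gene_distance(panel, "G", "H", SCORE_COLS) == 0.0

    def test_single_pair(self):
        panel = _panel(
            [("a", "G", "benign", 0.0, 0.0), ("b", "H", "pathogenic", 1.0, 0.0)]
        )
        assert gene_distance(panel, "G", "H", SCORE_COLS) == pytest.approx(1.0)

    def test_mean_over_pairs_brute_force(self, rng):
        rows = []
        for i in range(3):
            rows.append((f"g{i}", "G", "benign", *rng.random(2)))
        for j in range(4):
            rows.append((f"h{j}", "H", "VLP", *rng.random(2)))
        panel = _panel(rows)
        expected = np.mean(
            [
                np.linalg.norm(
                    panel.loc[i, SCORE_COLS].to_numpy(dtype=float)
                    - panel.loc[j, SCORE_COLS].to_numpy(dtype=float)
                )
                for i in range(3)
                for j in range(3, 7)
            ]
        )
        assert gene_distance(panel, "G", "H", SCORE_COLS) == pytest.approx(expected)
        assert gene_distance(panel, "H", "G", SCORE_COLS) == pytest.approx(expected)

    def test_empty_gene_raises(self):
        panel = _panel([("a", "G", "benign", 0.1, 0.1)])
        with pytest.raises(InvalidInputError):
            gene_distance(panel, "G", "H", SCORE_COLS)


class TestBuildTrainingSet:
    def test_no_expansion_when_minima_met(self, rng):
        rows = [(f"b{i}", "G", "benign", *rng.random(2)) for i in range(10)]
        rows += [(f"p{i}", "G", "pathogenic", *rng.random(2)) for i in range(10)]
        rows += [(f"d{i}", "D", "pathogenic", *rng.random(2)) for i in range(5)]
        ts = build_training_set(_panel(rows), "G", SCORE_COLS)
        assert ts.borrow_log == []
        assert ts.n == 20
        assert ts.n_negative == 10 and ts.n_positive == 10

    def test_borrow_weights_vlp(self, rng):
        # gene G: 6 benign, 2 pathogenic; donor D: 8 VLP -> needs 6 at 0.5 weight
        rows = [(f"b{i}", "G", "benign", *rng.random(2)) for i in range(6)]
        rows += [(f"p{i}", "G", "pathogenic", *rng.random(2)) for i in range(2)]
        rows += [(f"d{i}", "D", "VLP", *rng.random(2)) for i in range(8)]
        ts = build_training_set(_panel(rows), "G", SCORE_COLS)
        assert len(ts.borrow_log) == 6
        assert ts.n_positive == pytest.approx(5.0)
        assert all(g == "D" for _, g in ts.borrow_log)

    def test_borrow_weights_pathogenic(self, rng):
        rows = [(f"b{i}", "G", "benign", *rng.random(2)) for i in range(6)]
        rows += [(f"p{i}", "G", "pathogenic", *rng.random(2)) for i in range(2)]
        rows += [(f"d{i}", "D", "pathogenic", *rng.random(2)) for i in range(8)]
        ts = build_training_set(_panel(rows), "G", SCORE_COLS)
        assert len(ts.borrow_log) == 3
        assert ts.n_positive == pytest.approx(5.0)

    def test_closest_donor_used_first(self):
        rows = [(f"b{i}", "G", "benign", 0.5, 0.5) for i in range(6)]
        rows += [("p0", "G", "pathogenic", 0.5, 0.5)]
        # donor NEAR at distance ~0.1, donor FAR at ~0.4
        rows += [(f"n{i}", "NEAR", "pathogenic", 0.6, 0.5) for i in range(3)]
        rows += [(f"f{i}", "FAR", "pathogenic", 0.9, 0.5) for i in range(8)]
        ts = build_training_set(_panel(rows), "G", SCORE_COLS)
        donors = [g for _, g in ts.borrow_log]
        assert donors[:3] == ["NEAR", "NEAR", "NEAR"]
        assert set(donors[3:]) == {"FAR"}

    def test_descending_merge_order_within_donor(self):
        rows = [(f"b{i}", "G", "benign", 0.5, 0.5) for i in range(5)]
        rows += [(f"p{i}", "G", "pathogenic", 0.5, 0.5) for i in range(3)]
        rows += [
            ("d_far", "D", "pathogenic", 0.9, 0.5),
            ("d_mid", "D", "pathogenic", 0.7, 0.5),
            ("d_near", "D", "pathogenic", 0.55, 0.5),
        ]
        # needs 2 more positives: descending takes the farthest first
        ts = build_training_set(_panel(rows), "G", SCORE_COLS)
        assert [v for v, _ in ts.borrow_log] == ["d_far", "d_mid"]
        ts_asc = build_training_set(_panel(rows), "G", SCORE_COLS, descending=False)
        assert [v for v, _ in ts_asc.borrow_log] == ["d_near", "d_mid"]

    def test_only_deficient_side_borrowed(self, rng):
        rows = [(f"b{i}", "G", "benign", *rng.random(2)) for i in range(8)]
        rows += [(f"p{i}", "G", "pathogenic", *rng.random(2)) for i in range(2)]
        rows += [(f"dn{i}", "D", "benign", *rng.random(2)) for i in range(5)]
        rows += [(f"dp{i}", "D", "pathogenic", *rng.random(2)) for i in range(5)]
        ts = build_training_set(_panel(rows), "G", SCORE_COLS)
        borrowed_classes = {
            v: _panel(rows).set_index("variant_id").loc[v, "consensus_class"]
            for v, _ in ts.borrow_log
        }
        assert all(c == "pathogenic" for c in borrowed_classes.values())

    def test_own_variants_always_kept(self, rng):
        rows = [(f"b{i}", "G", "benign", *rng.random(2)) for i in range(6)]
        rows += [("p0", "G", "VLP", *rng.random(2))]
        rows += [(f"d{i}", "D", "pathogenic", *rng.random(2)) for i in range(6)]
        ts = build_training_set(_panel(rows), "G", SCORE_COLS)
        own = {f"b{i}" for i in range(6)} | {"p0"}
        assert own <= set(ts.variant_ids)

    def test_insufficient_data_raises(self, rng):
        rows = [(f"b{i}", "G", "benign", *rng.random(2)) for i in range(6)]
        rows += [("p0", "G", "pathogenic", *rng.random(2))]
        rows += [("d0", "D", "benign", *rng.random(2))]
        with pytest.raises(InsufficientTrainingDataError, match="G"):
            build_training_set(_panel(rows), "G", SCORE_COLS)

    def test_unknown_gene_raises(self):
        with pytest.raises(InvalidInputError):
            build_training_set(_panel([("a", "G", "benign", 0.1, 0.1)]), "ZZ", SCORE_COLS)


class TestSelectPredictors:
    def test_recovers_informative_predictor(self, rng):
        n, p = 200, 16
        X = rng.random((n, p))
        y = (rng.random(n) < expit(-4 + 8 * X[:, 5])).astype(float)
        ts = _training_set(X, y)
        selected = select_predictors(ts, seed=0)
        assert "p5" in selected
        assert 1 <= len(selected) <= 4

    def test_duplicated_predictor_kept_once(self, rng):
        n = 150
        x = rng.random(n)
        y = (rng.random(n) < expit(-3 + 6 * x)).astype(float)
        X = np.column_stack([x, x, rng.random(n)])
        ts = _training_set(X, y, names=["dup_a", "dup_b", "noise"])
        selected = select_predictors(ts, seed=0)
        assert len({s for s in selected if s.startswith("dup")}) <= 1

    def test_all_identical_response_raises(self, rng):
        ts = _training_set(rng.random((20, 3)), np.ones(20))
        with pytest.raises(InvalidInputError):
            select_predictors(ts)

    def test_pure_noise_falls_back_to_single_predictor(self, rng):
        X = rng.random((60, 4))
        y = rng.integers(0, 2, 60).astype(float)
        selected = select_predictors(_training_set(X, y), penalties=(8,), seed=0)
        assert len(selected) >= 1


class TestPGLogisticFit:
    def test_parameter_recovery(self, rng):
        n = 2000
        x = rng.uniform(0, 1, n)
        y = (rng.random(n) < expit(-1 + 3 * x)).astype(float)
        ts = _training_set(x[:, None], y, names=["s"])
        model = fit_pg_logistic(ts, ["s"], n_samples=600, burn_in=300, seed=3)
        mean = model.coef_samples.mean(axis=0)
        assert mean[0] == pytest.approx(-1.0, abs=0.3)
        assert mean[1] == pytest.approx(3.0, abs=0.6)

    def test_posterior_close_to_mle_oracle(self, rng):
        import statsmodels.api as sm

        hits = 0
        for rep in range(3):
            n = 400
            x = rng.uniform(0, 1, n)
            y = (rng.random(n) < expit(-0.5 + 2 * x)).astype(float)
            ts = _training_set(x[:, None], y, names=["s"])
            model = fit_pg_logistic(ts, ["s"], n_samples=400, burn_in=200, seed=rep)
            mle = sm.Logit(y, sm.add_constant(x)).fit(disp=0).params
            mean = model.coef_samples.mean(axis=0)
            sd = model.coef_samples.std(axis=0)
            if np.all(np.abs(mean - mle) <= 3 * sd):
                hits += 1
        assert hits >= 2

    def test_interval_coverage(self, rng):
        """95% posterior intervals cover the truth in >= 85% of replicates."""
        true = np.array([-0.5, 2.0])
        for n in (200, 2000):
            covered = np.zeros(2)
            reps = 50
            for rep in range(reps):
                x = rng.uniform(0, 1, n)
                y = (rng.random(n) < expit(true[0] + true[1] * x)).astype(float)
                ts = _training_set(x[:, None], y, names=["s"])
                model = fit_pg_logistic(ts, ["s"], n_samples=300, burn_in=150, seed=rep)
                lo, hi = np.percentile(model.coef_samples, [2.5, 97.5], axis=0)
                covered += (lo <= true) & (true <= hi)
            assert (covered / reps >= 0.85).all(), (n, covered / reps)

    def test_intercept_only_balanced(self, rng):
        y = np.array([0.0, 1.0] * 50)
        ts = _training_set(rng.random((100, 1)), y, names=["s"])
        model = fit_pg_logistic(ts, [], n_samples=500, burn_in=200, seed=1)
        assert expit(model.coef_samples[:, 0]).mean() == pytest.approx(0.5, abs=0.05)

    def test_degenerate_response_raises(self, rng):
        ts = _training_set(rng.random((20, 1)), np.zeros(20), names=["s"])
        with pytest.raises(SamplerError):
            fit_pg_logistic(ts, ["s"], n_samples=10, burn_in=10, seed=0)

    def test_deterministic_given_seed(self, rng):
        x = rng.random(50)
        y = (rng.random(50) < expit(x)).astype(float)
        ts = _training_set(x[:, None], y, names=["s"])
        m1 = fit_pg_logistic(ts, ["s"], n_samples=50, burn_in=50, seed=9)
        m2 = fit_pg_logistic(ts, ["s"], n_samples=50, burn_in=50, seed=9)
        np.testing.assert_array_equal(m1.coef_samples, m2.coef_samples)

    def test_save_load_roundtrip(self, tmp_path, rng):
        x = rng.random(40)
        y = np.array([0.0, 1.0] * 20)
        ts = _training_set(x[:, None], y, names=["s"])
        model = fit_pg_logistic(ts, ["s"], n_samples=50, burn_in=20, seed=0)
        path = tmp_path / "model.json"
        model.save(path)
        back = IVPModel.load(path)
        assert back.gene == model.gene
        assert back.predictors == model.predictors
        np.testing.assert_allclose(back.coef_samples, model.coef_samples)


class TestPredictDistribution:
    def _model(self, samples, names=("s",)):
        return IVPModel(gene="G", predictors=list(names), coef_samples=np.asarray(samples, float))

    def test_zero_coefficients_give_half(self):
        model = self._model(np.zeros((200, 2)))
        dist = predict_distribution(model, {"s": 0.7})
        np.testing.assert_allclose(dist.samples, 0.5)

    def test_single_sample_arithmetic(self):
        model = self._model([[0.0, 2.0]])
        dist = predict_distribution(model, {"s": 1.0})
        assert dist.samples[0] == pytest.approx(0.8808, abs=5e-5)

    def test_samples_in_open_unit_interval(self, rng):
        model = self._model(rng.standard_normal((500, 2)) * 50)
        dist = predict_distribution(model, {"s": 0.9})
        assert ((dist.samples > 0) & (dist.samples < 1)).all()

    def test_monotone_in_positive_coefficient(self, rng):
        samples = np.column_stack([rng.standard_normal(300), rng.uniform(0.5, 2.0, 300)])
        model = self._model(samples)
        lo = predict_distribution(model, {"s": 0.2}).samples
        hi = predict_distribution(model, {"s": 0.8}).samples
        assert (hi > lo).all()

    def test_missing_predictor_raises(self):
        model = self._model(np.zeros((10, 2)))
        with pytest.raises(InvalidInputError):
            predict_distribution(model, {"other": 1.0})
        with pytest.raises(InvalidInputError):
            predict_distribution(model, {"s": float("nan")})
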