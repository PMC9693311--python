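import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from earmorph import (
    Gallery,
    ShapeParameters,
    cmc_curve,
    identify,
    param_distance,
    verification_metrics,
    verify,
)
from earmorph.errors import (
    IncompatibilityError,
    InvalidInputError,
    NumericalError,
    UndefinedDistanceError,
)
from earmorph.recognition import METRICS, gallery_covariance, gallery_scaling

HASH = "testmodel"


def make_gallery(alphas, labels=None):
    labels = labels or [f"g{i}" for i in range(len(alphas))]
    entries = {
        lab: ShapeParameters(a, HASH, label=lab) for lab, a in zip(labels, alphas)
    }
    return Gallery(entries=entries, model_hash=HASH)


class TestParamDistance:
    @pytest.mark.parametrize("metric", METRICS)
    def test_identity_distance_is_zero(self, metric, rng):
        a = rng.normal(size=8)
        kw = {}
        if metric == "SE":
            kw["scaling"] = np.full(8, 2.0)
        if metric == "MH":
            kw["covariance"] = np.eye(8)
        assert param_distance(a, a, metric, **kw) == pytest.approx(0.0, abs=1e-12)

    def test_forced_small_examples(self):
        a, b = np.zeros(3), np.array([1.0, 2.0, 2.0])
        assert param_distance(a, b, "E") == pytest.approx(3.0)
        assert param_distance(a, b, "CT") == pytest.approx(5.0)
        assert param_distance(a, b, "CH") == pytest.approx(2.0)
        assert param_distance(a, b, "MN", p=2) == pytest.approx(3.0)

    def test_metric_equivalences(self, rng):
        a, b = rng.normal(size=10), rng.normal(size=10)
        assert param_distance(a, b, "MH", covariance=np.eye(10)) == pytest.approx(
            param_distance(a, b, "E"), abs=1e-10
        )
        assert param_distance(a, b, "SE", scaling=np.ones(10)) == pytest.approx(
            param_distance(a, b, "E"), abs=1e-10
        )
        assert param_distance(a, b, "MN", p=1) == pytest.approx(
            param_distance(a, b, "CT"), abs=1e-10
        )
        assert param_distance(a, b, "MN", p=64) == pytest.approx(
            param_distance(a, b, "CH"), abs=1e-6
        )

    def test_spearman_monotone_invariance_and_zero(self, rng):
        a, b = rng.normal(size=12), rng.normal(size=12)
        before = param_distance(a, b, "SP")
        after = param_distance(np.exp(a), b**3 if False else np.tanh(b) * 5 + 7, "SP")
        # strictly increasing coordinate-wise transforms keep the ranks
        assert after == pytest.approx(before, abs=1e-12)
        inc = np.sort(rng.normal(size=9))
        inc2 = np.sort(rng.normal(size=9))
        assert param_distance(inc, inc2, "SP") == pytest.approx(0.0, abs=1e-12)

    def test_correlation_of_negated_vector_is_two(self, rng):
        a = rng.normal(size=15)
        assert param_distance(a, -a + 3.0, "CR") == pytest.approx(2.0, abs=1e-10)

    def test_undefined_cases(self, rng):
        a = rng.normal(size=5)
        with pytest.raises(UndefinedDistanceError):
            param_distance(np.zeros(5), a, "CS")
        with pytest.raises(UndefinedDistanceError):
            param_distance(np.full(5, 2.0), a, "CR")
        with pytest.raises(NumericalError):
            param_distance(a, a + 1, "MH", covariance=np.zeros((5, 5)))
        with pytest.raises(InvalidInputError):
            param_distance(a, a, "nope")
        with pytest.raises(InvalidInputError):
            param_distance(a, rng.normal(size=6), "E")

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        a=arrays(float, 7, elements=st.floats(-10, 10)),
        b=arrays(float, 7, elements=st.floats(-10, 10)),
    )
    def test_symmetry_property(self, a, b):
        for metric in ("E", "CT", "CH", "MN"):
            assert param_distance(a, b, metric) == pytest.approx(
                param_distance(b, a, metric), abs=1e-10
            )


class TestIdentifyVerify:
    def test_exact_match_ranks_first_with_zero_distance(self, rng):
        alphas = [rng.normal(size=6) for _ in range(5)]
        g = make_gallery(alphas)
        probe = ShapeParameters(alphas[2], HASH, label="probe")
        res = identify(g, probe, metric="E")
        assert res.best_label == "g2"
        assert res.best_distance == pytest.approx(0.0, abs=1e-12)
        assert res.accepted

    def test_ranking_matches_exhaustive_sort_oracle(self, rng):
        alphas = [rng.normal(size=6) for _ in range(5)]
        g = make_gallery(alphas)
        probe = ShapeParameters(rng.normal(size=6), HASH)
        res = identify(g, probe, metric="E")
        oracle = sorted(
            ((f"g{i}", float(np.linalg.norm(a - probe.alpha))) for i, a in enumerate(alphas)),
            key=lambda lp: (lp[1], lp[0]),
        )
        assert [l for l, _ in res.ranking] == [l for l, _ in oracle]
        np.testing.assert_allclose([d for _, d in res.ranking], [d for _, d in oracle])

    def test_empty_gallery_and_hash_mismatch(self, rng):
        g = Gallery(entries={}, model_hash=HASH)
        probe = ShapeParameters(rng.normal(size=4), HASH)
        with pytest.raises(InvalidInputError):
            identify(g, probe)
        g2 = make_gallery([rng.normal(size=4)])
        with pytest.raises(IncompatibilityError):
            identify(g2, ShapeParameters(rng.normal(size=4), "otherhash"))

    def test_verify_strict_threshold_boundary(self):
        a = ShapeParameters(np.array([0.0, 0.0]), HASH)
        b = ShapeParameters(np.array([0.62, 0.0]), HASH)
        accepted, dist = verify(a, b, threshold=0.62, metric="E")
        assert dist == pytest.approx(0.62)
        assert not accepted  # distance equal to the threshold is rejected
        accepted, dist = verify(a, a, threshold=0.62, metric="E")
        assert accepted and dist == 0.0

    def test_verify_constructed_impostor_rejected(self, rng):
        # two anti-correlated rank patterns: SP distance near 2
        a = ShapeParameters(np.arange(10.0), HASH)
        b = ShapeParameters(-np.arange(10.0), HASH)
        accepted, dist = verify(a, b, threshold=0.62, metric="SP")
        assert dist > 0.62 and not accepted


class TestCmcCurve:
    def test_perfect_probes_hit_rank_one(self, rng):
        alphas = [rng.normal(size=5) for _ in range(6)]
        g = make_gallery(alphas)
        probes = [ShapeParameters(a, HASH, label=f"g{i}") for i, a in enumerate(alphas)]
        cmc = cmc_curve(g, probes, metric="E")
        assert cmc[1] == 100.0

    def test_adversarial_probe_forces_rank_two(self, rng):
        alphas = [rng.normal(size=5) for _ in range(2)]
        g = make_gallery(alphas)
        probes = [ShapeParameters(alphas[1], HASH, label="g0")]
        cmc = cmc_curve(g, probes, metric="E")
        assert cmc[1] == 0.0 and cmc[2] == 100.0

    def test_matches_rank_counting_oracle(self, rng):
        d = 6
        alphas = [rng.normal(size=d) for _ in range(20)]
        g = make_gallery(alphas)
        probes = [
            ShapeParameters(alphas[i] + rng.normal(0, 0.5, d), HASH, label=f"g{i}")
            for i in range(20)
        ]
        cmc = cmc_curve(g, probes, metric="E", max_rank=20)
        # oracle: count how often the true label is within rank r
        ranks = []
        for p in probes:
            dists = sorted(
                ((np.linalg.norm(a - p.alpha), f"g{i}") for i, a in enumerate(alphas))
            )
            ranks.append([lab for _, lab in dists].index(p.label) + 1)
        for r in range(1, 21):
            assert cmc[r] == pytest.approx(100.0 * np.mean(np.array(ranks) <= r))
        # non-decreasing, terminal 100%
        vals = [cmc[r] for r in range(1, 21)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert vals[-1] == 100.0

    def test_unenrolled_probe_label_rejected(self, rng):
        g = make_gallery([rng.normal(size=4) for _ in range(3)])
        probe = ShapeParameters(rng.normal(size=4), HASH, label="stranger")
        with pytest.raises(InvalidInputError):
            cmc_curve(g, [probe])


class TestVerificationMetrics:
    def test_accuracy_formula_at_zero_rates(self):
        rep = verification_metrics([0.1, 0.2], [0.8, 0.9], thresholds=[0.5])
        assert rep.far_curve[0] == 0.0
        assert rep.frr_curve[0] == 0.0
        assert rep.verification_accuracy == pytest.approx(100.0)

    def test_counting_oracle_small_sets(self):
        rep = verification_metrics([0.1, 0.2], [0.8, 0.9], thresholds=[0.5, 0.85])
        assert rep.far_curve[1] == pytest.approx(50.0)  # 0.8 < 0.85
        assert rep.frr_curve[1] == pytest.approx(0.0)
        acc = 100.0 - (50.0 + 0.0) / 2.0
        assert rep.best_threshold == pytest.approx(0.5)
        assert max(100.0, acc) == rep.verification_accuracy

    def test_far_frr_arithmetic_example(self):
        # FAR = 3%, FRR = 3% -> accuracy 97%
        genuine = np.concatenate([np.full(97, 0.1), np.full(3, 0.9)])
        impostor = np.concatenate([np.full(97, 0.8), np.full(3, 0.05)])
        rep = verification_metrics(genuine, impostor, thresholds=[0.5])
        assert rep.far_curve[0] == pytest.approx(3.0)
        assert rep.frr_curve[0] == pytest.approx(3.0)
        acc = 100.0 - (3.0 + 3.0) / 2.0
        assert acc == pytest.approx(97.0)

    def test_far_nondecreasing_frr_nonincreasing_in_threshold(self, rng):
        rep = verification_metrics(
            rng.exponential(0.3, 50), 0.5 + rng.exponential(0.5, 80)
        )
        assert np.all(np.diff(rep.far_curve) >= 0)
        assert np.all(np.diff(rep.frr_curve) <= 0)

    def test_empty_sets_rejected(self):
        with pytest.raises(InvalidInputError):
            verification_metrics([], [0.5])


class TestGalleryAux:
    def test_covariance_shrinks_when_ill_conditioned(self, rng):
        # fewer samples than dimensions: raw covariance is singular
        alphas = [rng.normal(size=10) for _ in range(4)]
        g = make_gallery(alphas)
        C = gallery_covariance(g)
        assert np.linalg.cond(C) < 1e6

    def test_scaling_is_per_dimension_sd(self, rng):
        alphas = [rng.normal(size=3) * np.array([1.0, 5.0, 0.1]) for _ in range(40)]
        g = make_gallery(alphas)
        s = gallery_scaling(g)
        np.testing.assert_allclose(s, np.std([a for a in alphas], axis=0, ddof=1))
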