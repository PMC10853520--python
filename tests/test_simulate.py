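import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sketchdev import simulate
from sketchdev.corpus import rasterize
from sketchdev.tracing import AffineParams


class TestCategoryLibrary:
    def test_study_scale_counts(self):
        lib = simulate.generate_category_library(48, 22, seed=1)
        assert len(lib) == 48
        assert sum(t.animate for t in lib) == 22
        inanimate = [t for t in lib if not t.animate]
        assert len(inanimate) == 26
        assert sum(t.big for t in inanimate) == 13  # half flagged big
        assert all(t.big is None for t in lib if t.animate)

    def test_seed_determinism(self):
        a = simulate.generate_category_library(2, 1, seed=7)
        b = simulate.generate_category_library(2, 1, seed=7)
        assert [t.category for t in a] == [t.category for t in b]
        for ta, tb in zip(a, b):
            for pa, pb in zip(ta.parts, tb.parts):
                assert pa.label == pb.label
                np.testing.assert_array_equal(pa.polyline, pb.polyline)

    def test_all_inanimate_boundary(self):
        lib = simulate.generate_category_library(4, 0, seed=3)
        assert all(not t.animate for t in lib)

    def test_too_few_categories_rejected(self):
        with pytest.raises(ValueError):
            simulate.generate_category_library(1, 0, seed=0)


class TestGenerateDrawing:
    def test_full_inclusion_no_jitter_reproduces_templates(self, small_library):
        quiet = simulate.AgeModel(jitter_at_base=0.0, jitter_floor=0.0)
        t = small_library[0]
        g = simulate.generate_drawing(t, 6, quiet, seed=0, inclusion_prob=1.0)
        assert g.drawing.n_strokes == len(t.parts)
        assert g.part_labels == t.part_labels
        # each stroke is the template polyline under the documented placement
        # map (margin offset + salience stretch about the centroid)
        w, h = g.drawing.canvas_size
        margin = 0.1 * min(w, h)
        for stroke, part in zip(g.drawing.strokes, t.parts):
            xy = margin + part.polyline * np.array([w - 2 * margin, h - 2 * margin])
            c = xy.mean(axis=0)
            expect = np.clip(c + (xy - c) * min(part.salience, 1.8), [0, 0], [w, h])
            np.testing.assert_allclose(stroke.xy, expect, atol=1e-9)

    def test_zero_inclusion_gives_empty_drawing(self, small_library, age_model):
        g = simulate.generate_drawing(
            small_library[0], 4, age_model, seed=1, inclusion_prob=0.0
        )
        assert g.drawing.n_strokes == 0

    def test_inclusion_rate_matches_binomial_oracle(self, small_library, age_model):
        t = small_library[1]
        n, p = 400, 0.6
        rng = np.random.default_rng(11)
        included = [
            simulate.generate_drawing(
                t, 5, age_model, rng, inclusion_prob=p
            ).drawing.n_strokes
            for _ in range(n)
        ]
        total = n * len(t.parts)
        se = math.sqrt(p * (1 - p) / total)
        assert abs(np.mean(included) / len(t.parts) - p) < 3 * se

    def test_age_monotone_part_inclusion(self, small_library, age_model):
        means = []
        for age in (3, 6, 9):
            rng = np.random.default_rng(5)
            means.append(
                np.mean(
                    [
                        simulate.generate_drawing(
                            t, age, age_model, rng
                        ).drawing.n_strokes
                        for t in small_library
                        for _ in range(30)
                    ]
                )
            )
        assert means[0] < means[1] < means[2]


class TestTracingTrials:
    def test_identity_affine_zero_noise_reproduces_target(self):
        trial = simulate.generate_tracing_trial(
            "square", AffineParams.identity(), contour_noise=0.0, seed=0, size=96
        )
        traced = rasterize(
            trial.strokes, size=96, canvas_size=trial.canvas_size
        )
        np.testing.assert_array_equal(traced, trial.target)

    def test_translation_shifts_centroid(self):
        base = simulate.generate_tracing_trial(
            "star", AffineParams.identity(), 0.0, seed=0, size=128
        )
        moved = simulate.generate_tracing_trial(
            "star", AffineParams(tx=5, ty=3), 0.0, seed=0, size=128
        )
        c0 = base.strokes[0].xy.mean(axis=0)
        c1 = moved.strokes[0].xy.mean(axis=0)
        np.testing.assert_allclose(c1 - c0, [5.0, 3.0], atol=1e-9)

    def test_seed_determinism(self):
        a = simulate.generate_tracing_trial("star", AffineParams(tx=2), 1.5, seed=9)
        b = simulate.generate_tracing_trial("star", AffineParams(tx=2), 1.5, seed=9)
        np.testing.assert_array_equal(a.strokes[0].points, b.strokes[0].points)

    def test_degenerate_affine_rejected(self):
        with pytest.raises(ValueError):
            AffineParams(sx=0.0)


class TestToyEncoder:
    def test_noise_free_nearest_prototype_is_perfect(self, small_library, age_model):
        enc = simulate.ToyEncoder(small_library, dim=32, signal=1.0, seed=0)
        gens = simulate.generate_drawing_set(
            small_library, [5], 10, age_model, seed=2
        )
        x, y = enc.encode_drawings(gens)
        protos = np.stack([enc.prototypes[t.category] for t in small_library])
        sims = x.to_numpy() @ protos.T
        pred = [small_library[j].category for j in sims.argmax(axis=1)]
        assert (np.array(pred) == y.to_numpy()).all()

    def test_deterministic_per_input(self, small_library):
        enc = simulate.ToyEncoder(small_library, dim=32, signal=0.4, seed=3)
        a = enc.encode("animal00", ("head",), key="k1")
        b = enc.encode("animal00", ("head",), key="k1")
        c = enc.encode("animal00", ("head",), key="k2")
        np.testing.assert_array_equal(a, b)
        assert not np.allclose(a, c)

    def test_dim_must_cover_categories(self, small_library):
        with pytest.raises(ValueError):
            simulate.ToyEncoder(small_library, dim=4)


class TestAnnotations:
    def test_perfect_agreement_recovers_truth(self, small_library, age_model):
        g = simulate.generate_drawing(
            small_library[0], 7, age_model, seed=4, inclusion_prob=1.0
        )
        ann = simulate.generate_annotations(g, agreement_rate=1.0, seed=0)
        for k, lab in enumerate(g.part_labels):
            got = set(ann.loc[ann["stroke_index"] == k, "labels"])
            assert got == {lab}

    def test_zero_agreement_collision_probability(self, small_library, age_model):
        # with agreement 0, each of 3 raters picks uniformly among m
        # alternatives; P(some label collides) = 1 - (m-1)(m-2)/m^2
        g = simulate.generate_drawing(
            small_library[0], 7, age_model, seed=4, inclusion_prob=1.0
        )
        # truth labels are template labels, disjoint from this vocabulary, so
        # every rater picks among all 9 vocab labels plus "unintelligible"
        vocab = [f"v{i}" for i in range(9)]
        m = len(vocab) + 1
        n_rep = 300
        collide = 0
        total = 0
        for rep in range(n_rep):
            ann = simulate.generate_annotations(
                g, agreement_rate=0.0, seed=rep, vocabulary=vocab
            )
            for _, grp in ann.groupby("stroke_index"):
                labs = list(grp["labels"])
                collide += len(set(labs)) < 3
                total += 1
        p_expect = 1 - (m - 1) * (m - 2) / m**2
        se = math.sqrt(p_expect * (1 - p_expect) / total)
        assert abs(collide / total - p_expect) < 3 * se

    def test_seed_determinism(self, small_library, age_model):
        g = simulate.generate_drawing(small_library[1], 5, age_model, seed=8)
        a = simulate.generate_annotations(g, 0.5, seed=12)
        b = simulate.generate_annotations(g, 0.5, seed=12)
        pd.testing.assert_frame_equal(a, b)


class TestRatings:
    def test_null_predictors_symmetric_distribution(self):
        errors = pd.DataFrame(
            {"x": np.zeros(3000)}, index=[f"t{i}" for i in range(3000)]
        )
        ratings = simulate.generate_ratings(
            errors, {"x": 1.0}, thresholds=[-1.5, -0.5, 0.5, 1.5],
            rater_sd=0.0, seed=0, ratings_per_tracing=1,
        )
        freq = ratings["rating"].value_counts(normalize=True)
        assert ratings["rating"].mean() == pytest.approx(3.0, abs=0.1)
        assert freq[1] == pytest.approx(freq[5], abs=0.03)
        assert freq[2] == pytest.approx(freq[4], abs=0.03)

    def test_extreme_negative_predictor_saturates_at_one(self):
        errors = pd.DataFrame({"x": np.full(50, 20.0)}, index=range(50))
        ratings = simulate.generate_ratings(
            errors, {"x": -1.0}, thresholds=[-1.5, -0.5, 0.5, 1.5],
            rater_sd=0.0, seed=1,
        )
        assert (ratings["rating"] == 1).all()

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(ValueError):
            simulate.generate_ratings(
                pd.DataFrame({"x": [0.0]}), {"x": 1.0},
                thresholds=[0.5, -0.5, 1.0, 2.0], rater_sd=0.0,
            )


@pytest.fixture(scope="module")
def games():
    rng = np.random.default_rng(0)
    return {
        "g0": pd.DataFrame(
            {
                "drawing_id": [f"d{i}" for i in range(40)],
                "category": np.repeat(["a", "b", "c", "d"], 10),
                "evidence": rng.normal(0, 1.5, 40),
            }
        )
    }


class TestRecognitionSessions:

    def test_zero_sensitivity_is_chance(self, games):
        cfg = simulate.RecognitionSimConfig(
            beta0=0.0, beta_age=0.0, n_sessions_per_age=10,
            dont_know_rate=0.0, rt_outlier_rate=0.0,
        )
        trials = simulate.generate_recognition_sessions(games, cfg, seed=0)
        draw = trials[trials["trial_type"] == "drawing"]
        p = draw["correct"].mean()
        se = math.sqrt(0.25 * 0.75 / len(draw))
        assert abs(p - 0.25) < 3 * se

    def test_saturating_evidence_gives_perfect_accuracy(self, games):
        g = {"g0": games["g0"].assign(evidence=50.0)}
        cfg = simulate.RecognitionSimConfig(
            beta0=2.0, n_sessions_per_age=3, dont_know_rate=0.0,
        )
        trials = simulate.generate_recognition_sessions(g, cfg, seed=1)
        draw = trials[trials["trial_type"] == "drawing"]
        assert draw["correct"].all()

    def test_accuracy_increases_with_age(self, games):
        cfg = simulate.RecognitionSimConfig(n_sessions_per_age=40)
        trials = simulate.generate_recognition_sessions(games, cfg, seed=2)
        draw = trials[trials["trial_type"] == "drawing"]
        acc = draw.groupby("recognizer_age_years")["correct"].mean()
        rho, p = stats.spearmanr(acc.index, acc.to_numpy())
        assert rho > 0 and p < 0.05
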