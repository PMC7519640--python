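import numpy as np
import pytest

import serrscell as sc
from serrscell.classify import (
    FeatureRow,
    ForestConfig,
    attribution_from_votes,
    feature_importances,
    oob_attributions,
    predict_attribution,
    predict_attributions,
    size_gate,
    train_forest,
)
from serrscell.pipeline import build_reference_pools
from serrscell.config import RunConfig, PoolsConfig
from serrscell.scoring import ReferenceLibrary
from serrscell.synthetic import NoiseModel, noise_free_class_models
import serrscell.synthetic as syn


def _row(i, r=(0.0, 0.0, 0.0), area=100.0, label=None):
    return FeatureRow(cell_id=i, r1=r[0], r2=r[1], r3=r[2], area_um2=area, label=label)


def separable_rows(n_per_class=100, seed=0):
    """Three tightly clustered classes in (r1, r2, r3, area)."""
    rng = np.random.default_rng(seed)
    rows = []
    centers = {
        "LNCaP": (0.05, 0.9, 0.05, 90.0),
        "U251": (0.9, 0.05, 0.4, 70.0),
        "PBMC": (0.4, 0.05, 0.9, 40.0),
    }
    i = 0
    for label, (r1, r2, r3, area) in centers.items():
        for _ in range(n_per_class):
            jit = rng.normal(0, 0.01, 3)
            rows.append(
                FeatureRow(
                    cell_id=i,
                    r1=float(np.clip(r1 + jit[0], -1, 1)),
                    r2=float(np.clip(r2 + jit[1], -1, 1)),
                    r3=float(np.clip(r3 + jit[2], -1, 1)),
                    area_um2=float(area + rng.normal(0, 1)),
                    label=label,
                )
            )
            i += 1
    return rows


def nearest_centroid_error(rows):
    """Oracle: standardized nearest-centroid training error."""
    X = np.array([[r.r1, r.r2, r.r3, r.area_um2] for r in rows])
    y = np.array([r.label for r in rows])
    Xs = (X - X.mean(0)) / X.std(0)
    cents = {c: Xs[y == c].mean(0) for c in np.unique(y)}
    pred = [
        min(cents, key=lambda c: np.linalg.norm(x - cents[c]))
        for x in Xs
    ]
    return float(np.mean(np.array(pred) != y))


class TestSizeGate:
    def test_strict_bounds(self):
        rows = [_row(i, area=a) for i, a in enumerate((25, 30, 31, 100, 179, 180, 200))]
        kept = size_gate(rows)
        assert [r.area_um2 for r in kept] == [31, 100, 179]

    def test_order_preserved_and_bounds_validated(self):
        rows = [_row(0, area=50), _row(1, area=40), _row(2, area=60)]
        assert [r.cell_id for r in size_gate(rows)] == [0, 1, 2]
        with pytest.raises(ValueError):
            size_gate(rows, lower=100, upper=50)


class TestTrainForest:
    def test_single_class_rejected(self):
        rows = [_row(i, label="PBMC", area=40) for i in range(20)]
        with pytest.raises(ValueError, match="two classes"):
            train_forest(rows)

    def test_minimum_rows_per_class(self):
        rows = [_row(i, label="PBMC", area=40) for i in range(20)]
        rows += [_row(100 + i, label="U251", area=70) for i in range(5)]
        with pytest.raises(ValueError, match="10 rows"):
            train_forest(rows)

    def test_unlabelled_rows_rejected(self):
        rows = [_row(i, label="PBMC", area=40) for i in range(10)]
        rows += [_row(100 + i, label=None, area=70) for i in range(10)]
        with pytest.raises(ValueError, match="labelled"):
            train_forest(rows)

    def test_separable_classes_near_zero_oob(self):
        rows = separable_rows(100)
        assert nearest_centroid_error(rows) == 0.0  # oracle: classes separable
        forest = train_forest(rows, ForestConfig(n_trees=200, seed=0))
        assert forest.oob_error < 0.02
        assert all(0 <= e <= 1 for e in forest.class_errors.values())

    def test_permuted_labels_give_chance_oob(self):
        rows = separable_rows(100)
        rng = np.random.default_rng(1)
        labels = rng.permutation([r.label for r in rows])
        shuffled = [
            FeatureRow(r.cell_id, r.r1, r.r2, r.r3, r.area_um2, label=l)
            for r, l in zip(rows, labels)
        ]
        forest = train_forest(shuffled, ForestConfig(n_trees=300, seed=0))
        mc_sd = np.sqrt((2 / 3) * (1 / 3) / len(rows))
        assert abs(forest.oob_error - 2 / 3) < 3 * mc_sd + 0.02

    def test_seeded_reproducibility(self):
        rows = separable_rows(40)
        a = train_forest(rows, ForestConfig(n_trees=100, seed=3))
        b = train_forest(rows, ForestConfig(n_trees=100, seed=3))
        assert a.oob_error == b.oob_error
        assert a.class_errors == b.class_errors
        pa = predict_attributions(a, rows[:10])
        pb = predict_attributions(b, rows[:10])
        assert [x.fractions for x in pa] == [x.fractions for x in pb]

    def test_gate_then_train_equals_train_on_pregated(self):
        rng = np.random.default_rng(2)
        rows = []
        for i in range(120):
            label = ("LNCaP", "PBMC", "U251")[i % 3]
            rows.append(
                FeatureRow(i, *rng.uniform(-0.5, 0.9, 3), area_um2=float(rng.uniform(10, 250)),
                           label=label)
            )
        gated = size_gate(rows)
        a = train_forest(gated, ForestConfig(n_trees=50, seed=5))
        b = train_forest(size_gate(gated), ForestConfig(n_trees=50, seed=5))
        assert a.oob_error == b.oob_error


class TestAttribution:
    def test_unanimous_vote(self):
        a = attribution_from_votes(1, np.array([200, 0, 0]))
        assert a.dominant == "LNCaP"
        assert a.attribution_pct == 100.0
        assert a.fractions == {"LNCaP": 1.0, "PBMC": 0.0, "U251": 0.0}

    def test_uniform_vote_is_uncertainty_baseline(self):
        a = attribution_from_votes(1, np.array([100, 100, 100]))
        assert a.attribution_pct == pytest.approx(100.0 / 3.0)

    def test_max_rule_and_tie_break(self):
        a = attribution_from_votes(1, np.array([50, 30, 20]))
        assert a.dominant == "LNCaP" and a.attribution_pct == pytest.approx(50.0)
        tie = attribution_from_votes(2, np.array([40, 40, 20]))
        assert tie.dominant == "LNCaP"  # fixed class order breaks ties

    def test_vote_conservation(self, default_forest, default_pools):
        pools, _ = default_pools
        rows = pools.all_rows()[:50]
        for a in oob_attributions(default_forest, rows):
            assert sum(a.fractions.values()) == pytest.approx(1.0, abs=1e-12)
        unlabelled = [FeatureRow(10_000 + i, r.r1, r.r2, r.r3, r.area_um2) for i, r in enumerate(rows)]
        for a in predict_attributions(default_forest, unlabelled):
            assert sum(a.fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_feature_mismatch_rejected(self, default_forest):
        row = _row(0, area=60)
        import dataclasses

        other = dataclasses.replace(default_forest, interaction_features=True)
        with pytest.raises(ValueError, match="feature"):
            predict_attributions(other, [row])

    def test_oob_attribution_requires_training_row(self, default_forest):
        with pytest.raises(KeyError):
            oob_attributions(default_forest, [_row(999_999, area=60)])

    def test_confident_prediction_on_separable_data(self):
        rows = separable_rows(50)
        forest = train_forest(rows, ForestConfig(n_trees=100, seed=0))
        probe = _row(5000, r=(0.05, 0.9, 0.05), area=90.0)
        a = predict_attribution(forest, probe)
        assert a.dominant == "LNCaP" and a.attribution_pct > 95.0


class TestFeatureImportance:
    def test_ns2_correlation_separates_epithelial_cells(self, default_forest):
        """On default synthetic data the NS-2 correlation must rank top-2 by
        impurity importance, reflecting that NS-2 identifies LNCaP."""
        imp = feature_importances(default_forest)
        top2 = sorted(imp, key=imp.get, reverse=True)[:2]
        assert "r_ns2" in top2
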