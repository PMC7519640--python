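"""Size gating and random-forest attribution of cells to phenotypes.

The classifier input per cell is the three Pearson coefficients against the
reporter references plus the measured cell area.  Cells outside the strict
30-180 um^2 window are discarded first (the gate removes most PBMCs).  A
bagged ensemble of classification trees votes on each cell; the share of
trees voting each class is the cell's "percentage of attribution", and the
dominant class identifies the cell.  A uniform vote (~33% each) marks an
unidentifiable cell.

For cells that were part of the training pools, attributions are computed
from out-of-bag trees only, matching the behaviour of R's randomForest when
predicting on the training set; in-bag votes would be near-certain and
useless for calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.ensemble._forest import _generate_sample_indices, _get_n_samples_bootstrap

CLASS_ORDER = ("LNCaP", "PBMC", "U251")


@dataclass(frozen=True)
class FeatureRow:
    """Per-cell classifier input: spectral correlations plus area."""

    cell_id: int
    r1: float
    r2: float
    r3: float
    area_um2: float
    label: str | None = None

    def __post_init__(self) -> None:
        for r in (self.r1, self.r2, self.r3):
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"cell {self.cell_id}: correlation {r} outside [-1, 1]")
        if self.area_um2 <= 0:
            raise ValueError(f"cell {self.cell_id}: area must be > 0")
        if self.label is not None and self.label not in CLASS_ORDER:
            raise ValueError(f"cell {self.cell_id}: unknown label {self.label!r}")


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 5000
    m_try: int = 3
    seed: int = 0
    interaction_features: bool = False
    class_weight: str | dict | None = None

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.m_try < 1:
            raise ValueError("m_try must be >= 1")


@dataclass
class Attribution:
    """Vote fractions of one cell; attribution percent = 100 x max fraction."""

    cell_id: int
    fractions: dict[str, float]
    dominant: str
    attribution_pct: float


@dataclass
class TrainedForest:
    model: RandomForestClassifier
    oob_error: float
    class_errors: dict[str, float]
    feature_names: tuple[str, ...]
    interaction_features: bool
    training_ids: dict[int, int] = field(repr=False)  # cell_id -> row index
    oob_votes: np.ndarray = field(repr=False)  # (n_train, 3) in CLASS_ORDER


def size_gate(rows: list[FeatureRow], lower: float = 30.0, upper: float = 180.0) -> list[FeatureRow]:
    """Keep cells with lower < area < upper (strict bounds), preserving order."""
    if not lower < upper:
        raise ValueError("size gate requires lower < upper")
    return [r for r in rows if lower < r.area_um2 < upper]


_BASE_FEATURES = ("r_ns1", "r_ns2", "r_ns3", "area_um2")


def _design_matrix(rows: list[FeatureRow], interactions: bool) -> tuple[np.ndarray, tuple[str, ...]]:
    X = np.array([[r.r1, r.r2, r.r3, r.area_um2] for r in rows], dtype=float)
    names = _BASE_FEATURES
    if interactions:
        extra_cols, extra_names = [], []
        for i in range(4):
            extra_cols.append(X[:, i] ** 2)
            extra_names.append(f"{names[i]}^2")
        for i in range(4):
            for j in range(i + 1, 4):
                extra_cols.append(X[:, i] * X[:, j])
                extra_names.append(f"{names[i]}*{names[j]}")
        X = np.column_stack([X] + extra_cols)
        names = names + tuple(extra_names)
    return X, names


def attribution_from_votes(cell_id: int, votes: np.ndarray) -> Attribution:
    """Votes in CLASS_ORDER -> Attribution; argmax ties resolve to the first
    class in the fixed order."""
    total = votes.sum()
    fractions = votes / total if total > 0 else np.full(3, 1.0 / 3.0)
    k = int(np.argmax(fractions))
    return Attribution(
        cell_id=cell_id,
        fractions={c: float(f) for c, f in zip(CLASS_ORDER, fractions)},
        dominant=CLASS_ORDER[k],
        attribution_pct=100.0 * float(fractions[k]),
    )


def _tree_vote_matrix(model: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Per-tree hard votes, (n_trees, n_samples) of CLASS_ORDER indices."""
    class_to_idx = {c: CLASS_ORDER.index(c) for c in model.classes_}
    remap = np.array([class_to_idx[c] for c in model.classes_])
    votes = np.empty((len(model.estimators_), X.shape[0]), dtype=np.int64)
    for t, tree in enumerate(model.estimators_):
        votes[t] = remap[tree.predict(X).astype(np.int64)]
    return votes


def train_forest(rows: list[FeatureRow], config: ForestConfig = ForestConfig()) -> TrainedForest:
    """Fit the bagged tree ensemble on labelled cells.

    Gini-impurity splitting, ``m_try`` features tried per split (clipped to
    the number of features), fully grown trees.  The out-of-bag error and
    per-class error rates are computed from hard out-of-bag tree votes.
    """
    if any(r.label is None for r in rows):
        raise ValueError("all training rows must be labelled")
    labels = [r.label for r in rows]
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training needs at least two classes")
    if counts.min() < 10:
        raise ValueError("training needs >= 10 rows per class")
    X, names = _design_matrix(rows, config.interaction_features)
    y = np.array(labels)
    model = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=min(config.m_try, X.shape[1]),
        criterion="gini",
        bootstrap=True,
        random_state=config.seed,
        class_weight=config.class_weight,
        n_jobs=1,
    )
    model.fit(X, y)

    n = X.shape[0]
    n_boot = _get_n_samples_bootstrap(n, model.max_samples, None)
    tree_votes = _tree_vote_matrix(model, X)
    oob_votes = np.zeros((n, 3), dtype=np.int64)
    for t, tree in enumerate(model.estimators_):
        sampled = _generate_sample_indices(tree.random_state, n, n_boot, None)
        oob_mask = np.bincount(sampled, minlength=n) == 0
        idx = np.flatnonzero(oob_mask)
        np.add.at(oob_votes, (idx, tree_votes[t, idx]), 1)

    y_idx = np.array([CLASS_ORDER.index(c) for c in y])
    has_votes = oob_votes.sum(axis=1) > 0
    oob_pred = np.argmax(oob_votes, axis=1)
    wrong = (oob_pred != y_idx) & has_votes
    oob_error = float(wrong.sum() / max(has_votes.sum(), 1))
    class_errors = {}
    for k, c in enumerate(CLASS_ORDER):
        sel = (y_idx == k) & has_votes
        class_errors[c] = float(wrong[sel].sum() / sel.sum()) if sel.any() else float("nan")

    return TrainedForest(
        model=model,
        oob_error=oob_error,
        class_errors=class_errors,
        feature_names=names,
        interaction_features=config.interaction_features,
        training_ids={r.cell_id: i for i, r in enumerate(rows)},
        oob_votes=oob_votes,
    )


def predict_attributions(forest: TrainedForest, rows: list[FeatureRow]) -> list[Attribution]:
    """Vote-fraction attribution of new cells: share of all trees voting each
    class."""
    if not rows:
        return []
    X, names = _design_matrix(rows, forest.interaction_features)
    if names != forest.feature_names:
        raise ValueError("feature set differs from the training features")
    tree_votes = _tree_vote_matrix(forest.model, X)
    counts = np.stack([(tree_votes == k).sum(axis=0) for k in range(3)], axis=1)
    return [attribution_from_votes(r.cell_id, counts[i]) for i, r in enumerate(rows)]


def predict_attribution(forest: TrainedForest, row: FeatureRow) -> Attribution:
    return predict_attributions(forest, [row])[0]


def oob_attributions(forest: TrainedForest, rows: list[FeatureRow]) -> list[Attribution]:
    """Attributions of training cells from their out-of-bag trees only."""
    out = []
    for r in rows:
        if r.cell_id not in forest.training_ids:
            raise KeyError(f"cell {r.cell_id} was not part of the training set")
        out.append(attribution_from_votes(r.cell_id, forest.oob_votes[forest.training_ids[r.cell_id]]))
    return out


def feature_importances(forest: TrainedForest) -> dict[str, float]:
    """Mean-decrease-in-impurity importance per feature."""
    return dict(zip(forest.feature_names, map(float, forest.model.feature_importances_)))
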