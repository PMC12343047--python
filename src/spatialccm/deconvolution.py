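"""Cell-type purity scores from a marker-expression classifier.

Lateral spillover makes a contaminated cell's expression profile drift
toward that of its neighbours. A random-forest classifier trained to
predict each cell's annotated type from its marker profile therefore
assigns contaminated cells lower probability of belonging to their own
type. These predicted probabilities ("purity scores") are used downstream
as regression covariates that absorb contamination-driven expression
variance.

The forest is trained once on all cells pooled across images. Two
prediction modes are offered: in-sample predicted probabilities (the
default) and out-of-bag votes, which are less optimistic about each cell's
purity because a cell never votes on itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .io_data import CellDataset

DEFAULT_N_TREES = 500


@dataclass
class PurityScores:
    """Row-stochastic cell x cell-type probability matrix p_{i,t}."""

    probabilities: pd.DataFrame  # index cell_id, columns cell types
    model_meta: dict

    def __post_init__(self) -> None:
        row_sums = self.probabilities.to_numpy().sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-6):
            raise ValueError("purity rows must sum to 1")

    @property
    def cell_types(self) -> list[str]:
        return list(self.probabilities.columns)

    def to_csv(self, path) -> None:
        self.probabilities.to_csv(path, index_label="cell_id")


@dataclass
class CellTypeClassifier:
    forest: RandomForestClassifier
    markers: list[str]
    classes: list[str]
    n_trees: int
    seed: int


def fit_cell_type_classifier(
    dataset: CellDataset, n_trees: int = DEFAULT_N_TREES, seed: int = 0
) -> CellTypeClassifier:
    """Train a random forest predicting cell_type from marker expression.

    All cells across all images are pooled; features are the raw marker
    intensities. The forest keeps out-of-bag votes so either prediction
    mode can be served later.
    """
    labels = dataset.cells["cell_type"].to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two cell types to fit a classifier")
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        small = list(counts[counts < 2].index)
        raise ValueError(f"cell types with fewer than 2 cells: {small}")
    # leaf size 10 keeps predicted probabilities graded rather than
    # saturating at 0/1 for every training cell (probability-forest
    # convention); saturated scores carry no contamination signal
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        min_samples_leaf=10,
        random_state=seed,
        oob_score=True,
        n_jobs=1,
    )
    forest.fit(dataset.expression.to_numpy(), labels)
    return CellTypeClassifier(
        forest=forest,
        markers=dataset.markers,
        classes=list(forest.classes_),
        n_trees=n_trees,
        seed=seed,
    )


def predict_purity(
    classifier: CellTypeClassifier,
    dataset: CellDataset,
    mode: str = "in_sample",
) -> PurityScores:
    """Predict per-cell cell-type probabilities.

    ``mode='in_sample'`` returns the forest's predicted probabilities for
    the given cells. ``mode='oob'`` returns out-of-bag votes and is only
    defined for the training dataset; cells that were in-bag for every tree
    fall back to in-sample probabilities.
    """
    missing = [m for m in classifier.markers if m not in dataset.markers]
    if missing:
        raise ValueError(f"dataset lacks classifier markers: {missing}")
    X = dataset.expression[classifier.markers].to_numpy()
    if mode == "in_sample":
        probs = classifier.forest.predict_proba(X)
    elif mode == "oob":
        oob = classifier.forest.oob_decision_function_
        if oob.shape[0] != len(dataset.cells):
            raise ValueError("out-of-bag mode requires the training dataset")
        probs = oob.copy()
        bad = ~np.isfinite(probs).all(axis=1) | (probs.sum(axis=1) == 0)
        if bad.any():
            probs[bad] = classifier.forest.predict_proba(X[bad])
    else:
        raise ValueError(f"unknown prediction mode {mode!r}")
    probs = probs / probs.sum(axis=1, keepdims=True)
    return PurityScores(
        probabilities=pd.DataFrame(
            probs,
            index=pd.Index(dataset.cells["cell_id"], name="cell_id"),
            columns=classifier.classes,
        ),
        model_meta={
            "algorithm": "random_forest",
            "n_trees": classifier.n_trees,
            "seed": classifier.seed,
            "mode": mode,
        },
    )
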