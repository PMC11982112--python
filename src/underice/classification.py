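"""Random-forest classifier selection for IFCB feature vectors.

The classifier never sees images — only the fixed-order feature vectors
from :mod:`underice.imaging`. Training sets are balanced per category
(categories below ``min_n`` images are excluded, those above ``max_n`` are
subsampled), a bagged-decision-tree forest is grown, and an image is
assigned the plurality class only when the winning vote fraction clears a
threshold; otherwise it is left 'unclassified'. The catch-all 'Other'
category is never trained on. Candidate classifiers are ranked on two
metrics: the error rate over accepted classifications and the unclassified
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

UNCLASSIFIED = "unclassified"
OTHER = "Other"
DEFAULT_VOTE_THRESHOLD = 0.5
DEFAULT_MIN_VALUES = (200, 300, 400, 500)
DEFAULT_MAX_VALUES = (300, 400, 500, 600, 700, 800, 900)
DEFAULT_TREE_COUNTS = (25, 50)


class DegenerateCandidateError(ValueError):
    """A grid pair with max_n < min_n: enumerated but not trainable."""


@dataclass
class TrainingSet:
    features: pd.DataFrame      # index image_id, numeric feature columns
    labels: pd.Series           # aligned with features
    categories: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.labels.index):
            raise ValueError("features and labels must share an index")
        if self.features.index.has_duplicates:
            raise ValueError("duplicate image ids in training set")


@dataclass
class ClassifierCandidate:
    min_n: int
    max_n: int
    n_trees: int
    status: str = "ok"                 # 'ok' | 'failed'
    model: Optional[RandomForestClassifier] = None
    error_rate: float = np.nan
    unclassified_fraction: float = np.nan
    n_training_images: int = 0
    excluded: list = field(default_factory=list)
    degenerate_evaluation: bool = False


# ---------------------------------------------------------------------------
# grid and training-set assembly
# ---------------------------------------------------------------------------

def enumerate_grid(min_values: Sequence[int] = DEFAULT_MIN_VALUES,
                   max_values: Sequence[int] = DEFAULT_MAX_VALUES,
                   tree_counts: Sequence[int] = DEFAULT_TREE_COUNTS):
    """Full Cartesian product of (min_n, max_n, n_trees), deterministic order.

    No max_n ≥ min_n constraint is applied: the 4 × 7 selection grid counts
    all 28 pairs, including the ones a later stage records as failed
    candidates.
    """
    if not (len(min_values) and len(max_values) and len(tree_counts)):
        raise ValueError("grid value lists must be non-empty")
    return [(int(a), int(b), int(t))
            for a, b, t in product(min_values, max_values, tree_counts)]


def assemble_training_set(database: pd.DataFrame, min_n: int, max_n: int,
                          seed: int = 0) -> tuple[TrainingSet, list]:
    """Balanced per-category training set from a feature database.

    ``database`` holds one row per image (index image_id) with a
    ``category`` column plus numeric features. Categories with fewer than
    ``min_n`` images are excluded (and reported); categories above ``max_n``
    are subsampled to ``max_n`` reproducibly by ``seed``. 'Other' is always
    excluded from training.
    """
    if database.empty:
        raise ValueError("empty training database")
    if min_n > max_n:
        raise DegenerateCandidateError(f"min_n {min_n} > max_n {max_n}")
    rng = np.random.default_rng(seed)
    kept, excluded = [], []
    for category, group in database.groupby("category", sort=True):
        if category == OTHER:
            continue
        if len(group) < min_n:
            excluded.append(category)
            continue
        if len(group) > max_n:
            idx = rng.choice(len(group), size=max_n, replace=False)
            group = group.iloc[np.sort(idx)]
        kept.append(group)
    if not kept:
        raise ValueError("no category met the minimum-image threshold")
    frame = pd.concat(kept)
    features = frame.drop(columns=["category"])
    ts = TrainingSet(features=features, labels=frame["category"],
                     categories=sorted(frame["category"].unique()),
                     provenance={"seed": seed, "min_n": min_n, "max_n": max_n})
    return ts, excluded


# ---------------------------------------------------------------------------
# training and prediction
# ---------------------------------------------------------------------------

def train_forest(ts: TrainingSet, n_trees: int, seed: int = 0) -> RandomForestClassifier:
    """Grow ``n_trees`` bagged decision trees on the training set."""
    if len(ts.categories) < 2:
        raise ValueError("at least two categories required to train")
    model = RandomForestClassifier(n_estimators=n_trees, bootstrap=True,
                                   random_state=seed, n_jobs=1)
    model.fit(ts.features.to_numpy(), ts.labels.to_numpy())
    model.feature_names_in_ = np.asarray(ts.features.columns, dtype=object)
    return model


def classify(model: RandomForestClassifier, features: pd.DataFrame,
             vote_threshold: float = DEFAULT_VOTE_THRESHOLD) -> pd.DataFrame:
    """Per-image label and winning vote fraction.

    The label is the class chosen by the most trees; if its vote fraction
    falls below ``vote_threshold`` the image is left 'unclassified'. Vote
    ties break to the lexicographically first class name.
    """
    expected = list(getattr(model, "feature_names_in_", features.columns))
    if list(features.columns) != expected:
        raise ValueError("feature columns do not match the training order")
    x = features.to_numpy()
    if x.shape[1] != model.n_features_in_:
        raise ValueError("feature dimension mismatch")
    # per-tree plurality votes (not averaged probabilities)
    votes = np.zeros((x.shape[0], len(model.classes_)), dtype=int)
    for tree in model.estimators_:
        pred = tree.predict(x).astype(int)
        votes[np.arange(x.shape[0]), pred] += 1
    order = np.argsort(model.classes_)  # classes_ is sorted; explicit anyway
    win = np.argmax(votes[:, order], axis=1)  # argmax takes first (lexicographic) tie
    labels = model.classes_[order][win]
    fractions = votes[np.arange(x.shape[0]), order[win]] / len(model.estimators_)
    labels = np.where(fractions >= vote_threshold, labels, UNCLASSIFIED)
    return pd.DataFrame({"label": labels, "vote_fraction": fractions},
                        index=features.index)


def evaluate_candidate(model: RandomForestClassifier, heldout_features: pd.DataFrame,
                       heldout_labels: pd.Series,
                       vote_threshold: float = DEFAULT_VOTE_THRESHOLD):
    """(error_rate over accepted images, unclassified fraction over all).

    If every image is rejected the error rate is undefined and reported as
    NaN with ``degenerate=True``.
    """
    if heldout_features.empty:
        raise ValueError("empty held-out set")
    result = classify(model, heldout_features, vote_threshold)
    accepted = result["label"] != UNCLASSIFIED
    unclassified_fraction = float(1.0 - accepted.mean())
    if not accepted.any():
        return np.nan, unclassified_fraction, True
    err = float((result.loc[accepted, "label"]
                 != heldout_labels.loc[accepted]).mean())
    return err, unclassified_fraction, False


def run_grid(database: pd.DataFrame, grid=None,
             vote_threshold: float = DEFAULT_VOTE_THRESHOLD,
             seed: int = 0, test_fraction: float = 0.2) -> list:
    """Train and score every grid candidate on a stratified 80/20 hold-out."""
    if grid is None:
        grid = enumerate_grid()
    candidates = []
    for min_n, max_n, n_trees in grid:
        cand = ClassifierCandidate(min_n=min_n, max_n=max_n, n_trees=n_trees)
        try:
            ts, excluded = assemble_training_set(database, min_n, max_n, seed)
            cand.excluded = excluded
            x_tr, x_te, y_tr, y_te = train_test_split(
                ts.features, ts.labels, test_size=test_fraction,
                stratify=ts.labels, random_state=seed)
            model = train_forest(
                TrainingSet(x_tr, y_tr, ts.categories, ts.provenance),
                n_trees, seed)
            err, unc, degenerate = evaluate_candidate(model, x_te, y_te,
                                                      vote_threshold)
            cand.model = model
            cand.error_rate = err
            cand.unclassified_fraction = unc
            cand.degenerate_evaluation = degenerate
            cand.n_training_images = len(x_tr)
        except (DegenerateCandidateError, ValueError) as exc:
            cand.status = "failed"
            cand.excluded = getattr(cand, "excluded", []) or [str(exc)]
        candidates.append(cand)
    return candidates


def grid_report(candidates) -> pd.DataFrame:
    return pd.DataFrame([
        {"min_n": c.min_n, "max_n": c.max_n, "n_trees": c.n_trees,
         "error_rate": c.error_rate,
         "unclassified_fraction": c.unclassified_fraction,
         "n_training_images": c.n_training_images, "status": c.status}
        for c in candidates])


def select_best(candidates) -> ClassifierCandidate:
    """Deterministic winner: lowest accepted-classification error rate,
    ties broken by lower unclassified fraction, then fewer training images,
    then fewer trees."""
    viable = [c for c in candidates
              if c.status == "ok" and np.isfinite(c.error_rate)]
    if not viable:
        raise ValueError("no successfully trained candidate")
    return min(viable, key=lambda c: (c.error_rate, c.unclassified_fraction,
                                      c.n_training_images, c.n_trees))


# ---------------------------------------------------------------------------
# verification samples
# ---------------------------------------------------------------------------

def verification_schedule(samples: pd.DataFrame, per_period: int = 3,
                          period_days: float = 14.0, seed: int = 0) -> list:
    """Sample ids manually verified: ``per_period`` random draws without
    replacement per ``period_days`` window (fewer if a window is short)."""
    if samples.empty:
        return []
    rng = np.random.default_rng(seed)
    times = pd.to_datetime(samples["time"])
    t0 = times.min()
    window = ((times - t0) / pd.Timedelta(days=period_days)).astype(int)
    chosen = []
    for _, group in samples.assign(_w=window).groupby("_w", sort=True):
        ids = group["sample_id"].tolist()
        take = min(per_period, len(ids))
        chosen.extend(list(rng.choice(ids, size=take, replace=False)))
    return chosen


def verification_compare(auto_labels: pd.Series, manual_labels: pd.Series) -> dict:
    """Per-class contingency between auto and manual classifications.

    Returns the confusion matrix (rows manual, columns auto), per-class
    counts for both assessors, and the overall agreement rate.
    """
    if not auto_labels.index.sort_values().equals(manual_labels.index.sort_values()):
        raise ValueError("auto and manual labels cover different images")
    manual = manual_labels.loc[auto_labels.index]
    confusion = pd.crosstab(manual, auto_labels,
                            rownames=["manual"], colnames=["auto"])
    return {
        "confusion": confusion,
        "auto_counts": auto_labels.value_counts().sort_index(),
        "manual_counts": manual.value_counts().sort_index(),
        "agreement": float((auto_labels == manual).mean()),
    }
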