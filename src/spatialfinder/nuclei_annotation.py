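"""Nucleus cell-typing: zero-shot text matching plus active-learning refinement.

The workflow starts from zero-shot labels (argmax cosine similarity between
each nucleus embedding and the text embeddings of the class names), then runs
annotation cycles: an annotator labels a small batch of nuclei, a
gradient-boosted multiclass classifier is retrained on the cumulative
annotation set, and the whole table is relabeled. A simulated annotator that
answers from planted truth stands in for the expert so the loop is testable
offline; its query strategy, per-cycle class focus and mislabel rate are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .embedding_backend import embed_text
from .slide_io import NucleiTable

__all__ = [
    "LabelSet",
    "AnnotationBatch",
    "ClassifierState",
    "zero_shot_label",
    "zero_shot_scores",
    "train_classifier",
    "apply_classifier",
    "SimulatedAnnotator",
    "active_learning_session",
]

# classifier defaults: standard gradient-boosted-tree settings, no tuning
XGB_PARAMS = dict(
    n_estimators=100,
    max_depth=6,
    learning_rate=0.3,
    objective="multi:softprob",
)


@dataclass(frozen=True)
class LabelSet:
    """Ordered cell-type class names, optionally designating a target class."""

    names: tuple
    target_class: str | None = None

    def __init__(self, names, target_class: str | None = None):
        names = tuple(names)
        if not 2 <= len(names) <= 10:
            raise ValueError("label set must contain 2-10 classes")
        if len(set(names)) != len(names):
            raise ValueError("class names must be unique")
        if target_class is not None and target_class not in names:
            raise ValueError(f"target class {target_class!r} not in label set")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "target_class", target_class)

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class AnnotationBatch:
    """One annotation cycle's worth of same-label nuclei."""

    nucleus_ids: np.ndarray
    label: str
    cycle: int = 0
    selection_mode: str = "rectangle"

    def __post_init__(self) -> None:
        self.nucleus_ids = np.asarray(self.nucleus_ids, dtype=np.int64)
        if self.selection_mode not in ("rectangle", "polygon"):
            raise ValueError("selection_mode must be rectangle or polygon")


@dataclass
class ClassifierState:
    """A trained multiclass model over nucleus embeddings."""

    model: object
    classes: tuple
    n_train: int
    cycle: int = 0


def zero_shot_scores(nuclei: NucleiTable, labels: LabelSet, backend) -> np.ndarray:
    """Cosine similarity of every nucleus embedding to every class text embedding."""
    if len(labels) == 0:
        raise ValueError("empty label set")
    text = np.stack([embed_text(name, backend).vector for name in labels.names])
    x = nuclei.embedding
    nx = np.linalg.norm(x, axis=1, keepdims=True)
    nt = np.linalg.norm(text, axis=1, keepdims=True)
    if (nx == 0).any() or (nt == 0).any():
        raise ValueError("zero-norm embedding encountered")
    return (x / nx) @ (text / nt).T


def zero_shot_label(nuclei: NucleiTable, labels: LabelSet, backend) -> NucleiTable:
    """Argmax-cosine label per nucleus; ties go to the lowest class index."""
    sims = zero_shot_scores(nuclei, labels, backend)
    idx = np.argmax(sims, axis=1)  # argmax takes the first maximum
    return nuclei.with_labels(np.array([labels.names[i] for i in idx], dtype=object))


def _cumulative_training_set(annotations, nuclei: NucleiTable):
    id_to_row = {int(i): r for r, i in enumerate(nuclei.nucleus_id)}
    rows, labels = [], []
    seen = {}
    for batch in annotations:
        for nid in batch.nucleus_ids:
            nid = int(nid)
            if nid not in id_to_row:
                raise ValueError(f"annotated nucleus id {nid} not in table")
            seen[nid] = batch.label  # later cycles override earlier labels
    for nid, lab in seen.items():
        rows.append(id_to_row[nid])
        labels.append(lab)
    return np.asarray(rows, dtype=int), np.asarray(labels, dtype=object)


def train_classifier(annotations, nuclei: NucleiTable, seed: int = 0) -> ClassifierState:
    """Fit the gradient-boosted classifier on the cumulative annotation set.

    Raises if the annotations cover fewer than two classes.
    """
    from xgboost import XGBClassifier

    rows, labels = _cumulative_training_set(annotations, nuclei)
    classes = tuple(dict.fromkeys(labels))
    if len(classes) < 2:
        raise ValueError(
            "training set covers a single class; annotate at least one more class"
        )
    y = np.array([classes.index(l) for l in labels])
    model = XGBClassifier(**XGB_PARAMS, num_class=len(classes), random_state=seed)
    model.fit(nuclei.embedding[rows], y)
    return ClassifierState(
        model=model, classes=classes, n_train=len(rows),
        cycle=max((b.cycle for b in annotations), default=0),
    )


def apply_classifier(state: ClassifierState, nuclei: NucleiTable):
    """Relabel every nucleus with the argmax-probability class.

    Returns ``(labeled table, probability matrix)``; probabilities sum to one
    per nucleus. An empty table returns empty outputs.
    """
    if len(nuclei) == 0:
        return nuclei.with_labels(np.array([], dtype=object)), np.zeros((0, len(state.classes)))
    if nuclei.dim != state.model.n_features_in_:
        raise ValueError(
            f"embedding dim {nuclei.dim} != classifier dim {state.model.n_features_in_}"
        )
    proba = state.model.predict_proba(nuclei.embedding)
    idx = np.argmax(proba, axis=1)
    labels = np.array([state.classes[i] for i in idx], dtype=object)
    return nuclei.with_labels(labels), proba


class SimulatedAnnotator:
    """Answers annotation queries from planted truth (the pathologist stand-in).

    Parameters
    ----------
    truth : planted class label per nucleus (aligned to the table).
    mislabel_rate : probability of returning a wrong label for a nucleus.
    focus_schedule : optional ``{cycle: class_name}``; on those cycles only
        nuclei of that true class are labeled (class-at-a-time behavior).
    """

    def __init__(self, truth, mislabel_rate: float = 0.0, focus_schedule: dict | None = None,
                 seed: int = 0):
        self.truth = np.asarray(truth, dtype=object)
        self.mislabel_rate = float(mislabel_rate)
        self.focus_schedule = focus_schedule or {}
        self.rng = np.random.default_rng(seed)

    def __call__(self, query_rows: np.ndarray, cycle: int, labels: LabelSet):
        """Return (rows, labels) for the queried nuclei, honoring any class focus."""
        rows = np.asarray(query_rows, dtype=int)
        focus = self.focus_schedule.get(cycle)
        if focus is not None:
            rows = rows[self.truth[rows] == focus]
        out = self.truth[rows].copy()
        if self.mislabel_rate > 0 and len(rows):
            flip = self.rng.random(len(rows)) < self.mislabel_rate
            for i in np.flatnonzero(flip):
                others = [n for n in labels.names if n != out[i]]
                out[i] = self.rng.choice(others)
        return rows, out


def active_learning_session(
    nuclei: NucleiTable,
    labels: LabelSet,
    annotator,
    backend,
    n_cycles: int = 10,
    budget_per_cycle: int = 30,
    seed: int = 0,
    truth=None,
):
    """Run the zero-shot + iterative-retraining loop.

    Starts from zero-shot labels; each cycle queries ``budget_per_cycle``
    nuclei (uncertainty-first: lowest current max-score among unannotated),
    passes them to the annotator, retrains on the cumulative annotations and
    relabels the whole table. Returns ``(state, labeled table, log)`` where the
    log records per-cycle cumulative annotation counts and — when planted
    truth is available — accuracy against it. A zero budget or zero cycles
    returns the zero-shot labeling with an empty log.
    """
    rng = np.random.default_rng(seed)
    sims = zero_shot_scores(nuclei, labels, backend)
    labeled = nuclei.with_labels(
        np.array([labels.names[i] for i in np.argmax(sims, axis=1)], dtype=object)
    )
    confidence = sims.max(axis=1)

    def acc(lbls):
        if truth is None:
            return np.nan
        return float((np.asarray(lbls, dtype=object) == np.asarray(truth, dtype=object)).mean())

    records = [
        {"cycle": 0, "n_annotated_cum": 0, "n_new": 0, "accuracy": acc(labeled.label)}
    ]
    state = None
    if n_cycles < 1 or budget_per_cycle < 1:
        empty = pd.DataFrame(columns=["cycle", "n_annotated_cum", "n_new", "accuracy"])
        return state, labeled, empty

    annotations: list[AnnotationBatch] = []
    annotated_rows: set[int] = set()
    for cycle in range(1, n_cycles + 1):
        # uncertainty-first with random tie-breaking, so flat confidence
        # fields are sampled across the tissue rather than in index order
        order = np.lexsort((rng.random(len(confidence)), confidence))
        candidates = np.array(
            [r for r in order if r not in annotated_rows], dtype=int
        )
        query = candidates[:budget_per_cycle]
        if len(query) == 0:
            break
        rows, batch_labels = annotator(query, cycle, labels)
        if len(rows) == 0:
            records.append(
                {"cycle": cycle, "n_annotated_cum": len(annotated_rows), "n_new": 0,
                 "accuracy": records[-1]["accuracy"]}
            )
            continue
        annotated_rows.update(int(r) for r in rows)
        for lab in dict.fromkeys(batch_labels):
            ids = nuclei.nucleus_id[rows[np.asarray(batch_labels, dtype=object) == lab]]
            annotations.append(AnnotationBatch(ids, str(lab), cycle=cycle))
        try:
            state = train_classifier(annotations, nuclei, seed=int(rng.integers(2**31)))
        except ValueError:
            # single-class annotation set so far: keep zero-shot labels this cycle
            records.append(
                {"cycle": cycle, "n_annotated_cum": len(annotated_rows),
                 "n_new": len(rows), "accuracy": records[-1]["accuracy"]}
            )
            continue
        labeled, proba = apply_classifier(state, nuclei)
        confidence = proba.max(axis=1)
        records.append(
            {"cycle": cycle, "n_annotated_cum": len(annotated_rows),
             "n_new": len(rows), "accuracy": acc(labeled.label)}
        )
    return state, labeled, pd.DataFrame(records)
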