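"""Viable / apoptotic / necrotic classification of tracked nuclei.

A binary decision tree trained on expert-labelled Hoechst features
(area, mean, min, max, SD) separates large-uniform nuclei (class 1:
viable or necrotic) from condensed bright nuclei (class 2: apoptotic).
Class-1 nuclei are then split by a PI intensity threshold calibrated on
control images: low PI = viable, high PI = necrotic (membrane rupture).

Because staining fluctuates frame to frame, raw per-frame labels are
finally regularised per track by allowing only physiologically feasible
transitions — death is irreversible, and an apoptotic cell may still
rupture (secondary necrosis) — choosing the feasible sequence with the
minimum number of disagreements against the raw labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from sklearn.tree import DecisionTreeClassifier

from .track import RecordKind, Track
from .types import FEATURE_COLUMNS, CellState, NucleusDetection

#: allowed[s, s'] — stay anywhere; viable->apoptotic, viable->necrotic,
#: apoptotic->necrotic (secondary necrosis); nothing leaves necrotic.
#: With states ordered viable < apoptotic < necrotic this is s' >= s.
FEASIBLE_TRANSITIONS = np.array([
    [True, True, True],
    [False, True, True],
    [False, False, True],
])

CLASS1_LARGE_UNIFORM = 1
CLASS2_CONDENSED = 2


@dataclass
class PiCalibration:
    """PI threshold separating viable from necrotic, plus provenance."""

    threshold: float
    method: str  # "otsu" | "mean_plus_k_sd"


@dataclass
class TrainedClassifier:
    """Portable decision tree (axis-aligned splits) plus PI threshold.

    The tree is stored as flat arrays so models serialise to plain JSON
    and predictions do not depend on any fitted estimator object.
    """

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    leaf_class: np.ndarray  # class id per node (valid at leaves)
    pi_threshold: float = np.inf
    feature_order: tuple[str, ...] = FEATURE_COLUMNS

    @property
    def depth(self) -> int:
        def walk(node: int) -> int:
            if self.children_left[node] == -1:
                return 0
            return 1 + max(walk(self.children_left[node]),
                           walk(self.children_right[node]))
        return walk(0)

    def predict_class(self, features: np.ndarray) -> int:
        """Walk the tree for one feature vector; returns class 1 or 2."""
        node = 0
        while self.children_left[node] != -1:
            if features[self.feature[node]] <= self.threshold[node]:
                node = self.children_left[node]
            else:
                node = self.children_right[node]
        return int(self.leaf_class[node])

    def to_json(self) -> str:
        return json.dumps({
            "children_left": self.children_left.tolist(),
            "children_right": self.children_right.tolist(),
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "leaf_class": self.leaf_class.tolist(),
            "pi_threshold": self.pi_threshold,
            "feature_order": list(self.feature_order),
        })

    @classmethod
    def from_json(cls, text: str) -> "TrainedClassifier":
        d = json.loads(text)
        return cls(
            children_left=np.asarray(d["children_left"], dtype=int),
            children_right=np.asarray(d["children_right"], dtype=int),
            feature=np.asarray(d["feature"], dtype=int),
            threshold=np.asarray(d["threshold"], dtype=float),
            leaf_class=np.asarray(d["leaf_class"], dtype=int),
            pi_threshold=float(d["pi_threshold"]),
            feature_order=tuple(d["feature_order"]),
        )


def train_tree(features: np.ndarray, classes: np.ndarray,
               max_depth: int = 4,
               min_samples_leaf: int = 3) -> TrainedClassifier:
    """Fit the binary tree separating class 1 from class 2 nuclei.

    Parameters
    ----------
    features : (n, 5) array in the order (area, mean, min, max, sd).
    classes : (n,) array of 1 (large uniform) or 2 (condensed bright).

    Training is deterministic given the data. Contradictory duplicated
    rows end in a majority-vote leaf. The PI threshold is left unset
    (``inf``: everything viable) until calibrated.
    """
    features = np.asarray(features, dtype=float)
    classes = np.asarray(classes, dtype=int)
    if features.ndim != 2 or features.shape[1] != len(FEATURE_COLUMNS):
        raise ValueError(f"features must be (n, {len(FEATURE_COLUMNS)})")
    present, counts = np.unique(classes, return_counts=True)
    if len(present) < 2:
        raise ValueError("training set must contain both classes")
    if counts.min() < 5:
        raise ValueError("need at least 5 rows per class")
    if not np.all(np.isfinite(features)):
        raise ValueError("features must be finite")

    est = DecisionTreeClassifier(max_depth=max_depth,
                                 min_samples_leaf=min_samples_leaf,
                                 random_state=0)
    est.fit(features, classes)
    t = est.tree_
    # majority class per node in the estimator's class order
    leaf_class = est.classes_[np.argmax(t.value[:, 0, :], axis=1)]
    return TrainedClassifier(
        children_left=t.children_left.copy(),
        children_right=t.children_right.copy(),
        feature=t.feature.copy(),
        threshold=t.threshold.copy(),
        leaf_class=leaf_class.astype(int),
    )


def calibrate_pi_threshold(detections: list[NucleusDetection],
                           k: float = 5.0) -> PiCalibration:
    """PI threshold from calibration images containing PI-negative cells.

    Otsu's criterion partitions the per-nucleus mean PI intensities; if
    the two groups are well separated (means at least twice the sum of
    the group SDs apart, at least 3 nuclei each) the distribution is
    considered bimodal and the threshold is placed midway between the
    group means — with widely separated populations the Otsu objective is
    nearly flat between them and its discrete argmax can sit on a
    cluster's tail, so the midpoint is the stable choice. Otherwise the
    controls are treated as all-negative and the threshold falls back to
    mean + k*SD.
    """
    if not detections:
        raise ValueError("empty calibration set")
    vals = np.array([d.pi_mean for d in detections], dtype=float)
    if vals.max() > vals.min():
        cut = float(threshold_otsu(vals))
        lo, hi = vals[vals <= cut], vals[vals > cut]
        if lo.size >= 3 and hi.size >= 3:
            sep = (hi.mean() - lo.mean()) / max(lo.std() + hi.std(), 1e-12)
            if sep >= 2.0:
                return PiCalibration(
                    threshold=float((lo.mean() + hi.mean()) / 2.0),
                    method="otsu")
    return PiCalibration(threshold=float(vals.mean() + k * vals.std()),
                         method="mean_plus_k_sd")


def classify_frame(detection: NucleusDetection | None,
                   model: TrainedClassifier) -> CellState | None:
    """One nucleus, one frame -> state (None = UNKNOWN for gap/extended).

    Condensed (class 2) nuclei are apoptotic regardless of PI; large
    uniform (class 1) nuclei are viable below the PI threshold, necrotic
    above it.
    """
    if detection is None:
        return None
    if model.predict_class(detection.features) == CLASS2_CONDENSED:
        return CellState.APOPTOTIC
    if detection.pi_mean > model.pi_threshold:
        return CellState.NECROTIC
    return CellState.VIABLE


def validate_sequence(raw_states: list[CellState | None],
                      allowed: np.ndarray = FEASIBLE_TRANSITIONS,
                      ) -> tuple[list[CellState], int]:
    """Minimum-discrepancy feasible state sequence by dynamic programming.

    Finds the sequence obeying the feasibility graph that disagrees with
    the fewest known raw labels; UNKNOWN (None) frames cost nothing and
    inherit the optimal path's state. Among minimum-discrepancy sequences
    the reconstruction prefers, per frame going forward, the state that
    matches the raw label, then the earliest state in the death ordering
    (so transitions happen as late as the evidence allows).

    Returns ``(validated_states, n_corrections)`` where n_corrections is
    the number of known raw labels that were overruled.
    """
    n = len(raw_states)
    if n == 0:
        raise ValueError("empty sequence")
    n_states = allowed.shape[0]

    def cost(t: int, s: int) -> int:
        r = raw_states[t]
        return 0 if r is None or int(r) == s else 1

    # cost-to-go
    v = np.zeros((n, n_states), dtype=int)
    for s in range(n_states):
        v[n - 1, s] = cost(n - 1, s)
    for t in range(n - 2, -1, -1):
        for s in range(n_states):
            nxt = [v[t + 1, s2] for s2 in range(n_states) if allowed[s, s2]]
            v[t, s] = cost(t, s) + min(nxt)

    def pick(candidates: list[int], t: int, values: np.ndarray) -> int:
        best = min(values[c] for c in candidates)
        opts = [c for c in candidates if values[c] == best]
        r = raw_states[t]
        if r is not None and int(r) in opts:
            return int(r)
        return opts[0]  # earliest state: transitions as late as possible

    states: list[int] = [pick(list(range(n_states)), 0, v[0])]
    for t in range(1, n):
        cands = [s2 for s2 in range(n_states) if allowed[states[-1], s2]]
        states.append(pick(cands, t, v[t]))

    n_corr = sum(1 for t, s in enumerate(states)
                 if raw_states[t] is not None and int(raw_states[t]) != s)
    return [CellState(s) for s in states], n_corr


def _greedy_pass(raw_states: list[CellState | None], allowed: np.ndarray,
                 forward: bool) -> tuple[list[CellState], int]:
    n = len(raw_states)
    idx = range(n) if forward else range(n - 1, -1, -1)
    seq: list[int | None] = [None] * n
    cur: int | None = None
    for t in idx:
        r = raw_states[t]
        if cur is None:
            cur = int(r) if r is not None else None
        elif r is not None:
            ok = allowed[cur, int(r)] if forward else allowed[int(r), cur]
            if ok:
                cur = int(r)
        seq[t] = cur
    if all(s is None for s in seq):
        out = [int(CellState.VIABLE)] * n
    elif forward:  # unknowns only at the head: inherit the first known state
        first = next(s for s in seq if s is not None)
        out = [first if s is None else s for s in seq]
    else:  # unknowns only at the tail: inherit the last known state
        last = next(s for s in reversed(seq) if s is not None)
        out = [last if s is None else s for s in seq]
    n_corr = sum(1 for t in range(n)
                 if raw_states[t] is not None and int(raw_states[t]) != out[t])
    return [CellState(s) for s in out], n_corr


def validate_sequence_two_pass(raw_states: list[CellState | None],
                               allowed: np.ndarray = FEASIBLE_TRANSITIONS,
                               ) -> tuple[list[CellState], int]:
    """Heuristic forward/backward correction, keeping the lower-discrepancy
    pass (forward wins ties). Kept as an optional alternative to the exact
    dynamic program."""
    if len(raw_states) == 0:
        raise ValueError("empty sequence")
    fwd, cf = _greedy_pass(raw_states, allowed, forward=True)
    bwd, cb = _greedy_pass(raw_states, allowed, forward=False)
    return (fwd, cf) if cf <= cb else (bwd, cb)


@dataclass
class StateSequence:
    """Per-frame raw and validated states of one track."""

    track_id: int
    raw_states: list[CellState | None]
    validated_states: list[CellState] = field(default_factory=list)
    n_corrections: int = 0


def classify_track(track: Track, model: TrainedClassifier,
                   allowed: np.ndarray = FEASIBLE_TRANSITIONS,
                   validation: str = "dp") -> StateSequence:
    """Raw per-frame states of a track plus feasibility-validated states."""
    raw = [classify_frame(r.detection if r.kind == RecordKind.DETECTION
                          else None, model)
           for r in track.records]
    validate = (validate_sequence if validation == "dp"
                else validate_sequence_two_pass)
    validated, n_corr = validate(raw, allowed)
    return StateSequence(track_id=track.track_id, raw_states=raw,
                         validated_states=validated, n_corrections=n_corr)


def classify_tracks(tracks: list[Track], model: TrainedClassifier,
                    allowed: np.ndarray = FEASIBLE_TRANSITIONS,
                    validation: str = "dp") -> list[StateSequence]:
    return [classify_track(tr, model, allowed, validation) for tr in tracks]
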