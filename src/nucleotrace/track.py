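"""Linking per-frame detections into cell tracks.

Frame-to-frame linking is solved as a rectangular linear assignment
problem (LAP) over squared centroid displacements with a hard distance
gate and birth/death alternatives, the standard formulation for
particle-tracking of this kind. Fragments are then joined across
detection gaps of up to ``max_gap_frames`` frames, merge/split events of
clumped nuclei are recorded as lineage, and tracks that do not span the
whole movie are padded with EXTENDED records so classification can
propagate states to the start/end of the experiment.

Intensity and area terms are deliberately excluded from the linking cost:
intensity changes are the phenotype signal the classifier reads, so using
them for linking would bias tracking against dying cells.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .types import NucleusDetection

_BIG = 1e12


@dataclass
class TrackingParams:
    max_link_distance_px: float = 10.0
    max_gap_frames: int = 3
    allow_merge_split: bool = True
    min_track_length_frames: int = 3

    def __post_init__(self) -> None:
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")
        if self.max_link_distance_px <= 0:
            raise ValueError("max_link_distance_px must be positive")


class RecordKind(enum.Enum):
    DETECTION = "detection"
    GAP = "gap"
    EXTENDED = "extended"


@dataclass
class TrackRecord:
    frame_index: int
    kind: RecordKind
    detection: NucleusDetection | None = None


@dataclass
class LineageEvent:
    kind: str  # "merge" | "split"
    frame: int
    parent_ids: list[int]
    child_ids: list[int]


@dataclass
class Track:
    """A time-ordered chain of detections with gaps and extensions."""

    track_id: int
    records: list[TrackRecord] = field(default_factory=list)
    extended_head: bool = False
    extended_tail: bool = False
    parent_ids: list[int] = field(default_factory=list)
    child_ids: list[int] = field(default_factory=list)

    @property
    def detections(self) -> list[NucleusDetection]:
        return [r.detection for r in self.records
                if r.kind == RecordKind.DETECTION]

    @property
    def first_detection(self) -> TrackRecord:
        return next(r for r in self.records if r.kind == RecordKind.DETECTION)

    @property
    def last_detection(self) -> TrackRecord:
        return next(r for r in reversed(self.records)
                    if r.kind == RecordKind.DETECTION)

    def validate(self, max_gap_frames: int | None = None) -> None:
        """Assert structural invariants (strictly increasing frames, gap cap)."""
        frames = [r.frame_index for r in self.records]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise AssertionError("frame indices not strictly increasing")
        if max_gap_frames is not None:
            run = 0
            for r in self.records:
                run = run + 1 if r.kind == RecordKind.GAP else 0
                if run > max_gap_frames:
                    raise AssertionError("gap run exceeds max_gap_frames")


def link_frames(detections_t: list[NucleusDetection],
                detections_t1: list[NucleusDetection],
                params: TrackingParams,
                ) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Assign detections of frame t to frame t+1.

    Minimises total squared centroid displacement over one-to-one pairs
    within ``max_link_distance_px``; unmatched detections become track
    ends (frame t) or starts (frame t+1). Birth/death alternatives cost
    the squared gate, the standard LAP construction.

    Returns ``(links, unmatched_t, unmatched_t1)`` with ``links`` as
    (index in t, index in t+1) pairs.
    """
    n, m = len(detections_t), len(detections_t1)
    if n == 0 or m == 0:
        return [], list(range(n)), list(range(m))
    a = np.array([d.centroid for d in detections_t])
    b = np.array([d.centroid for d in detections_t1])
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    gate2 = params.max_link_distance_px ** 2
    cost = np.where(d2 <= gate2, d2, _BIG)

    # Jaqaman-style augmented matrix: [[cost, death], [birth, cost.T]]
    full = np.full((n + m, n + m), _BIG)
    full[:n, :m] = cost
    full[n:, m:] = np.minimum(cost.T, gate2)  # auxiliary block
    for i in range(n):
        full[i, m + i] = gate2  # death of detection i
    for j in range(m):
        full[n + j, j] = gate2  # birth of detection j
    rows, cols = linear_sum_assignment(full)

    links: list[tuple[int, int]] = []
    matched_t: set[int] = set()
    matched_t1: set[int] = set()
    for r, c in zip(rows, cols):
        if r < n and c < m and cost[r, c] < _BIG:
            links.append((int(r), int(c)))
            matched_t.add(int(r))
            matched_t1.add(int(c))
    links.sort()
    return (links,
            [i for i in range(n) if i not in matched_t],
            [j for j in range(m) if j not in matched_t1])


def build_fragments(detections_by_frame: list[list[NucleusDetection]],
                    params: TrackingParams) -> list[Track]:
    """Chain frame-to-frame links into gapless track fragments."""
    fragments: list[Track] = []
    active: dict[int, Track] = {}  # index in current frame -> fragment
    for t, dets in enumerate(detections_by_frame):
        if t == 0:
            for i, d in enumerate(dets):
                fr = Track(track_id=len(fragments))
                fr.records.append(TrackRecord(t, RecordKind.DETECTION, d))
                fragments.append(fr)
                active[i] = fr
            continue
        links, _, starts = link_frames(detections_by_frame[t - 1], dets,
                                       params)
        new_active: dict[int, Track] = {}
        for i, j in links:
            fr = active[i]
            fr.records.append(TrackRecord(t, RecordKind.DETECTION, dets[j]))
            new_active[j] = fr
        for j in starts:
            fr = Track(track_id=len(fragments))
            fr.records.append(TrackRecord(t, RecordKind.DETECTION, dets[j]))
            fragments.append(fr)
            new_active[j] = fr
        active = new_active
    return fragments


def close_gaps(fragments: list[Track], params: TrackingParams,
               ) -> tuple[list[Track], list[Track]]:
    """Join fragments across detection gaps of 1..max_gap_frames frames.

    A fragment ending at frame t joins one starting at t+g+1 when
    g <= max_gap_frames and the end-to-start distance is within
    ``max_link_distance_px * (g + 1)`` (the search radius grows linearly
    with the gap, a diffusive drift bound). Candidate joins are applied
    in order of increasing distance (ties: lowest fragment ids). Chains
    are then assembled with explicit GAP records; tracks with fewer
    detections than ``min_track_length_frames`` are discarded.

    Returns ``(tracks, discarded)``.
    """
    n = len(fragments)
    ends = [fr.last_detection for fr in fragments]
    starts = [fr.first_detection for fr in fragments]
    cands: list[tuple[float, int, int, int]] = []
    for i in range(n):
        e = ends[i]
        for j in range(n):
            if i == j:
                continue
            s = starts[j]
            g = s.frame_index - e.frame_index - 1
            if not 1 <= g <= params.max_gap_frames:
                continue
            dist = float(np.hypot(
                e.detection.centroid[0] - s.detection.centroid[0],
                e.detection.centroid[1] - s.detection.centroid[1]))
            if dist <= params.max_link_distance_px * (g + 1):
                cands.append((dist, i, j, g))
    cands.sort()

    nxt = [-1] * n
    prv = [-1] * n
    for dist, i, j, g in cands:
        if nxt[i] == -1 and prv[j] == -1:
            nxt[i] = j
            prv[j] = i

    tracks: list[Track] = []
    discarded: list[Track] = []
    for i in range(n):
        if prv[i] != -1:
            continue  # not a chain head
        records: list[TrackRecord] = []
        k = i
        while k != -1:
            if records:
                for gf in range(records[-1].frame_index + 1,
                                fragments[k].records[0].frame_index):
                    records.append(TrackRecord(gf, RecordKind.GAP))
            records.extend(fragments[k].records)
            k = nxt[k]
        tr = Track(track_id=len(tracks) + len(discarded), records=records)
        n_det = sum(1 for r in records if r.kind == RecordKind.DETECTION)
        (tracks if n_det >= params.min_track_length_frames
         else discarded).append(tr)
    for new_id, tr in enumerate(tracks):
        tr.track_id = new_id
    return tracks, discarded


def merge_split(tracks: list[Track],
                params: TrackingParams) -> list[LineageEvent]:
    """Record merge/split lineage between adjacent-frame track ends/starts.

    A track ending at frame t whose endpoint lies within the link gate of
    another track's detection at t+1 merges into that track
    (under-segmentation: two nuclei, one mask). A track starting at frame
    t near another track's detection at t-1 splits from it
    (over-segmentation resolving, or a clump separating). Measurements
    are never combined across merged identities; only lineage is stored.
    """
    if not params.allow_merge_split:
        return []
    events: list[LineageEvent] = []
    by_frame: dict[int, list[tuple[Track, NucleusDetection]]] = {}
    for tr in tracks:
        for r in tr.records:
            if r.kind == RecordKind.DETECTION:
                by_frame.setdefault(r.frame_index, []).append((tr, r.detection))

    gate = params.max_link_distance_px
    for tr in sorted(tracks, key=lambda t: t.track_id):
        end = tr.last_detection
        t1 = end.frame_index + 1
        frames_present = {r.frame_index for r in tr.records
                          if r.kind == RecordKind.DETECTION}
        best = None
        for other, det in by_frame.get(t1, []):
            if other.track_id == tr.track_id:
                continue
            other_frames = {r.frame_index for r in other.records
                            if r.kind == RecordKind.DETECTION}
            if end.frame_index not in other_frames:
                continue  # partner must continue through the merge
            dist = float(np.hypot(
                end.detection.centroid[0] - det.centroid[0],
                end.detection.centroid[1] - det.centroid[1]))
            if dist <= gate and (best is None or dist < best[0]):
                best = (dist, other)
        if best is not None:
            other = best[1]
            events.append(LineageEvent("merge", t1,
                                       [tr.track_id, other.track_id],
                                       [other.track_id]))
            tr.child_ids.append(other.track_id)

        start = tr.first_detection
        t0 = start.frame_index - 1
        if t0 < 0:
            continue
        best = None
        for other, det in by_frame.get(t0, []):
            if other.track_id == tr.track_id:
                continue
            other_frames = {r.frame_index for r in other.records
                            if r.kind == RecordKind.DETECTION}
            if start.frame_index not in other_frames:
                continue
            dist = float(np.hypot(
                start.detection.centroid[0] - det.centroid[0],
                start.detection.centroid[1] - det.centroid[1]))
            if dist <= gate and (best is None or dist < best[0]):
                best = (dist, other)
        if best is not None:
            other = best[1]
            events.append(LineageEvent("split", start.frame_index,
                                       [other.track_id],
                                       [other.track_id, tr.track_id]))
            tr.parent_ids.append(other.track_id)
    return events


def extend_tracks(tracks: list[Track], n_frames: int) -> list[Track]:
    """Pad tracks to the full movie with measurement-free EXTENDED records.

    Objects appearing late or disappearing early (typically after death)
    still get a state for every frame: classification later fills the
    EXTENDED records by feasible-state propagation.
    """
    for tr in tracks:
        first = tr.records[0].frame_index
        last = tr.records[-1].frame_index
        if first > 0:
            head = [TrackRecord(f, RecordKind.EXTENDED)
                    for f in range(first)]
            tr.records = head + tr.records
            tr.extended_head = True
        if last < n_frames - 1:
            tail = [TrackRecord(f, RecordKind.EXTENDED)
                    for f in range(last + 1, n_frames)]
            tr.records = tr.records + tail
            tr.extended_tail = True
    return tracks


def track_detections(detections_by_frame: list[list[NucleusDetection]],
                     params: TrackingParams | None = None,
                     ) -> tuple[list[Track], list[Track], list[LineageEvent]]:
    """Full tracking pipeline: link, close gaps, lineage, extend.

    Returns ``(tracks, discarded_fragments, lineage_events)``.
    """
    params = params or TrackingParams()
    n_frames = len(detections_by_frame)
    fragments = build_fragments(detections_by_frame, params)
    tracks, discarded = close_gaps(fragments, params)
    events = merge_split(tracks, params)
    extend_tracks(tracks, n_frames)
    for tr in tracks:
        tr.validate(params.max_gap_frames)
    return tracks, discarded, events
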