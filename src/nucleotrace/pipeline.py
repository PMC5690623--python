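"""End-to-end orchestration and ground-truth evaluation.

Chains the stages (render/load -> illumination correction -> segmentation
-> tracking -> classification -> well summary) and provides the
evaluation helpers that score each stage against a synthetic scene's
ground truth: detection precision/recall, track purity, per-frame state
accuracy and population-fraction error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import classify as cls
from . import preprocess, segment
from .report import WellSummary, summarize_well
from .synthetic import CellSpec, GroundTruth, SceneConfig, render_frame, sample_scene
from .track import LineageEvent, RecordKind, Track, TrackingParams, track_detections
from .types import CellState, Channel, NucleusDetection


@dataclass
class PipelineResult:
    detections_by_frame: list[list[NucleusDetection]]
    tracks: list[Track]
    discarded: list[Track]
    lineage: list[LineageEvent]
    sequences: list[cls.StateSequence]
    summary: WellSummary
    model: cls.TrainedClassifier


def segment_stacks(hoechst: list, pi: list,
                   params: segment.ChannelSegParams = segment.HOECHST_PARAMS,
                   block_size: int = preprocess.DEFAULT_BLOCK_SIZE,
                   ) -> list[list[NucleusDetection]]:
    """Correct both channels frame by frame and segment the Hoechst one."""
    out = []
    for h, p in zip(hoechst, pi):
        hc = preprocess.correct_frame(h, block_size)
        pc = preprocess.correct_frame(p, block_size)
        _, dets = segment.segment_frame(hc, pc, params)
        out.append(dets)
    return out


def segment_scene(cells: list[CellSpec], config: SceneConfig,
                  frames: list[int] | None = None,
                  params: segment.ChannelSegParams = segment.HOECHST_PARAMS,
                  ) -> list[list[NucleusDetection]]:
    """Render, correct and segment the given frames of a synthetic scene."""
    frames = list(range(config.n_frames)) if frames is None else frames
    hoechst = [render_frame(cells, t, config, Channel.HOECHST) for t in frames]
    pi = [render_frame(cells, t, config, Channel.PI) for t in frames]
    return segment_stacks(hoechst, pi, params)


def match_detections(dets: list[NucleusDetection], cells: list[CellSpec],
                     frame: int) -> dict[int, int]:
    """Greedy one-to-one matching detection -> cell_id.

    A detection matches the nearest unmatched visible cell whose true
    centroid lies within that cell's radius.
    """
    vis = [c for c in cells if c.visible_at(frame)]
    if not vis or not dets:
        return {}
    pos = np.array([c.trajectory[frame] for c in vis])
    cents = np.array([d.centroid for d in dets])
    dist = np.hypot(pos[:, None, 0] - cents[None, :, 0],
                    pos[:, None, 1] - cents[None, :, 1])
    radii = np.array([c.radius_px for c in vis])
    pairs = [(dist[i, j], i, j) for i in range(len(vis))
             for j in range(len(dets)) if dist[i, j] <= radii[i]]
    pairs.sort()
    used_c: set[int] = set()
    used_d: set[int] = set()
    match: dict[int, int] = {}
    for d_, i, j in pairs:
        if i in used_c or j in used_d:
            continue
        match[j] = vis[i].cell_id
        used_c.add(i)
        used_d.add(j)
    return match


def segmentation_scores(cells: list[CellSpec], config: SceneConfig,
                        detections_by_frame: list[list[NucleusDetection]],
                        frames: list[int] | None = None,
                        ) -> tuple[float, float]:
    """(precision, recall) of detections against visible ground-truth cells,
    pooled over frames; a match requires the true centroid within one cell
    radius of the detection centroid."""
    frames = list(range(len(detections_by_frame))) if frames is None else frames
    tp = n_det = n_vis = 0
    for k, t in enumerate(frames):
        dets = detections_by_frame[k]
        m = match_detections(dets, cells, t)
        tp += len(m)
        n_det += len(dets)
        n_vis += sum(1 for c in cells if c.visible_at(t))
    precision = tp / n_det if n_det else 1.0
    recall = tp / n_vis if n_vis else 1.0
    return precision, recall


def make_training_data(config: SceneConfig, frames: list[int] | None = None,
                       ) -> tuple[np.ndarray, np.ndarray,
                                  list[NucleusDetection]]:
    """Expert-labelled training table from a synthetic calibration scene.

    Features are measured by the real segmentation path; labels come from
    the generator's state schedules (class 2 = condensed/apoptotic,
    class 1 = large uniform, i.e. viable or necrotic), standing in for
    the human expert's annotations.
    """
    cells, _ = sample_scene(config)
    frames = frames if frames is not None else list(
        range(0, config.n_frames, max(1, config.n_frames // 8)))
    feats, labels, all_dets = [], [], []
    for k, t in enumerate(frames):
        dets = segment_scene(cells, config, [t])[0]
        match = match_detections(dets, cells, t)
        for j, d in enumerate(dets):
            all_dets.append(d)
            if j not in match:
                continue
            state = cells[match[j]].state_at(t)
            feats.append(d.features)
            labels.append(cls.CLASS2_CONDENSED
                          if state == CellState.APOPTOTIC
                          else cls.CLASS1_LARGE_UNIFORM)
    return np.array(feats), np.array(labels), all_dets


def train_model(config: SceneConfig | None = None, max_depth: int = 4,
                ) -> cls.TrainedClassifier:
    """Train tree + calibrate PI threshold on a dedicated calibration scene."""
    config = config or SceneConfig(rng_seed=20_000)
    feats, labels, dets = make_training_data(config)
    model = cls.train_tree(feats, labels, max_depth=max_depth)
    model.pi_threshold = cls.calibrate_pi_threshold(dets).threshold
    return model


def run_pipeline(cells: list[CellSpec], config: SceneConfig,
                 model: cls.TrainedClassifier,
                 tracking: TrackingParams | None = None,
                 seg_params: segment.ChannelSegParams = segment.HOECHST_PARAMS,
                 well_id: str = "A1",
                 validation: str = "dp") -> PipelineResult:
    """Full analysis of one rendered scene with a pre-trained model."""
    detections = segment_scene(cells, config, None, seg_params)
    tracks, discarded, events = track_detections(detections, tracking)
    sequences = cls.classify_tracks(tracks, model, validation=validation)
    summary = summarize_well(sequences, well_id=well_id)
    return PipelineResult(detections, tracks, discarded, events, sequences,
                          summary, model)


# ---------------------------------------------------------------------------
# ground-truth scoring


def track_to_cell(track: Track, cells: list[CellSpec],
                  config: SceneConfig) -> tuple[int | None, float]:
    """Majority ground-truth cell of a track and the track's purity
    (fraction of its detections attributed to that cell)."""
    votes: dict[int, int] = {}
    n_det = 0
    for r in track.records:
        if r.kind != RecordKind.DETECTION:
            continue
        n_det += 1
        m = match_detections([r.detection], cells, r.frame_index)
        if 0 in m:
            votes[m[0]] = votes.get(m[0], 0) + 1
    if not votes or n_det == 0:
        return None, 0.0
    best = max(sorted(votes), key=lambda k: votes[k])
    return best, votes[best] / n_det


def tracking_scores(tracks: list[Track], cells: list[CellSpec],
                    config: SceneConfig) -> dict[str, float]:
    """Mean track purity and the fraction of cells recovered as exactly
    one track."""
    purities = []
    owner: dict[int, int] = {}
    for tr in tracks:
        cid, purity = track_to_cell(tr, cells, config)
        purities.append(purity)
        if cid is not None:
            owner[cid] = owner.get(cid, 0) + 1
    one_track = sum(1 for c in cells if owner.get(c.cell_id, 0) == 1)
    return {
        "mean_purity": float(np.mean(purities)) if purities else 0.0,
        "frac_cells_one_track": one_track / len(cells) if cells else 1.0,
    }


def state_accuracy(sequences: list[cls.StateSequence], tracks: list[Track],
                   cells: list[CellSpec], config: SceneConfig,
                   ) -> dict[str, float]:
    """Per-frame 3-state accuracy pooled over tracks matched to ground truth.

    ``raw_accuracy`` and ``validated_accuracy_known`` are computed on the
    frames that have a raw label (the like-for-like before/after pair);
    ``validated_accuracy`` covers every frame, including gap/extended ones
    that only the validated sequence can label.
    """
    by_id = {tr.track_id: tr for tr in tracks}
    raw_ok = known_n = valk_ok = val_ok = val_n = 0
    for seq in sequences:
        cid, _ = track_to_cell(by_id[seq.track_id], cells, config)
        if cid is None:
            continue
        sched = cells[cid].state_schedule
        for t in range(len(seq.validated_states)):
            truth = int(sched[t])
            val_hit = int(int(seq.validated_states[t]) == truth)
            if seq.raw_states[t] is not None:
                known_n += 1
                raw_ok += int(int(seq.raw_states[t]) == truth)
                valk_ok += val_hit
            val_n += 1
            val_ok += val_hit
    return {
        "raw_accuracy": raw_ok / known_n if known_n else float("nan"),
        "validated_accuracy_known": valk_ok / known_n if known_n
        else float("nan"),
        "validated_accuracy": val_ok / val_n if val_n else float("nan"),
    }


def fraction_error(summary: WellSummary, truth: GroundTruth) -> float:
    """Max absolute error of reported vs true population fractions."""
    return float(np.max(np.abs(summary.fractions - truth.fractions)))
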