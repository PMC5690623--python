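"""Reading and writing the pipeline's on-disk formats.

Image stacks are plain multi-page TIFF (one page per frame); tabular
outputs are CSV with a commented header describing the coordinate
convention (0-based row/col). Track tables use the ``label`` column to
carry GAP/EXTENDED markers for measurement-free records.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .classify import StateSequence
from .track import LineageEvent, RecordKind, Track, TrackRecord
from .types import STATE_FROM_NAME, STATE_NAMES, Channel, ImagePlane, NucleusDetection

_COORD_COMMENT = "# coordinates are 0-based (row, col) pixel indices\n"

OBJECT_COLUMNS = ["well", "field", "frame", "label", "centroid_row",
                  "centroid_col", "area_px", "h_mean", "h_min", "h_max",
                  "h_sd", "pi_mean"]


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    # one grayscale page per frame (never RGB, whatever the frame count)
    tifffile.imwrite(str(path), np.asarray(stack), photometric="minisblack")


def read_stack(path: str | Path, channel: Channel = Channel.HOECHST,
               well_id: str = "A1", field_id: str = "f0",
               ) -> list[ImagePlane]:
    """Read a multi-frame TIFF into a list of ImagePlanes."""
    stack = tifffile.imread(str(path))
    if stack.ndim == 2:
        stack = stack[None]
    return [ImagePlane(pixels=stack[t], channel=channel, frame_index=t,
                       well_id=well_id, field_id=field_id)
            for t in range(stack.shape[0])]


def detections_to_frame(dets: list[NucleusDetection]) -> pd.DataFrame:
    return pd.DataFrame([{
        "well": d.well_id, "field": d.field_id, "frame": d.frame_index,
        "label": d.label, "centroid_row": d.centroid[0],
        "centroid_col": d.centroid[1], "area_px": d.area_px,
        "h_mean": d.hoechst_mean, "h_min": d.hoechst_min,
        "h_max": d.hoechst_max, "h_sd": d.hoechst_sd, "pi_mean": d.pi_mean,
    } for d in dets], columns=OBJECT_COLUMNS)


def frame_to_detections(df: pd.DataFrame) -> list[NucleusDetection]:
    return [NucleusDetection(
        label=int(r.label), frame_index=int(r.frame), channel=Channel.HOECHST,
        centroid=(float(r.centroid_row), float(r.centroid_col)),
        area_px=int(r.area_px), hoechst_mean=float(r.h_mean),
        hoechst_min=float(r.h_min), hoechst_max=float(r.h_max),
        hoechst_sd=float(r.h_sd), pi_mean=float(r.pi_mean),
        well_id=str(r.well), field_id=str(r.field),
    ) for r in df.itertuples()]


def write_objects_csv(path: str | Path, dets: list[NucleusDetection]) -> None:
    with open(path, "w") as fh:
        fh.write(_COORD_COMMENT)
        detections_to_frame(dets).to_csv(fh, index=False)


def read_objects_csv(path: str | Path) -> list[list[NucleusDetection]]:
    """Objects CSV -> detections grouped by frame (index = frame)."""
    df = pd.read_csv(path, comment="#")
    n_frames = int(df["frame"].max()) + 1 if len(df) else 0
    by_frame: list[list[NucleusDetection]] = [[] for _ in range(n_frames)]
    for det in frame_to_detections(df):
        by_frame[det.frame_index].append(det)
    return by_frame


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for r in tr.records:
            if r.kind == RecordKind.DETECTION:
                d = r.detection
                rows.append({
                    "track_id": tr.track_id, "frame": r.frame_index,
                    "label": d.label, "centroid_row": d.centroid[0],
                    "centroid_col": d.centroid[1], "area_px": d.area_px,
                    "h_mean": d.hoechst_mean, "h_min": d.hoechst_min,
                    "h_max": d.hoechst_max, "h_sd": d.hoechst_sd,
                    "pi_mean": d.pi_mean,
                })
            else:
                rows.append({"track_id": tr.track_id, "frame": r.frame_index,
                             "label": r.kind.value.upper()})
    return pd.DataFrame(rows)


def frame_to_tracks(df: pd.DataFrame) -> list[Track]:
    tracks: dict[int, Track] = {}
    for r in df.itertuples():
        tr = tracks.setdefault(int(r.track_id), Track(track_id=int(r.track_id)))
        if str(r.label) == "GAP":
            tr.records.append(TrackRecord(int(r.frame), RecordKind.GAP))
        elif str(r.label) == "EXTENDED":
            tr.records.append(TrackRecord(int(r.frame), RecordKind.EXTENDED))
        else:
            det = NucleusDetection(
                label=int(float(r.label)), frame_index=int(r.frame),
                channel=Channel.HOECHST,
                centroid=(float(r.centroid_row), float(r.centroid_col)),
                area_px=int(r.area_px), hoechst_mean=float(r.h_mean),
                hoechst_min=float(r.h_min), hoechst_max=float(r.h_max),
                hoechst_sd=float(r.h_sd), pi_mean=float(r.pi_mean))
            tr.records.append(TrackRecord(int(r.frame),
                                          RecordKind.DETECTION, det))
    out = []
    for tid in sorted(tracks):
        tr = tracks[tid]
        tr.records.sort(key=lambda rec: rec.frame_index)
        tr.extended_head = tr.records[0].kind == RecordKind.EXTENDED
        tr.extended_tail = tr.records[-1].kind == RecordKind.EXTENDED
        out.append(tr)
    return out


def write_tracks_csv(path: str | Path, tracks: list[Track]) -> None:
    with open(path, "w") as fh:
        fh.write(_COORD_COMMENT)
        tracks_to_frame(tracks).to_csv(fh, index=False)


def read_tracks_csv(path: str | Path) -> list[Track]:
    return frame_to_tracks(pd.read_csv(path, comment="#"))


def lineage_to_frame(events: list[LineageEvent]) -> pd.DataFrame:
    return pd.DataFrame([{
        "event": e.kind, "frame": e.frame,
        "parent_ids": ";".join(map(str, e.parent_ids)),
        "child_ids": ";".join(map(str, e.child_ids)),
    } for e in events], columns=["event", "frame", "parent_ids", "child_ids"])


def states_to_frame(sequences: list[StateSequence]) -> pd.DataFrame:
    rows = []
    for seq in sequences:
        for t, (raw, val) in enumerate(zip(seq.raw_states,
                                           seq.validated_states)):
            rows.append({
                "track_id": seq.track_id, "frame": t,
                "raw_state": "UNKNOWN" if raw is None else STATE_NAMES[raw],
                "validated_state": STATE_NAMES[val],
            })
    return pd.DataFrame(rows)


def frame_to_sequences(df: pd.DataFrame) -> list[StateSequence]:
    out = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        raw = [None if s == "UNKNOWN" else STATE_FROM_NAME[s]
               for s in grp["raw_state"]]
        val = [STATE_FROM_NAME[s] for s in grp["validated_state"]]
        n_corr = sum(1 for r, v in zip(raw, val)
                     if r is not None and r != v)
        out.append(StateSequence(track_id=int(tid), raw_states=raw,
                                 validated_states=val, n_corrections=n_corr))
    return out
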