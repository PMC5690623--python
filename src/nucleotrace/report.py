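"""Population summaries: well time-courses and per-condition statistics.

Aggregates validated per-track states into the percentages of viable,
apoptotic and necrotic cells per well over time (the quantity the assay
reports), then medians with inter-quartile bands across wells of the
same treatment, endpoint tables for boxplots, and condition heatmaps.
Significance testing is out of scope; summaries export tidy tables any
stats tool can consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import StateSequence
from .types import STATE_NAMES, CellState

STATE_ORDER = (CellState.VIABLE, CellState.APOPTOTIC, CellState.NECROTIC)


@dataclass
class WellSummary:
    well_id: str
    counts: np.ndarray  # (n_frames, 3) in STATE_ORDER
    n_tracks: int
    metadata: dict = field(default_factory=dict)

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.n_tracks

    @property
    def n_frames(self) -> int:
        return self.counts.shape[0]


@dataclass
class ConditionSummary:
    label: str
    median: np.ndarray  # (n_frames, 3)
    q25: np.ndarray
    q75: np.ndarray
    endpoint: np.ndarray  # (n_wells, 3) final-frame fractions
    well_ids: list[str]


def summarize_well(sequences: list[StateSequence], well_id: str = "A1",
                   metadata: dict | None = None) -> WellSummary:
    """Per-frame state counts/fractions for one well.

    The denominator is the number of tracks (constant across frames:
    extension makes every track full-length), so fractions always sum
    to 1.
    """
    if not sequences:
        raise ValueError("no tracks in well")
    n_frames = len(sequences[0].validated_states)
    counts = np.zeros((n_frames, 3), dtype=int)
    for seq in sequences:
        if len(seq.validated_states) != n_frames:
            raise ValueError("tracks have inconsistent lengths")
        for t, s in enumerate(seq.validated_states):
            counts[t, int(s)] += 1
    return WellSummary(well_id=well_id, counts=counts,
                       n_tracks=len(sequences), metadata=metadata or {})


def summarize_condition(wells: list[WellSummary],
                        label: str = "") -> ConditionSummary:
    """Median and quartiles across wells of one treatment."""
    if not wells:
        raise ValueError("no wells")
    fr = np.stack([w.fractions for w in wells])  # (n_wells, n_frames, 3)
    return ConditionSummary(
        label=label,
        median=np.median(fr, axis=0),
        q25=np.percentile(fr, 25, axis=0),
        q75=np.percentile(fr, 75, axis=0),
        endpoint=fr[:, -1, :].copy(),
        well_ids=[w.well_id for w in wells],
    )


def well_summary_frame(wells: list[WellSummary]) -> pd.DataFrame:
    """Tidy per-well table: one row per (well, frame, state)."""
    rows = []
    for w in wells:
        fr = w.fractions
        for t in range(w.n_frames):
            for s in STATE_ORDER:
                rows.append({
                    "well_id": w.well_id,
                    "frame": t,
                    "state": STATE_NAMES[s],
                    "count": int(w.counts[t, int(s)]),
                    "fraction": fr[t, int(s)],
                    "n_tracks": w.n_tracks,
                    **w.metadata,
                })
    return pd.DataFrame(rows)


def condition_summary_frame(conds: list[ConditionSummary]) -> pd.DataFrame:
    rows = []
    for c in conds:
        n_frames = c.median.shape[0]
        for t in range(n_frames):
            for s in STATE_ORDER:
                rows.append({
                    "condition": c.label,
                    "frame": t,
                    "state": STATE_NAMES[s],
                    "median": c.median[t, int(s)],
                    "q25": c.q25[t, int(s)],
                    "q75": c.q75[t, int(s)],
                })
    return pd.DataFrame(rows)


_STATE_COLORS = {"viable": "tab:blue", "apoptotic": "tab:green",
                 "necrotic": "tab:red"}


def plot_timecourse(cond: ConditionSummary, ax=None):
    """Median traces with shaded inter-quartile bands, one per state."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    frames = np.arange(cond.median.shape[0])
    for s in STATE_ORDER:
        name = STATE_NAMES[s]
        ax.plot(frames, 100 * cond.median[:, int(s)],
                color=_STATE_COLORS[name], label=name)
        ax.fill_between(frames, 100 * cond.q25[:, int(s)],
                        100 * cond.q75[:, int(s)],
                        color=_STATE_COLORS[name], alpha=0.25, lw=0)
    ax.set_xlabel("frame")
    ax.set_ylabel("population (%)")
    ax.set_ylim(0, 100)
    ax.set_title(cond.label)
    ax.legend()
    return ax


def plot_endpoint_box(conds: list[ConditionSummary], ax=None):
    """Endpoint (final-frame) per-well fractions as grouped boxplots."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    width = 0.25
    for k, s in enumerate(STATE_ORDER):
        name = STATE_NAMES[s]
        data = [100 * c.endpoint[:, int(s)] for c in conds]
        pos = np.arange(len(conds)) + (k - 1) * width
        bp = ax.boxplot(data, positions=pos, widths=width * 0.9,
                        patch_artist=True)
        for box in bp["boxes"]:
            box.set_facecolor(_STATE_COLORS[name])
    ax.set_xticks(np.arange(len(conds)))
    ax.set_xticklabels([c.label for c in conds], rotation=30, ha="right")
    ax.set_ylabel("endpoint population (%)")
    return ax


def plot_condition_heatmap(conds: list[ConditionSummary],
                           state: CellState = CellState.VIABLE, ax=None):
    """Condition x frame heatmap of the median fraction of one state."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mat = np.stack([100 * c.median[:, int(state)] for c in conds])
    im = ax.imshow(mat, aspect="auto", cmap="viridis", vmin=0, vmax=100)
    ax.set_yticks(range(len(conds)))
    ax.set_yticklabels([c.label for c in conds])
    ax.set_xlabel("frame")
    ax.figure.colorbar(im, ax=ax, label=f"median {STATE_NAMES[state]} (%)")
    return ax
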