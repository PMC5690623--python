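"""Synthetic two-channel time-lapse scenes with full ground truth.

Emulates the statistical structure of Hoechst/PI high-content-screening
movies of primary neurons: uniformly stained viable nuclei, condensed and
brighter apoptotic nuclei, PI-positive necrotic nuclei, a smooth uneven
background illumination field, photon/read noise, clumped adjacent nuclei,
small frame-to-frame drift, and transient detection dropouts. Every cell
carries a per-frame state schedule that only moves toward death, so the
generator doubles as the oracle for segmentation, tracking, classification
and population reporting.

Geometry convention: a nucleus of radius ``r`` is rendered as an isotropic
Gaussian blob with sigma = r/2, truncated at 2.5 sigma. Its ground-truth
mask is the full rendered support (the disk of radius 1.25 r), which is
what a threshold just above the noise floor recovers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import CellState, Channel, ImagePlane

#: blob support is truncated at this many sigma from the centre;
#: ground-truth masks are exactly this disk
BLOB_TRUNCATION_SIGMA = 2.5
#: apoptotic nuclei shrink to this fraction of their viable radius
#: (~half the area, keeping condensed nuclei above the 9 px detection gate)
CONDENSED_RADIUS_FACTOR = 0.75

_CHANNEL_CODE = {Channel.HOECHST: 0, Channel.PI: 1}


class SceneCapacityError(ValueError):
    """Requested cell count cannot be placed in the frame without overlap."""


@dataclass
class CellSpec:
    """Ground-truth description of one simulated cell."""

    cell_id: int
    trajectory: np.ndarray  # (n_frames, 2) sub-pixel (row, col)
    radius_px: float
    state_schedule: np.ndarray  # (n_frames,) CellState values
    hoechst_base: float
    condensation_factor: float = 2.0
    pi_gain: float = 3000.0
    dropout_frames: frozenset[int] = frozenset()

    def state_at(self, frame: int) -> CellState:
        return CellState(int(self.state_schedule[frame]))

    def visible_at(self, frame: int) -> bool:
        return frame not in self.dropout_frames


@dataclass
class SceneConfig:
    """Parameters of one simulated field of view.

    Defaults emulate the reference acquisition at desk scale: 25 frames
    (24 h at 1 h intervals), 256x256 px fields (the instrument acquired
    1024x1024, available by setting ``frame_shape``), nuclei whose
    segmented diameters fall inside the 9-20 px Hoechst size gate, and a
    smooth planar background ~10% of blob peak.
    """

    n_frames: int = 25
    frame_shape: tuple[int, int] = (256, 256)
    n_cells: int = 100
    radius_range: tuple[float, float] = (5.5, 7.5)
    anchor_pull: float = 0.8  # AR(1) coefficient of the positional jitter
    hoechst_base_range: tuple[float, float] = (2500.0, 4000.0)
    pi_gain_range: tuple[float, float] = (2500.0, 4000.0)
    condensation_factor: float = 2.0
    background_offset: float = 200.0
    background_amplitude: float = 300.0
    pi_background_offset: float = 60.0
    pi_background_amplitude: float = 60.0
    noise_sd: float = 20.0
    #: per-cell per-frame multiplicative jitter (lognormal sigma) emulating
    #: focus drift and staining fluctuation: amplitude and apparent radius
    intensity_jitter_sd: float = 0.12
    radius_jitter_sd: float = 0.04
    clump_fraction: float = 0.1
    max_step: float = 2.0
    # fate mix: remaining mass stays viable
    apoptotic_fraction: float = 0.35
    necrotic_fraction: float = 0.25
    secondary_necrosis_fraction: float = 0.15
    dropout_fraction: float = 0.15
    max_dropout_run: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames <= 0 or self.n_cells < 0:
            raise ValueError("n_frames must be positive, n_cells non-negative")
        if self.radius_range[0] <= 0 or self.radius_range[0] > self.radius_range[1]:
            raise ValueError("invalid radius_range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.clump_fraction <= 1:
            raise ValueError("clump_fraction must lie in [0, 1]")
        if self.max_dropout_run < 1:
            raise ValueError("max_dropout_run must be >= 1")


@dataclass
class GroundTruth:
    """Oracle data for one scene: label masks, schedules, true fractions."""

    hoechst_masks: np.ndarray  # (n_frames, H, W) uint16, cell_id + 1
    pi_masks: np.ndarray
    state_schedules: dict[int, np.ndarray]  # cell_id -> (n_frames,)
    fractions: np.ndarray  # (n_frames, 3) viable/apoptotic/necrotic


def background_field(config: SceneConfig, channel: Channel) -> np.ndarray:
    """Analytic illumination field: a tilted plane.

    Returns ``offset + amplitude * (0.6 r/H + 0.4 c/W)`` so the field is
    smooth, strictly positive and known in closed form for tests.
    """
    h, w = config.frame_shape
    rows = np.arange(h)[:, None] / max(h - 1, 1)
    cols = np.arange(w)[None, :] / max(w - 1, 1)
    if channel == Channel.HOECHST:
        off, amp = config.background_offset, config.background_amplitude
    else:
        off, amp = config.pi_background_offset, config.pi_background_amplitude
    return off + amp * (0.6 * rows + 0.4 * cols)


def _place_centroids(config: SceneConfig, rng: np.random.Generator,
                     radii: np.ndarray) -> np.ndarray:
    """Initial centroids: jittered grid for free cells, satellites for clumps.

    ``clump_fraction`` is the fraction of cells that end up with a
    nearest neighbour closer than one of their own diameters; clumps are
    built as satellite/anchor pairs, so ``round(f*n/2)`` satellites give
    ``2*round(f*n/2)`` clumped cells (within one cell of f*n).
    """
    n = config.n_cells
    if n == 0:
        return np.zeros((0, 2))
    h, w = config.frame_shape
    rmax = float(radii.max())
    margin = rmax + 3.0
    jitter = 1.0
    n_pairs = int(round(config.clump_fraction * n / 2.0))
    n_free = n - n_pairs
    g = int(np.ceil(np.sqrt(n_free)))
    span_r, span_c = h - 2 * margin, w - 2 * margin
    spacing = min(span_r, span_c) / max(g, 1)
    if spacing < 2 * rmax + 2 * jitter + 1:
        raise SceneCapacityError(
            f"cannot place {n} cells of radius <= {rmax:.1f} in a "
            f"{h}x{w} frame without overlap"
        )
    # jittered grid, randomly subsampled and shuffled
    gr = margin + (np.arange(g) + 0.5) * span_r / g
    gc = margin + (np.arange(g) + 0.5) * span_c / g
    grid = np.array([(r, c) for r in gr for c in gc])
    idx = rng.permutation(len(grid))[:n_free]
    free = grid[idx] + rng.uniform(-jitter, jitter, size=(n_free, 2))

    pts = list(free)
    used: set[int] = set()
    for k in range(n_pairs):
        rs = radii[n_free + k]
        placed = False
        for a in rng.permutation(n_free):
            if int(a) in used:
                continue
            ra = radii[a]
            d = 2.0 * min(ra, rs) * rng.uniform(0.80, 0.95)
            others = np.array([p for j, p in enumerate(pts) if j != a])
            for _ in range(120):
                theta = rng.uniform(0, 2 * np.pi)
                cand = pts[a] + d * np.array([np.cos(theta), np.sin(theta)])
                if not (margin <= cand[0] <= h - margin
                        and margin <= cand[1] <= w - margin):
                    continue
                if len(others) == 0 or np.min(
                        np.hypot(*(others - cand).T)) >= 2 * rmax + 1:
                    pts.append(cand)
                    used.add(int(a))
                    placed = True
                    break
            if placed:
                break
        if not placed:
            raise SceneCapacityError("no room to place clumped cell")
    return np.asarray(pts)


def _sample_schedule(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """One per-cell state schedule, non-decreasing toward death."""
    n = config.n_frames
    sched = np.full(n, int(CellState.VIABLE))
    u = rng.uniform()
    if n < 4 or u >= config.apoptotic_fraction + config.necrotic_fraction:
        return sched
    onset = int(rng.integers(2, max(n - 1, 3)))
    if u < config.apoptotic_fraction:
        sched[onset:] = int(CellState.APOPTOTIC)
        if (rng.uniform() < config.secondary_necrosis_fraction
                and onset + 3 <= n - 1):
            t2 = int(rng.integers(onset + 3, n))
            sched[t2:] = int(CellState.NECROTIC)
    else:
        sched[onset:] = int(CellState.NECROTIC)
    return sched


def sample_scene(config: SceneConfig) -> tuple[list[CellSpec], GroundTruth]:
    """Draw a full scene: cell specs plus ground-truth masks and fractions.

    Deterministic for a fixed ``config.rng_seed``. Raises
    :class:`SceneCapacityError` when ``n_cells`` cannot fit in the frame.
    """
    rng = np.random.default_rng(config.rng_seed)
    n, t = config.n_cells, config.n_frames
    h, w = config.frame_shape

    radii = rng.uniform(*config.radius_range, size=n)
    start = _place_centroids(config, rng, radii)

    cells: list[CellSpec] = []
    margin = (radii.max() + 3.0) if n else 0.0
    for i in range(n):
        # adherent nuclei jiggle around an anchor point: mean-reverting
        # (AR(1)) positional jitter with hard-capped per-frame step length
        traj = np.empty((t, 2))
        traj[0] = start[i]
        jig = np.zeros(2)
        for f in range(1, t):
            eta = rng.uniform(-1, 1, size=2)
            nrm = np.hypot(*eta)
            eta = eta / (nrm if nrm else 1.0) * rng.uniform(
                0, 0.6 * config.max_step)
            new_jig = config.anchor_pull * jig + eta
            step = (start[i] + new_jig) - traj[f - 1]
            slen = np.hypot(*step)
            if slen > config.max_step:
                step *= config.max_step / slen
            traj[f] = traj[f - 1] + step
            jig = traj[f] - start[i]
        traj[:, 0] = np.clip(traj[:, 0], margin, h - margin)
        traj[:, 1] = np.clip(traj[:, 1], margin, w - margin)

        sched = _sample_schedule(config, rng)

        dropout: frozenset[int] = frozenset()
        if rng.uniform() < config.dropout_fraction and t >= 3:
            run = int(rng.integers(1, config.max_dropout_run + 1))
            run = min(run, t - 2)
            t0 = int(rng.integers(1, t - run))
            dropout = frozenset(range(t0, t0 + run))

        cells.append(CellSpec(
            cell_id=i,
            trajectory=traj,
            radius_px=float(radii[i]),
            state_schedule=sched,
            hoechst_base=float(rng.uniform(*config.hoechst_base_range)),
            condensation_factor=config.condensation_factor,
            pi_gain=float(rng.uniform(*config.pi_gain_range)),
            dropout_frames=dropout,
        ))

    truth = _build_ground_truth(cells, config)
    return cells, truth


def _rendered_radius(cell: CellSpec, frame: int) -> float:
    if cell.state_at(frame) == CellState.APOPTOTIC:
        return cell.radius_px * CONDENSED_RADIUS_FACTOR
    return cell.radius_px


def _frame_factors(config: SceneConfig, frame: int, channel: Channel,
                   n_cells: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell multiplicative (amplitude, radius) jitter for one frame.

    Deterministic given (seed, frame, channel); indexed by cell list
    position so rendering and ground-truth masks agree exactly.
    """
    rng = np.random.default_rng(
        [config.rng_seed, frame, _CHANNEL_CODE[channel], 101])
    amp = np.exp(rng.normal(0.0, config.intensity_jitter_sd, size=n_cells))
    rad = np.exp(rng.normal(0.0, config.radius_jitter_sd, size=n_cells))
    return amp, rad


def _truth_masks(cells: list[CellSpec], config: SceneConfig,
                 channel: Channel) -> np.ndarray:
    h, w = config.frame_shape
    masks = np.zeros((config.n_frames, h, w), dtype=np.uint16)
    for t in range(config.n_frames):
        _, rad_f = _frame_factors(config, t, channel, len(cells))
        # nearest-centre assignment where truth disks overlap
        dist = np.full((h, w), np.inf)
        for k, cell in enumerate(cells):
            if not cell.visible_at(t):
                continue
            state = cell.state_at(t)
            if channel == Channel.PI and state != CellState.NECROTIC:
                continue
            r_eff = _rendered_radius(cell, t) * rad_f[k]
            # truth mask = rendered support: sigma * truncation, sigma = r/2
            tr = (r_eff / 2.0) * BLOB_TRUNCATION_SIGMA
            cr, cc = cell.trajectory[t]
            r0, r1 = int(max(0, cr - tr - 1)), int(min(h, cr + tr + 2))
            c0, c1 = int(max(0, cc - tr - 1)), int(min(w, cc + tr + 2))
            rr, cc_ = np.mgrid[r0:r1, c0:c1]
            d = np.hypot(rr - cr, cc_ - cc)
            inside = d <= tr
            closer = inside & (d < dist[r0:r1, c0:c1])
            masks[t, r0:r1, c0:c1][closer] = cell.cell_id + 1
            dist[r0:r1, c0:c1][closer] = d[closer]
    return masks


def _build_ground_truth(cells: list[CellSpec], config: SceneConfig) -> GroundTruth:
    t = config.n_frames
    schedules = {c.cell_id: c.state_schedule.copy() for c in cells}
    if cells:
        states = np.stack([c.state_schedule for c in cells])  # (n_cells, t)
        fractions = np.stack(
            [(states == s).mean(axis=0) for s in (0, 1, 2)], axis=1)
    else:
        fractions = np.zeros((0, 3))
    return GroundTruth(
        hoechst_masks=_truth_masks(cells, config, Channel.HOECHST),
        pi_masks=_truth_masks(cells, config, Channel.PI),
        state_schedules=schedules,
        fractions=fractions,
    )


def _add_blob(canvas: np.ndarray, cr: float, cc: float, radius: float,
              amplitude: float) -> None:
    sigma = radius / 2.0
    ext = BLOB_TRUNCATION_SIGMA * sigma
    h, w = canvas.shape
    r0, r1 = int(max(0, cr - ext - 1)), int(min(h, cr + ext + 2))
    c0, c1 = int(max(0, cc - ext - 1)), int(min(w, cc + ext + 2))
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc_ = np.mgrid[r0:r1, c0:c1]
    d2 = (rr - cr) ** 2 + (cc_ - cc) ** 2
    blob = amplitude * np.exp(-d2 / (2.0 * sigma ** 2))
    blob[d2 > ext ** 2] = 0.0
    canvas[r0:r1, c0:c1] += blob


def render_frame(cells: list[CellSpec], frame_index: int, config: SceneConfig,
                 channel: Channel) -> ImagePlane:
    """Render one noisy frame of one channel.

    Visible cells are drawn as truncated Gaussian blobs (brightest in the
    centre, dim toward the edges). Apoptotic nuclei shrink by the
    condensation radius factor and brighten by ``condensation_factor`` in
    Hoechst; necrotic nuclei appear in PI at ``pi_gain`` from their first
    necrotic frame. The illumination field and Gaussian noise are added
    last; output is clipped to the unsigned 16-bit camera range.
    """
    if frame_index >= config.n_frames:
        raise ValueError("frame_index beyond configured n_frames")
    channel = Channel(channel)
    h, w = config.frame_shape
    canvas = np.zeros((h, w), dtype=float)
    amp_f, rad_f = _frame_factors(config, frame_index, channel, len(cells))
    for k, cell in enumerate(cells):
        if not cell.visible_at(frame_index):
            continue
        state = cell.state_at(frame_index)
        cr, cc = cell.trajectory[frame_index]
        radius = _rendered_radius(cell, frame_index) * rad_f[k]
        if channel == Channel.HOECHST:
            amp = cell.hoechst_base * amp_f[k]
            if state == CellState.APOPTOTIC:
                amp *= cell.condensation_factor
            _add_blob(canvas, cr, cc, radius, amp)
        else:
            if state == CellState.NECROTIC:
                _add_blob(canvas, cr, cc, radius, cell.pi_gain * amp_f[k])

    canvas += background_field(config, channel)
    if config.noise_sd > 0:
        noise_rng = np.random.default_rng(
            [config.rng_seed, frame_index, _CHANNEL_CODE[channel]])
        canvas += noise_rng.normal(0.0, config.noise_sd, size=canvas.shape)
    pixels = np.clip(np.rint(canvas), 0, 65535).astype(np.uint16)
    return ImagePlane(pixels=pixels, channel=channel, frame_index=frame_index)


def render_scene(cells: list[CellSpec], config: SceneConfig,
                 channel: Channel) -> np.ndarray:
    """Render the full (n_frames, H, W) uint16 stack of one channel."""
    return np.stack([
        render_frame(cells, t, config, channel).pixels
        for t in range(config.n_frames)
    ])
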