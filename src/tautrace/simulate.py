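"""Ground-truthed synthetic two-channel live-imaging experiments.

The simulator emulates the statistical and visual structure that the
downstream analysis assumes: biosensor-expressing neurons (soma disc plus
neurite segments in the reporter channel, a dim nucleus in the far-red
channel), stochastic per-cell aggregation-onset times driven by exponential
hazards that differ between lines and scale with lysate dose, distinct
aggregate morphology archetypes rendered after onset, an elevated death
hazard after onset, death rendered as a bright fragmented nuclear flash,
independent field-of-view exit (censoring), and Gaussian read noise.

All event clocks are piecewise-constant exponentials, so every downstream
estimate can be checked against closed forms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from .config import MORPHOLOGIES, SimulationConfig

CHANNEL_REPORTER = 0
CHANNEL_NUCLEAR = 1
CHANNEL_NAMES = ("reporter_yfp", "nuclear_far_red")

_SPRITE_HALF = 48  # half-size of the per-cell static sprite patch


# ----------------------------------------------------------------------
@dataclass
class TimeLapseStack:
    """A two-channel time-lapse of one imaging field (one well).

    ``pixels`` is ``T x 2 x H x W`` unsigned 16-bit; channel 0 is the
    aggregation reporter (YFP), channel 1 the far-red nuclear dye.
    ``t0_offset_h`` is the delay between seed addition and the first frame.
    """

    pixels: np.ndarray
    pixel_size_um: float
    frame_interval_h: float
    t0_offset_h: float
    well_id: str = "W00"
    channel_names: tuple[str, str] = CHANNEL_NAMES

    def __post_init__(self) -> None:
        if self.pixels.ndim != 4 or self.pixels.shape[1] != 2:
            raise ValueError("pixels must be T x 2 x H x W")
        if self.pixels.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if self.pixel_size_um <= 0 or self.frame_interval_h <= 0:
            raise ValueError("calibration must be strictly positive")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def frame_times_h(self) -> np.ndarray:
        """Frame acquisition times in hours post seed addition."""
        return self.t0_offset_h + np.arange(self.n_frames) * self.frame_interval_h

    # -- persistence ----------------------------------------------------
    def save_tiff(self, path) -> None:
        """Write a multi-page TIFF (T*C pages, C fastest) plus a JSON sidecar."""
        path = str(path)
        t, c, h, w = self.pixels.shape
        tifffile.imwrite(path, self.pixels.reshape(t * c, h, w))
        meta = {
            "well_id": self.well_id,
            "shape_tchw": [t, c, h, w],
            "page_order": "frame-major, channel interleaved",
            "channel_names": list(self.channel_names),
            "pixel_size_um": self.pixel_size_um,
            "frame_interval_h": self.frame_interval_h,
            "t0_offset_h": self.t0_offset_h,
        }
        with open(path + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load_tiff(cls, path) -> "TimeLapseStack":
        path = str(path)
        with open(path + ".json") as fh:
            meta = json.load(fh)
        pages = tifffile.imread(path)
        t, c, h, w = meta["shape_tchw"]
        return cls(
            pixels=pages.reshape(t, c, h, w),
            pixel_size_um=meta["pixel_size_um"],
            frame_interval_h=meta["frame_interval_h"],
            t0_offset_h=meta["t0_offset_h"],
            well_id=meta["well_id"],
            channel_names=tuple(meta["channel_names"]),
        )


@dataclass
class SimTruth:
    """Ground-truth event table and trajectories for a simulated experiment.

    ``cells`` has one row per simulated cell with continuous (pre-
    discretisation) event times in hours post seed addition; NaN marks an
    event that never occurs within the simulated horizon.  ``positions``
    maps well id to an ``(n_cells, T, 2)`` array of per-frame (x, y) pixel
    positions (NaN after field-of-view exit).
    """

    cells: pd.DataFrame
    positions: dict[str, np.ndarray]
    frame_interval_h: float
    t0_offset_h: float
    horizon_h: float

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)


# ----------------------------------------------------------------------
# event-time sampling

def _sample_cell_events(cfg: SimulationConfig, rng: np.random.Generator, n: int):
    """Sample (onset, death, exit, dissolve, morphology) for ``n`` cells.

    Onset ~ Exp(onset hazard).  Death follows a piecewise-constant hazard:
    the base rate before onset and base x multiplier afterwards (times an
    extra multiplier for the Ordered strain, modelling strain-dependent
    toxicity).  Exit is an independent exponential.  Times are continuous
    hours post seed addition.
    """
    inf = np.inf
    lam_on = cfg.onset_hazard_per_h
    onset = rng.exponential(1.0 / lam_on, n) if lam_on > 0 else np.full(n, inf)

    morph = np.asarray(
        [MORPHOLOGIES[i] for i in rng.choice(
            len(MORPHOLOGIES), size=n, p=list(cfg.morphology_mix)
        )],
        dtype=object,
    )

    lam_d0 = cfg.death_base_hazard_per_h
    lam_d1 = lam_d0 * cfg.death_post_onset_multiplier * np.where(
        morph == "Ordered", cfg.ordered_death_multiplier, 1.0
    )
    if lam_d0 > 0:
        pre = rng.exponential(1.0 / lam_d0, n)
        with np.errstate(divide="ignore"):
            scale = np.where(lam_d1 > 0, 1.0 / np.maximum(lam_d1, 1e-300), inf)
        post_extra = np.where(
            lam_d1 > 0, rng.exponential(1.0, n) * scale, inf
        )
        death = np.where(pre < onset, pre, onset + post_extra)
    else:
        death = np.full(n, inf)

    lam_x = cfg.exit_hazard_per_h
    exit_t = rng.exponential(1.0 / lam_x, n) if lam_x > 0 else np.full(n, inf)

    dissolve = np.full(n, inf)
    if cfg.transient_prob > 0:
        trans = rng.random(n) < cfg.transient_prob
        dwell = rng.exponential(cfg.transient_dwell_mean_h, n)
        dissolve = np.where(trans, onset + dwell, inf)
    return onset, death, exit_t, dissolve, morph


def simulate_event_table(
    cfg: SimulationConfig, n_cells: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Event-level simulation without image rendering.

    Samples the same per-cell clocks as :func:`simulate_experiment` and
    returns right-censored records discretised to the frame grid (columns
    as in :func:`truth_event_table`).  Useful for statistical calibration
    at sample sizes where rendering would be pointless.
    """
    n = n_cells if n_cells is not None else cfg.n_cells_per_well * cfg.n_wells
    rng = np.random.default_rng(cfg.rng_seed if rng is None else rng)
    onset, death, exit_t, dissolve, morph = _sample_cell_events(cfg, rng, n)
    dt, t0, hor = cfg.frame_interval_h, cfg.t0_offset_h, cfg.horizon_h

    def disc(t):
        f = np.ceil((np.asarray(t, float) - t0) / dt)
        return t0 + np.maximum(f, 0.0) * dt

    death = np.where(death <= hor, disc(death), np.inf)
    exit_t = np.where(exit_t <= hor, disc(exit_t), np.inf)
    onset_d = np.where(onset <= hor, disc(onset), np.inf)
    time = np.minimum(np.minimum(death, exit_t), hor)
    event = (death <= exit_t) & (death <= hor)
    onset_obs = np.where(onset_d <= time, onset_d, np.nan)
    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "line": cfg.line_label,
            "dose_ug": cfg.dose_ug,
            "time_h": time,
            "event": event,
            "onset_h": onset_obs,
            "morphology_label": np.where(np.isfinite(onset_obs), morph, None),
            "true_onset_h": np.where(onset <= hor, onset, np.nan),
        }
    )


# ----------------------------------------------------------------------
# rendering primitives

def _stamp(img: np.ndarray, x: float, y: float, amp: float, sigma: float,
           sigma_y: float | None = None, theta: float = 0.0) -> None:
    """Add an (optionally anisotropic, rotated) Gaussian blob in place."""
    if amp <= 0:
        return
    sy = sigma if sigma_y is None else sigma_y
    ext = int(np.ceil(3.0 * max(sigma, sy)))
    h, w = img.shape
    x0, x1 = int(np.floor(x)) - ext, int(np.floor(x)) + ext + 1
    y0, y1 = int(np.floor(y)) - ext, int(np.floor(y)) + ext + 1
    x0c, x1c = max(x0, 0), min(x1, w)
    y0c, y1c = max(y0, 0), min(y1, h)
    if x0c >= x1c or y0c >= y1c:
        return
    xs = np.arange(x0c, x1c) - x
    ys = np.arange(y0c, y1c) - y
    xx, yy = np.meshgrid(xs, ys)
    if theta != 0.0:
        c, s = np.cos(theta), np.sin(theta)
        xr = c * xx + s * yy
        yr = -s * xx + c * yy
    else:
        xr, yr = xx, yy
    img[y0c:y1c, x0c:x1c] += amp * np.exp(
        -0.5 * ((xr / sigma) ** 2 + (yr / sy) ** 2)
    )


def _add_patch(img: np.ndarray, patch: np.ndarray, cx: int, cy: int,
               scale: float = 1.0) -> None:
    """Add ``patch`` (centred at its midpoint) onto ``img`` at (cx, cy)."""
    ph, pw = patch.shape
    hy, hx = ph // 2, pw // 2
    h, w = img.shape
    y0, y1 = cy - hy, cy - hy + ph
    x0, x1 = cx - hx, cx - hx + pw
    sy0 = max(0, -y0)
    sx0 = max(0, -x0)
    y0c, x0c = max(y0, 0), max(x0, 0)
    y1c, x1c = min(y1, h), min(x1, w)
    if y0c >= y1c or x0c >= x1c:
        return
    img[y0c:y1c, x0c:x1c] += scale * patch[
        sy0 : sy0 + (y1c - y0c), sx0 : sx0 + (x1c - x0c)
    ]


class _CellGeometry:
    """Static per-cell appearance: sprites plus aggregate layout."""

    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator,
                 expression: float, morphology: str | None):
        size = 2 * _SPRITE_HALF + 1
        c = float(_SPRITE_HALF)
        self.reporter = np.zeros((size, size), np.float32)
        self.nuclear = np.zeros((size, size), np.float32)
        self.expression = expression

        _stamp(self.reporter, c, c, expression, 4.0)
        _stamp(self.nuclear, c, c, cfg.nuclear_amplitude_gray, 2.5)

        # neurite segments radiating from the soma
        self.neurites = []
        n_seg = rng.integers(2, 5)
        base_angle = rng.uniform(0, 2 * np.pi)
        for k in range(n_seg):
            ang = base_angle + k * 2 * np.pi / n_seg + rng.normal(0, 0.3)
            length = float(np.clip(rng.normal(26, 5), 16, 40))
            self.neurites.append((ang, length))
            for r in np.arange(4.0, length, 1.6):
                _stamp(
                    self.reporter,
                    c + r * np.cos(ang),
                    c + r * np.sin(ang),
                    cfg.neurite_amplitude_gray,
                    1.0,
                )
        self.neurite_mask = self.reporter - _gauss_peak_contrib(
            expression, 4.0, size
        ) > 0.5 * cfg.neurite_amplitude_gray

        # soma-aggregate archetype layout (offsets in the sprite frame);
        # all archetypes are confined to the soma (within ~6 px of centre)
        self.morphology = morphology
        amp = cfg.punctum_amplitude_gray
        self.soma_aggregate: list[tuple[float, float, float, float, float, float]] = []
        # entries: (dx, dy, amp, sigma_x, sigma_y, theta)
        if morphology == "Ordered":
            ang = rng.uniform(0, 2 * np.pi)
            self.ordered_offset = (4.0 * np.cos(ang), 4.0 * np.sin(ang))
        elif morphology == "Disordered":
            # six puncta on a jittered two-radius ring: spacing >= ~5.4 px
            # keeps the above-threshold footprints distinct components even
            # on top of the diffuse soma pedestal (overlapping wings plus
            # pedestal sum below the detection threshold)
            n_p = 6
            rot = rng.uniform(0, 2 * np.pi)
            for k in range(n_p):
                a = rot + k * 2 * np.pi / n_p + rng.uniform(-0.06, 0.06)
                r = (3.6 if k % 2 else 6.2) + rng.uniform(-0.15, 0.15)
                self.soma_aggregate.append(
                    (r * np.cos(a), r * np.sin(a), amp, 1.4, 1.4, 0.0)
                )
        elif morphology == "Speckles":
            for _ in range(4):
                r = rng.uniform(0.0, 2.0)
                a = rng.uniform(0, 2 * np.pi)
                self.soma_aggregate.append(
                    (r * np.cos(a), r * np.sin(a), amp, 1.4, 1.4, 0.0)
                )
        elif morphology == "Other":
            ang = rng.uniform(0, 2 * np.pi)
            for sgn in (-1.0, 1.0):
                # two lenticular blobs, major axes perpendicular to their
                # separation so they stay distinct components
                self.soma_aggregate.append(
                    (
                        sgn * 4.5 * np.cos(ang),
                        sgn * 4.5 * np.sin(ang),
                        amp,
                        2.5,
                        1.1,
                        ang + np.pi / 2,
                    )
                )

        # nuclear fragments rendered at death (bright, within the nucleus)
        self.fragments = []
        for a in rng.uniform(0, 2 * np.pi) + np.array([0.0, 2.1, 4.2]):
            self.fragments.append((2.8 * np.cos(a), 2.8 * np.sin(a)))

    def ordered_blob(self, frames_since_onset: int, amp: float):
        """Growing-then-compacting single condensation (Ordered archetype)."""
        k = frames_since_onset
        if k < 6:
            sigma = 1.5 + (2.4 - 1.5) * k / 6.0
            a = amp
        else:
            sigma = 2.4 * 0.99 ** (k - 6)  # area shrinks ~2%/frame
            a = min(amp * (1.0 + 0.01 * (k - 6)), 1.6 * amp)
        dx, dy = self.ordered_offset
        return dx, dy, a, sigma


def _gauss_peak_contrib(amp: float, sigma: float, size: int) -> np.ndarray:
    c = size // 2
    xs = np.arange(size) - c
    xx, yy = np.meshgrid(xs, xs)
    return amp * np.exp(-0.5 * (xx**2 + yy**2) / sigma**2)


# ----------------------------------------------------------------------
def _simulate_well(cfg: SimulationConfig, rng: np.random.Generator,
                   well_id: str, first_cell_id: int):
    """Simulate and render one well; returns (stack, cells_df, positions)."""
    n = cfg.n_cells_per_well
    T = cfg.frames
    H = W = cfg.image_size_px
    dt = cfg.frame_interval_h
    frame_times = cfg.t0_offset_h + np.arange(T) * dt

    onset, death, exit_t, dissolve, morph_labels = _sample_cell_events(cfg, rng, n)

    margin = min(25, H // 4)
    min_sep = 24.0  # tracked neurons are individually identifiable
    pos_list: list[np.ndarray] = []
    attempts = 0
    while len(pos_list) < n and attempts < 200 * n:
        attempts += 1
        p = rng.uniform(margin, H - margin, 2)
        if all(np.hypot(*(p - q)) >= min_sep for q in pos_list):
            pos_list.append(p)
    if len(pos_list) < n:
        raise ValueError(
            "cannot place cells without crowding; reduce n_cells_per_well "
            "or enlarge image_size_px"
        )
    pos0 = np.asarray(pos_list)  # (x, y)
    speed = rng.uniform(0.02, 0.08, n)
    direction = rng.uniform(0, 2 * np.pi, n)
    vel = np.stack([speed * np.cos(direction), speed * np.sin(direction)], axis=1)
    # diffuse reporter stays below the aggregate threshold: aggregates are
    # bright condensations on top of a dimmer diffuse background
    expression = cfg.soma_amplitude_gray * np.clip(
        rng.lognormal(0.0, 0.35, n), 0.8, 1.4
    )

    geoms = [
        _CellGeometry(cfg, rng, expression[i], morph_labels[i]) for i in range(n)
    ]

    # neurite-seed accrual after onset: Poisson arrivals along neurites.
    # Seeds are kept clear of other somata so neuritic puncta are not
    # mistaken for soma aggregates of a neighbouring cell.
    seed_events: list[list[tuple[float, float, float, float]]] = []
    for i in range(n):
        events = []
        if np.isfinite(onset[i]) and cfg.neurite_seed_rate_per_h > 0:
            t = onset[i]
            while len(events) < cfg.max_neurite_seeds_per_cell:
                t = t + rng.exponential(1.0 / cfg.neurite_seed_rate_per_h)
                if t > frame_times[-1]:
                    break
                for _ in range(20):
                    ang, length = geoms[i].neurites[
                        rng.integers(len(geoms[i].neurites))
                    ]
                    if length <= 13.0:
                        continue
                    # seeds sit distal on neurites, clear of the soma disc
                    r = rng.uniform(12.0, length)
                    dx, dy = r * np.cos(ang), r * np.sin(ang)
                    p = pos0[i] + (dx, dy)
                    d_other = np.hypot(*(pos0 - p).T)
                    d_other[i] = np.inf
                    if d_other.min() >= 14.0:
                        sigma = rng.uniform(1.0, 1.8)
                        events.append((t, dx, dy, sigma))
                        break
        seed_events.append(events)

    # per-frame event indices (first frame at or after the event time)
    def to_frame(t):
        f = np.ceil((t - cfg.t0_offset_h) / dt).astype(float)
        f = np.where(np.isfinite(t), np.maximum(f, 0.0), np.inf)
        return f

    f_on = to_frame(onset)
    f_death = to_frame(death)
    f_exit = to_frame(exit_t)
    f_diss = to_frame(dissolve)

    positions = np.full((n, T, 2), np.nan)
    pixels = np.zeros((T, 2, H, W), np.float32)

    for f in range(T):
        rep = pixels[f, CHANNEL_REPORTER]
        nuc = pixels[f, CHANNEL_NUCLEAR]
        for i in range(n):
            if f >= f_exit[i]:
                continue  # left the field of view
            move_f = min(f, f_death[i])  # dead cells stop drifting
            p = pos0[i] + vel[i] * move_f
            positions[i, f] = p
            cx, cy = int(round(p[0])), int(round(p[1]))
            g = geoms[i]

            # reporter: soma + neurites, fading out after lysis
            if f <= f_death[i]:
                fade = 1.0
            elif f == f_death[i] + 1:
                fade = 0.4
            elif f == f_death[i] + 2:
                fade = 0.1
            else:
                fade = 0.0
            if fade > 0:
                _add_patch(rep, g.reporter, cx, cy, fade)

            # aggregates (soma archetype + neurite seeds) between onset and
            # dissolution, fading with the reporter after death
            agg_on = f_on[i] <= f < f_diss[i]
            if agg_on and fade > 0:
                t_f = frame_times[f]
                if g.morphology == "Ordered":
                    dx, dy, a, sg = g.ordered_blob(
                        int(f - f_on[i]), cfg.punctum_amplitude_gray
                    )
                    _stamp(rep, p[0] + dx, p[1] + dy, a * fade, sg)
                else:
                    for dx, dy, a, sx, sy, th in g.soma_aggregate:
                        _stamp(rep, p[0] + dx, p[1] + dy, a * fade, sx, sy, th)
                for t_s, dx, dy, sg in seed_events[i]:
                    if t_s <= t_f:
                        _stamp(
                            rep, p[0] + dx, p[1] + dy,
                            cfg.punctum_amplitude_gray * fade, sg,
                        )

            # nuclear channel: dim nucleus, bright persistent fragments at death
            if f < f_death[i]:
                _add_patch(nuc, g.nuclear, cx, cy)
            else:
                k = f - f_death[i]
                # x2 compensates disc-mean dilution of point-like
                # fragments, so the nucleus-region mean jumps by roughly
                # death_flash_fold x the live-nucleus level
                frag_amp = (
                    2.0 * cfg.nuclear_amplitude_gray * cfg.death_flash_fold
                    * 0.93**k
                )
                for dx, dy in g.fragments:
                    _stamp(nuc, p[0] + dx, p[1] + dy, frag_amp, 1.2)

    pixels += cfg.background_gray
    pixels += rng.normal(0.0, cfg.noise_sigma_gray, pixels.shape).astype(np.float32)
    stack = TimeLapseStack(
        pixels=np.clip(pixels, 0, 65535).astype(np.uint16),
        pixel_size_um=cfg.pixel_size_um,
        frame_interval_h=dt,
        t0_offset_h=cfg.t0_offset_h,
        well_id=well_id,
    )

    horizon = frame_times[-1]
    morph_labels = np.where(onset <= horizon, morph_labels, None)
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(first_cell_id, first_cell_id + n),
            "well_id": well_id,
            "line": cfg.line_label,
            "lysate_type": cfg.lysate_type,
            "dose_ug": cfg.dose_ug,
            "true_onset_h": np.where(onset <= horizon, onset, np.nan),
            "true_death_h": np.where(death <= horizon, death, np.nan),
            "true_exit_h": np.where(exit_t <= horizon, exit_t, np.nan),
            "true_dissolve_h": np.where(dissolve <= horizon, dissolve, np.nan),
            "morphology_label": morph_labels,
            "t0_soma_intensity": expression,
            "x0_px": pos0[:, 0],
            "y0_px": pos0[:, 1],
        }
    )
    return stack, cells, positions


# ----------------------------------------------------------------------
def simulate_experiment(cfg: SimulationConfig):
    """Simulate ``cfg.n_wells`` replicate wells of one condition.

    Returns ``(stacks, truth)`` where ``stacks`` is a list of
    :class:`TimeLapseStack` (one per well) and ``truth`` a :class:`SimTruth`
    with continuous ground-truth event times.  Identical config and seed
    give bit-identical output.
    """
    cfg.validate()
    seeds = np.random.SeedSequence(cfg.rng_seed).spawn(cfg.n_wells)
    stacks, frames_cells, positions = [], [], {}
    cell_id = 0
    for w, ss in enumerate(seeds):
        well_id = f"W{w:02d}"
        rng = np.random.default_rng(ss)
        stack, cells, pos = _simulate_well(cfg, rng, well_id, cell_id)
        cell_id += len(cells)
        stacks.append(stack)
        frames_cells.append(cells)
        positions[well_id] = pos
    truth = SimTruth(
        cells=pd.concat(frames_cells, ignore_index=True),
        positions=positions,
        frame_interval_h=cfg.frame_interval_h,
        t0_offset_h=cfg.t0_offset_h,
        horizon_h=cfg.horizon_h,
    )
    return stacks, truth


def truth_event_table(truth: SimTruth, horizon_h: float | None = None) -> pd.DataFrame:
    """Convert ground truth to right-censored survival records.

    Times are on the seed-addition clock, discretised to the frame grid
    (an event is recorded at the first frame at or after it occurs).  Exit
    from the field of view and the end of the experiment are censoring
    events.  Returns one record per cell with columns ``time_h``,
    ``event`` (True = death) plus covariates and the (discretised) onset.
    """
    if horizon_h is None:
        horizon_h = truth.horizon_h
    if horizon_h > truth.horizon_h + 1e-9:
        raise ValueError("horizon exceeds the simulated duration")
    dt = truth.frame_interval_h
    t0 = truth.t0_offset_h

    def discretise(t):
        f = np.ceil((np.asarray(t, float) - t0) / dt)
        return t0 + np.maximum(f, 0.0) * dt

    c = truth.cells
    death = discretise(c["true_death_h"].to_numpy())
    exit_t = discretise(c["true_exit_h"].to_numpy())
    onset = discretise(c["true_onset_h"].to_numpy())
    death = np.where(np.isnan(death) | (death > horizon_h), np.inf, death)
    exit_t = np.where(np.isnan(exit_t) | (exit_t > horizon_h), np.inf, exit_t)

    time = np.minimum(np.minimum(death, exit_t), horizon_h)
    event = (death <= exit_t) & (death <= horizon_h)
    onset_obs = np.where(
        np.isnan(onset) | (onset > time), np.nan, onset
    )
    return pd.DataFrame(
        {
            "cell_id": c["cell_id"],
            "well_id": c["well_id"],
            "line": c["line"],
            "dose_ug": c["dose_ug"],
            "time_h": time,
            "event": event,
            "onset_h": onset_obs,
            "morphology_label": c["morphology_label"],
            "t0_soma_intensity": c["t0_soma_intensity"],
        }
    )


# ----------------------------------------------------------------------
def render_seed_frame(
    n_puncta: int,
    image_size_px: int = 256,
    pixel_size_um: float = 0.65,
    amplitude_gray: float = 15000.0,
    noise_sigma_gray: float = 500.0,
    background_gray: float = 1000.0,
    diameter_band_um: tuple[float, float] = (1.0, 3.0),
    intensity_threshold_gray: float = 10000.0,
    n_somata: int = 0,
    rng: np.random.Generator | int | None = None,
):
    """Render one synthetic frame of isolated neurite-seed puncta.

    Punctum Gaussian widths are chosen so the footprint above
    ``background + intensity_threshold_gray`` has an equivalent diameter
    drawn uniformly from ``diameter_band_um``.  Optional large bright
    somata exercise the large-object exclusion rule.  Returns
    ``(frame_uint16, truth)`` where ``truth`` is a DataFrame of punctum
    centres and target diameters.
    """
    rng = np.random.default_rng(rng)
    H = W = image_size_px
    img = np.full((H, W), float(background_gray), np.float32)
    ratio = amplitude_gray / intensity_threshold_gray
    if ratio <= 1.0:
        raise ValueError("amplitude must exceed the detection threshold")
    k = np.sqrt(2.0 * np.log(ratio))  # footprint radius = k * sigma

    margin = 15
    min_sep = 14.0
    pts: list[tuple[float, float]] = []
    attempts = 0
    while len(pts) < n_puncta + n_somata and attempts < 20000:
        attempts += 1
        p = rng.uniform(margin, H - margin, 2)
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 > min_sep**2 for q in pts):
            pts.append((p[0], p[1]))
    if len(pts) < n_puncta + n_somata:
        raise ValueError("could not place that many objects without crowding")

    rows = []
    for j in range(n_puncta):
        d_um = rng.uniform(*diameter_band_um)
        sigma = (d_um / pixel_size_um) / 2.0 / k
        x, y = pts[j]
        _stamp(img, x, y, amplitude_gray, sigma)
        rows.append({"x_px": x, "y_px": y, "diameter_um": d_um, "kind": "punctum"})
    for j in range(n_somata):
        x, y = pts[n_puncta + j]
        # steep bright disc whose footprint (~6.6 um) exceeds the band max
        _stamp(img, x, y, amplitude_gray * 1.5, 4.0)
        rows.append({"x_px": x, "y_px": y, "diameter_um": np.nan, "kind": "soma"})

    img += rng.normal(0.0, noise_sigma_gray, img.shape).astype(np.float32)
    frame = np.clip(img, 0, 65535).astype(np.uint16)
    return frame, pd.DataFrame(rows)
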