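"""Single-cell tracking and censored event-history calling.

Links soma detections across frames, calls death from the nuclear-dye
flash, calls aggregation onset with a persistence requirement, applies the
censoring rules (field-of-view exit, end of experiment), and emits each
neuron's class label — the automated equivalent of frame-by-frame manual
scoring of tracked neurons.

Cell classes follow the Initial_State + End_State + Survival_Status
grammar: initial and end state are ``O`` (no aggregate) or ``A``
(aggregate); survival is ``A`` (alive / censored) or ``D`` (dead); e.g.
``"O+A+D"`` is a cell that started aggregate-free, formed an aggregate and
died.  A transient flag marks aggregates that later dissolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.optimize import linear_sum_assignment
from skimage import measure
from skimage import morphology as skmorph

from .detect import detect_soma_aggregate, local_background
from .simulate import CHANNEL_NUCLEAR, CHANNEL_REPORTER, TimeLapseStack

DEFAULT_MAX_DISP_PX = 6.0
DEFAULT_MAX_GAP_FRAMES = 4
DEFAULT_BORDER_MARGIN_PX = 10.0
DEFAULT_FLASH_FOLD = 3.0
DEFAULT_FLASH_WINDOW_FRAMES = 5
DEFAULT_PERSISTENCE_FRAMES = 2
PATCH_HALF_PX = 35  # 70 x 70 px patches around tracked somata


@dataclass
class CellTrack:
    """One neuron's longitudinal record."""

    cell_id: int
    well_id: str
    positions: np.ndarray            # (T, 2) (x, y); NaN where unobserved
    soma_reporter_intensity: np.ndarray
    nuclear_intensity: np.ndarray
    aggregate_flag: np.ndarray
    start_frame: int
    end_frame: int                   # last observed frame index
    frame_interval_h: float
    t0_offset_h: float
    onset_h: float | None = None
    death_h: float | None = None
    censor_h: float | None = None
    transient: bool = False
    t0_intensity: float = np.nan
    t0_intensity_norm: float = np.nan
    class_label: str | None = None
    line: str | None = None
    dose_ug: float | None = None

    def frame_time(self, f: int) -> float:
        return self.t0_offset_h + f * self.frame_interval_h


@dataclass
class CellClass:
    initial_state: str  # {O, A}
    end_state: str      # {O, A}
    survival: str       # {A, D}
    transient: bool = False

    @property
    def label(self) -> str:
        return f"{self.initial_state}+{self.end_state}+{self.survival}"


# ----------------------------------------------------------------------
def detect_somata(
    frame: np.ndarray,
    nuclear_frame: np.ndarray | None = None,
    threshold_gray: float = 2500.0,
    min_area_px: int = 15,
    nuclear_min_gray: float = 1200.0,
) -> np.ndarray:
    """Centroids (x, y) of soma-sized bright components in a reporter frame.

    The whole-frame median serves as the background level; the synthetic
    background is spatially flat, so a scalar estimate suffices here.
    When a nuclear-channel frame is supplied, components without a
    nuclear-dye signal (live nucleus or post-lysis fragments) are rejected:
    neurons are reporter-positive cells with a labelled nucleus, which
    excludes bright cell-free debris such as neurite aggregate clusters.
    """
    fg = frame.astype(np.float64) - np.median(frame)
    # opening severs thin noise bridges between a soma and nearby bright
    # neurite-aggregate clusters, which would otherwise drag the centroid
    mask = ndimage.binary_opening(
        fg > threshold_gray, structure=skmorph.disk(1)
    )
    labels = measure.label(mask, connectivity=2)
    nuc_fg = None
    if nuclear_frame is not None:
        nuc = nuclear_frame.astype(np.float64)
        nuc_fg = ndimage.uniform_filter(nuc - np.median(nuc), size=3)
    out = []
    for p in measure.regionprops(labels):
        if p.area < min_area_px:
            continue
        if nuc_fg is not None:
            sl = p.slice
            if nuc_fg[sl][p.image].max() < nuclear_min_gray:
                continue
        cy, cx = p.centroid
        out.append((cx, cy, float(p.area)))
    return np.asarray(out, float).reshape(-1, 3)


def link_tracks(
    detections_per_frame: list[np.ndarray],
    max_disp_px: float = DEFAULT_MAX_DISP_PX,
    max_gap_frames: int = DEFAULT_MAX_GAP_FRAMES,
    share_area_factor: float | None = 1.45,
) -> list[dict]:
    """Frame-to-frame nearest-neighbour linking with gap bridging.

    Detections are ``(x, y)`` or ``(x, y, area)`` rows.  Per frame, active
    tracks are assigned to detections by minimising the total displacement
    (pairs beyond ``max_disp_px`` are forbidden); exact ties are broken
    toward the lower track id / detection index.  When areas are provided,
    a track left unmatched may share a detection at least
    ``share_area_factor`` times the median first-frame area: two touching
    somata merge into one oversized component, and both identities ride
    through the merge instead of one track dying.  Tracks unmatched for
    more than ``max_gap_frames`` consecutive frames are closed; unmatched
    detections open new tracks.

    Returns a list of dicts with keys ``start_frame``, ``end_frame`` and
    ``positions`` (length-T array of (x, y), NaN where unobserved).
    """
    if len(detections_per_frame) < 1:
        raise ValueError("need at least one frame of detections")
    T = len(detections_per_frame)
    tracks: list[dict] = []
    active: list[int] = []

    def split(dets):
        dets = np.asarray(dets, float)
        if dets.size == 0:
            return np.zeros((0, 2)), None
        dets = dets.reshape(len(dets), -1)
        if dets.shape[1] >= 3:
            return dets[:, :2], dets[:, 2]
        return dets[:, :2], None

    def new_track(f: int, xy) -> None:
        pos = np.full((T, 2), np.nan)
        pos[f] = xy
        tracks.append(
            {"start_frame": f, "end_frame": f, "positions": pos, "_missed": 0}
        )
        active.append(len(tracks) - 1)

    xy0, area0 = split(detections_per_frame[0])
    big_area = None
    if area0 is not None and share_area_factor is not None and len(area0):
        big_area = share_area_factor * float(np.median(area0))
    for xy in xy0:
        new_track(0, xy)

    big = 1e9
    for f in range(1, T):
        dets, areas = split(detections_per_frame[f])
        n_tr, n_de = len(active), len(dets)
        matched_tracks: set[int] = set()
        matched_dets: set[int] = set()
        cost = dist = None
        if n_tr and n_de:
            last = np.array(
                [tracks[t]["positions"][tracks[t]["end_frame"]] for t in active]
            )
            dist = np.linalg.norm(last[:, None, :] - dets[None, :, :], axis=-1)
            cost = np.where(dist <= max_disp_px, dist, big)
            # deterministic tie-break toward lower incumbent ids
            tie = 1e-7 * (
                np.arange(n_tr)[:, None] * n_de + np.arange(n_de)[None, :]
            )
            rows, cols = linear_sum_assignment(cost + tie)
            for r, c in zip(rows, cols):
                if cost[r, c] >= big:
                    continue
                t = active[r]
                tracks[t]["positions"][f] = dets[c]
                tracks[t]["end_frame"] = f
                tracks[t]["_missed"] = 0
                matched_tracks.add(r)
                matched_dets.add(c)
        still_active = []
        for r, t in enumerate(active):
            if r in matched_tracks:
                still_active.append(t)
                continue
            # merge tolerance: ride along on an oversized component; the
            # merged centroid sits about half the pair separation away, so
            # the search radius is wider than the ordinary association gate
            shared = False
            if (
                dist is not None
                and areas is not None
                and big_area is not None
            ):
                share_disp = 1.8 * max_disp_px
                cand = [
                    c for c in range(n_de)
                    if dist[r, c] <= share_disp and areas[c] >= big_area
                ]
                if cand:
                    c = min(cand, key=lambda c: dist[r, c])
                    tracks[t]["positions"][f] = dets[c]
                    tracks[t]["end_frame"] = f
                    tracks[t]["_missed"] = 0
                    still_active.append(t)
                    shared = True
            if not shared:
                tracks[t]["_missed"] += 1
                if tracks[t]["_missed"] <= max_gap_frames:
                    still_active.append(t)
        active = still_active
        for c in range(n_de):
            if c not in matched_dets:
                new_track(f, dets[c])

    for tr in tracks:
        tr.pop("_missed")
    return tracks


# ----------------------------------------------------------------------
def call_death(
    nuclear_intensity: np.ndarray,
    flash_fold: float = DEFAULT_FLASH_FOLD,
    window_frames: int = DEFAULT_FLASH_WINDOW_FRAMES,
    last_frame: int | None = None,
) -> int | None:
    """First frame where the nuclear dye flashes (lysis), or None.

    A flash is an intensity at least ``flash_fold`` times the rolling
    median of up to ``window_frames`` preceding observed frames.  Slow
    drifts move the rolling median along and never trigger.
    """
    x = np.asarray(nuclear_intensity, float)
    n_obs = int(np.isfinite(x).sum())
    if n_obs < window_frames + 1:
        raise ValueError("track shorter than the rolling window")
    stop = len(x) if last_frame is None else min(len(x), last_frame + 1)
    for t in range(1, stop):
        if not np.isfinite(x[t]):
            continue
        prev = x[max(0, t - window_frames) : t]
        prev = prev[np.isfinite(prev)]
        if prev.size == 0:
            continue
        if x[t] >= flash_fold * np.median(prev):
            return t
    return None


def call_onset(
    aggregate_flag: np.ndarray,
    persistence_frames: int = DEFAULT_PERSISTENCE_FRAMES,
    end_frame: int | None = None,
) -> tuple[int | None, bool]:
    """(first frame of a persistent aggregate run, transient flag).

    Onset is the first frame beginning a run of at least
    ``persistence_frames`` positive frames.  The aggregate is transient if,
    after onset, the flag is negative for at least ``persistence_frames``
    consecutive frames before the end of the observed track.
    """
    flags = np.asarray(aggregate_flag, bool)
    if end_frame is not None:
        flags = flags[: end_frame + 1]
    n = len(flags)
    onset = None
    for t in range(n - persistence_frames + 1):
        if flags[t : t + persistence_frames].all():
            onset = t
            break
    if onset is None:
        return None, False
    run = 0
    for t in range(onset, n):
        run = run + 1 if not flags[t] else 0
        if run >= persistence_frames:
            return onset, True
    return onset, False


def apply_censoring(
    track: CellTrack,
    horizon_h: float,
    image_size_px: int | None = None,
    border_margin_px: float = DEFAULT_BORDER_MARGIN_PX,
) -> CellTrack:
    """Resolve the censoring status of a linked track.

    Death takes precedence; otherwise the track is censored at its last
    observed frame if it ended early (border exit or gap timeout), or at
    the horizon if it survived the whole experiment in frame.  Exactly one
    of ``death_h`` / ``censor_h`` is set afterwards, and no observations
    are kept past that time.
    """
    if track.death_h is not None and track.censor_h is not None:
        raise ValueError("death and censor both set")
    T = len(track.positions)
    if track.death_h is not None:
        cut = int(round((track.death_h - track.t0_offset_h) / track.frame_interval_h))
    else:
        end_time = track.frame_time(track.end_frame)
        track.censor_h = min(end_time, horizon_h) if track.end_frame < T - 1 else horizon_h
        cut = int(round((track.censor_h - track.t0_offset_h) / track.frame_interval_h))
    # drop observations after the event
    track.positions[cut + 1 :] = np.nan
    track.soma_reporter_intensity[cut + 1 :] = np.nan
    track.nuclear_intensity[cut + 1 :] = np.nan
    track.aggregate_flag[cut + 1 :] = False
    track.end_frame = min(track.end_frame, cut)
    return track


def classify_track(track: CellTrack) -> CellClass:
    """Compose the class label from the resolved event history."""
    if track.death_h is None and track.censor_h is None:
        raise ValueError("track has unresolved death/censor status")
    flags = track.aggregate_flag
    initial = "A" if flags[track.start_frame] else "O"
    end = "A" if flags[track.end_frame] else "O"
    survival = "D" if track.death_h is not None else "A"
    cls = CellClass(initial, end, survival, transient=track.transient)
    track.class_label = cls.label
    return cls


def normalize_t0_intensity(
    df: pd.DataFrame,
    value_col: str = "t0_intensity",
    group_cols: tuple[str, ...] = ("line", "replicate"),
) -> pd.DataFrame:
    """Divide each cell's first-frame soma intensity by its group mean.

    Groups are (replicate, line) as in per-replicate normalisation of
    tracked-neuron fluorescence; the group mean of normalised values is 1.
    """
    df = df.copy()
    means = df.groupby(list(group_cols))[value_col].transform("mean")
    if (means == 0).any() or means.isna().any():
        raise ValueError("empty or zero-intensity normalisation group")
    df["t0_intensity_norm"] = df[value_col] / means
    return df


# ----------------------------------------------------------------------
def uptake_by_compartment(df: pd.DataFrame, group_col: str = "aggregate",
                          compartments: tuple[str, ...] = (
                              "soma_mean", "cytoplasm_mean", "nuclear_mean")
                          ) -> pd.DataFrame:
    """Compare label uptake between groups per cellular compartment.

    ``df`` has one row per cell with mean label intensities for the whole
    soma, the soma minus the nucleus (cytoplasm) and the nucleus, plus a
    two-level grouping column (e.g. aggregate-bearing vs aggregate-free).
    Welch two-sample t tests are reported per compartment.
    """
    levels = sorted(df[group_col].unique())
    if len(levels) != 2:
        raise ValueError("need exactly two groups")
    a = df[df[group_col] == levels[0]]
    b = df[df[group_col] == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 cells per group")
    rows = []
    for comp in compartments:
        t, p = stats.ttest_ind(a[comp], b[comp], equal_var=False)
        rows.append(
            dict(
                compartment=comp,
                mean_a=float(a[comp].mean()),
                mean_b=float(b[comp].mean()),
                mean_difference=float(a[comp].mean() - b[comp].mean()),
                t=float(t),
                p=float(p),
                group_a=levels[0],
                group_b=levels[1],
            )
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# whole-well tracking

def _disk_mask(size: int, radius: float) -> np.ndarray:
    c = size // 2
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def _patch(img: np.ndarray, cx: int, cy: int, half: int) -> np.ndarray:
    """Extract a (2*half+1)^2 patch, edge-padded at borders."""
    h, w = img.shape
    y0, y1 = cy - half, cy + half + 1
    x0, x1 = cx - half, cx + half + 1
    py0, py1 = max(0, -y0), max(0, y1 - h)
    px0, px1 = max(0, -x0), max(0, x1 - w)
    core = img[max(y0, 0) : min(y1, h), max(x0, 0) : min(x1, w)]
    if py0 or py1 or px0 or px1:
        core = np.pad(core, ((py0, py1), (px0, px1)), mode="edge")
    return core


@dataclass
class TrackingParams:
    soma_threshold_gray: float = 2500.0
    soma_min_area_px: int = 15
    max_disp_px: float = DEFAULT_MAX_DISP_PX
    max_gap_frames: int = DEFAULT_MAX_GAP_FRAMES
    border_margin_px: float = DEFAULT_BORDER_MARGIN_PX
    flash_fold: float = DEFAULT_FLASH_FOLD
    flash_window_frames: int = DEFAULT_FLASH_WINDOW_FRAMES
    persistence_frames: int = DEFAULT_PERSISTENCE_FRAMES
    aggregate_threshold_gray: float = 10000.0
    aggregate_min_area_px: int = 4
    soma_mask_radius_px: float = 7.5
    nuclear_mask_radius_px: float = 3.0
    patch_half_px: int = PATCH_HALF_PX
    background_radius_px: int = 15
    death_grace_frames: int = 2  # flash may land just after the last link


def track_well(
    stack: TimeLapseStack,
    params: TrackingParams | None = None,
    line: str | None = None,
    dose_ug: float | None = None,
    first_cell_id: int = 0,
) -> list[CellTrack]:
    """Detect, link and phenotype all neurons present at the first frame.

    Tracks beginning mid-experiment (cells entering the field) are
    excluded, mirroring selection of cells present at t0.
    """
    params = params or TrackingParams()
    T = stack.n_frames
    reporter = stack.pixels[:, CHANNEL_REPORTER]
    nuclear = stack.pixels[:, CHANNEL_NUCLEAR]

    backgrounds = np.stack(
        [local_background(reporter[f], params.background_radius_px) for f in range(T)]
    )
    dets = [
        detect_somata(
            reporter[f], nuclear[f],
            params.soma_threshold_gray, params.soma_min_area_px,
        )
        for f in range(T)
    ]
    raw_tracks = link_tracks(dets, params.max_disp_px, params.max_gap_frames)
    raw_tracks = [t for t in raw_tracks if t["start_frame"] == 0]

    half = params.patch_half_px
    size = 2 * half + 1
    soma_mask = _disk_mask(size, params.soma_mask_radius_px)
    nuclear_mask = _disk_mask(size, params.nuclear_mask_radius_px)
    meas_soma = _disk_mask(size, 5.0)
    meas_nuc_local = _disk_mask(
        2 * int(params.nuclear_mask_radius_px) + 1, params.nuclear_mask_radius_px
    )

    horizon = stack.frame_times_h[-1]
    out: list[CellTrack] = []
    for k, tr in enumerate(raw_tracks):
        pos = tr["positions"]
        # carry the last known position forward so a death flash landing
        # just after the final link is still measured
        filled = pos.copy()
        last = None
        for f in range(T):
            if np.isfinite(filled[f]).all():
                last = filled[f]
            elif last is not None:
                filled[f] = last

        soma_int = np.full(T, np.nan)
        nuc_int = np.full(T, np.nan)
        patches = np.empty((T, size, size), np.float64)
        bg_patches = np.empty((T, size, size), np.float64)
        # nuclear intensity is measured around the local nuclear-channel
        # peak near the track position: the reporter centroid shifts when
        # bright aggregates form, but the nucleus stays put in its own
        # channel
        search = 9
        yy, xx = np.mgrid[-search : search + 1, -search : search + 1]
        search_mask = yy**2 + xx**2 <= search**2
        nuc_r = int(params.nuclear_mask_radius_px)
        for f in range(T):
            cx, cy = int(round(filled[f, 0])), int(round(filled[f, 1]))
            rp = _patch(reporter[f].astype(np.float64), cx, cy, half)
            bp = _patch(backgrounds[f], cx, cy, half)
            npch = _patch(nuclear[f].astype(np.float64), cx, cy, half)
            patches[f] = rp
            bg_patches[f] = bp
            soma_int[f] = (rp - bp)[meas_soma].mean()
            core = npch[
                half - search - 2 : half + search + 3,
                half - search - 2 : half + search + 3,
            ]
            sm = ndimage.uniform_filter(core, size=3)[2:-2, 2:-2]
            sm = np.where(search_mask, sm, -np.inf)
            py, px = np.unravel_index(np.argmax(sm), sm.shape)
            py += half - search
            px += half - search
            nuc_int[f] = npch[
                py - nuc_r : py + nuc_r + 1, px - nuc_r : px + nuc_r + 1
            ][meas_nuc_local].mean()

        flags, _ = detect_soma_aggregate(
            patches,
            soma_mask,
            nuclear_mask,
            params.aggregate_threshold_gray,
            params.aggregate_min_area_px,
            background_stack=bg_patches,
        )

        track = CellTrack(
            cell_id=first_cell_id + k,
            well_id=stack.well_id,
            positions=pos,
            soma_reporter_intensity=soma_int,
            nuclear_intensity=nuc_int,
            aggregate_flag=flags,
            start_frame=tr["start_frame"],
            end_frame=tr["end_frame"],
            frame_interval_h=stack.frame_interval_h,
            t0_offset_h=stack.t0_offset_h,
            line=line,
            dose_ug=dose_ug,
        )
        track.t0_intensity = soma_int[0]

        last_considered = min(T - 1, tr["end_frame"] + params.death_grace_frames)
        try:
            death_f = call_death(
                nuc_int, params.flash_fold, params.flash_window_frames,
                last_frame=last_considered,
            )
        except ValueError:
            death_f = None
        if death_f is not None:
            track.death_h = track.frame_time(death_f)
            track.end_frame = max(track.end_frame, min(death_f, T - 1))

        onset_end = death_f if death_f is not None else track.end_frame
        onset_f, transient = call_onset(
            flags, params.persistence_frames, end_frame=onset_end
        )
        if onset_f is not None:
            track.onset_h = track.frame_time(onset_f)
            track.transient = transient
        track.aggregate_flag[onset_end + 1 :] = False

        apply_censoring(track, horizon, stack.pixels.shape[-1], params.border_margin_px)
        classify_track(track)
        out.append(track)
    return out


def tracks_to_table(tracks: list[CellTrack], replicate: int | None = None) -> pd.DataFrame:
    """Per-cell event table (one row per tracked neuron)."""
    rows = []
    for t in tracks:
        rows.append(
            dict(
                cell_id=t.cell_id,
                well_id=t.well_id,
                line=t.line,
                dose_ug=t.dose_ug,
                replicate=replicate,
                onset_h=t.onset_h if t.onset_h is not None else np.nan,
                death_h=t.death_h if t.death_h is not None else np.nan,
                censor_h=t.censor_h if t.censor_h is not None else np.nan,
                class_label=t.class_label,
                transient=t.transient,
                t0_intensity=t.t0_intensity,
                t0_intensity_norm=t.t0_intensity_norm,
                x0_px=t.positions[t.start_frame, 0],
                y0_px=t.positions[t.start_frame, 1],
            )
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["time_h"] = df["death_h"].fillna(df["censor_h"])
        df["event"] = df["death_h"].notna()
    return df
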