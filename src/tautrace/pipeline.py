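"""End-to-end orchestration: simulate -> detect -> track -> analyse -> report.

A :class:`PipelineConfig` describes a multi-condition experiment (cell
lines x lysate doses x replicate wells); :func:`run_pipeline` produces the
per-cell event table, per-well seeding series, survival / onset / Cox /
ANOVA statistics and morphology tables, and writes everything as CSV plus
a markdown summary and a reproducibility manifest.  The master seed fully
determines all stochastic behaviour; rerunning with the same config is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import survival as sv
from .config import SimulationConfig
from .detect import SeedCountSeries, count_series, subtract_baseline
from .morphology import (
    MIN_AGGREGATE_FRAMES,
    classify_patch_series,
    morphology_statistics,
)
from .simulate import CHANNEL_REPORTER, SimTruth, simulate_experiment
from .track import (
    CellTrack,
    TrackingParams,
    _disk_mask,
    _patch,
    normalize_t0_intensity,
    track_well,
    tracks_to_table,
)

log = logging.getLogger("tautrace")


@dataclass
class Condition:
    """One experimental condition: (line, lysate, dose) x replicate wells."""

    line: str = "control"
    lysate_type: str = "seed"
    dose_ug: float = 10.0
    n_wells: int = 2


@dataclass
class PipelineConfig:
    base: SimulationConfig = field(default_factory=SimulationConfig)
    conditions: list[Condition] = field(
        default_factory=lambda: [
            Condition("control", "seed", 10.0, 2),
            Condition("mutant", "seed", 10.0, 2),
            Condition("control", "none", 0.0, 1),
            Condition("mutant", "none", 0.0, 1),
        ]
    )
    tracking: TrackingParams = field(default_factory=TrackingParams)
    seed: int = 0
    analyses: tuple[str, ...] = ("seeding", "survival", "morphology")
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "base": self.base.to_dict(),
            "conditions": [dataclasses.asdict(c) for c in self.conditions],
            "tracking": dataclasses.asdict(self.tracking),
            "seed": self.seed,
            "analyses": list(self.analyses),
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            base=SimulationConfig.from_dict(d.get("base", {})),
            conditions=[Condition(**c) for c in d.get("conditions", [])],
            tracking=TrackingParams(**d.get("tracking", {})),
            seed=int(d.get("seed", 0)),
            analyses=tuple(d.get("analyses", ("seeding", "survival", "morphology"))),
            log_level=d.get("log_level", "INFO"),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ReportBundle:
    event_table: pd.DataFrame
    seed_counts: pd.DataFrame
    series: list[SeedCountSeries]
    stacks: dict[str, object]
    truth: SimTruth | None
    results: dict
    config: PipelineConfig


# ----------------------------------------------------------------------
def run_pipeline(config: PipelineConfig, outdir=None) -> ReportBundle:
    """Run the full simulate/detect/track/analyse pipeline."""
    logging.basicConfig(level=config.log_level)
    rng_master = np.random.SeedSequence(config.seed)
    cond_seeds = rng_master.spawn(len(config.conditions))

    event_frames, series_list, stacks = [], [], {}
    truths: list[pd.DataFrame] = []
    positions = {}
    track_store: dict[str, list[CellTrack]] = {}
    cell_id = 0
    for k, (cond, ss) in enumerate(zip(config.conditions, cond_seeds)):
        cfg = config.base.replace(
            line_label=cond.line,
            lysate_type=cond.lysate_type,
            dose_ug=cond.dose_ug,
            n_wells=cond.n_wells,
            rng_seed=int(ss.generate_state(1)[0] % (2**31)),
        )
        log.info(
            "condition %d: line=%s lysate=%s dose=%g ug, %d wells",
            k, cond.line, cond.lysate_type, cond.dose_ug, cond.n_wells,
        )
        well_stacks, truth = simulate_experiment(cfg)
        for w, stack in enumerate(well_stacks):
            uid = f"C{k}{stack.well_id}"
            stack.well_id = uid
            stacks[uid] = stack
            truth.cells.loc[truth.cells["well_id"] == f"W{w:02d}", "well_id"] = uid
            positions[uid] = truth.positions[f"W{w:02d}"]

            s = count_series(stack, config.tracking.aggregate_threshold_gray)
            s.line, s.dose_ug, s.replicate = cond.line, cond.dose_ug, w
            series_list.append(s)

            tracks = track_well(
                stack, config.tracking, line=cond.line, dose_ug=cond.dose_ug,
                first_cell_id=cell_id,
            )
            cell_id += len(tracks)
            track_store[uid] = tracks
            tab = tracks_to_table(tracks, replicate=w)
            event_frames.append(tab)
        truth.positions = positions
        truths.append(truth.cells)

    truth_all = SimTruth(
        cells=pd.concat(truths, ignore_index=True),
        positions=positions,
        frame_interval_h=config.base.frame_interval_h,
        t0_offset_h=config.base.t0_offset_h,
        horizon_h=config.base.horizon_h,
    )
    events = pd.concat(event_frames, ignore_index=True)
    if len(events):
        events = normalize_t0_intensity(
            events, value_col="t0_intensity", group_cols=("line", "replicate")
        )

    # baseline subtraction against the no-lysate wells of the same line
    corrected: list[SeedCountSeries] = []
    for s in series_list:
        refs = [
            r for r in series_list
            if r.line == s.line and (r.dose_ug or 0) == 0 and r is not s
        ]
        corrected.append(subtract_baseline(s, refs) if refs else s)
    seed_counts = (
        pd.concat([s.to_frame() for s in corrected], ignore_index=True)
        if corrected else pd.DataFrame()
    )

    results: dict = {}
    if "seeding" in config.analyses:
        results.update(_seeding_analyses(corrected))
    if "survival" in config.analyses and len(events):
        results.update(_survival_analyses(events))
    if "morphology" in config.analyses and len(events):
        results["morphology"] = _morphology_analyses(
            events, track_store, stacks, config.tracking
        )

    bundle = ReportBundle(
        event_table=events,
        seed_counts=seed_counts,
        series=corrected,
        stacks=stacks,
        truth=truth_all,
        results=results,
        config=config,
    )
    if outdir is not None:
        write_report(bundle, outdir)
    return bundle


def _seeding_analyses(series: list[SeedCountSeries]) -> dict:
    out: dict = {}
    dosed = [s for s in series if (s.dose_ug or 0) > 0]
    rows = [
        dict(well_id=s.well_id, line=s.line, dose_ug=s.dose_ug,
             replicate=s.replicate, auc=sv.auc_trapezoid(s))
        for s in series
    ]
    out["auc"] = pd.DataFrame(rows)
    dosed_auc = out["auc"][out["auc"]["dose_ug"] > 0]
    try:
        out["anova"] = sv.anova_line_by_dose(dosed_auc).table
    except ValueError as exc:
        log.warning("seeding ANOVA skipped: %s", exc)
    if dosed:
        try:
            slopes, test = sv.seeding_slope(dosed)
            out["slopes"], out["slope_test"] = slopes, test
        except ValueError as exc:
            log.warning("slope comparison skipped: %s", exc)
    return out


def _survival_analyses(events: pd.DataFrame) -> dict:
    out: dict = {}
    early, others = sv.early_aggregator_groups(events)
    if len(early) and len(others) and (early["event"].any() or others["event"].any()):
        out["early_vs_others"] = sv.log_rank(
            early["time_h"], early["event"], others["time_h"], others["event"]
        )
    lines = sorted(events["line"].dropna().unique())
    if len(lines) == 2:
        a = events[events["line"] == lines[0]]
        b = events[events["line"] == lines[1]]
        rec_a, rec_b = sv.onset_records(a), sv.onset_records(b)
        if rec_a["event"].any() or rec_b["event"].any():
            out["onset_by_line"] = sv.log_rank(
                rec_a["time_h"], rec_a["event"], rec_b["time_h"], rec_b["event"]
            )
        pa, pb = sv.post_onset_records(a), sv.post_onset_records(b)
        if len(pa) and len(pb) and (pa["event"].any() or pb["event"].any()):
            out["post_onset_by_line"] = sv.log_rank(
                pa["time_h"], pa["event"], pb["time_h"], pb["event"]
            )
        cox_df = pd.DataFrame(
            {
                "time_h": events["time_h"],
                "event": events["event"].astype(int),
                "line_mutant": (events["line"] == "mutant").astype(int),
                "not_early": (
                    ~(events["onset_h"] <= sv.EARLY_AGGREGATOR_CUTOFF_H).fillna(False)
                ).astype(int),
            }
        )
        if events["event"].any():
            try:
                out["cox"] = sv.cox_fit(cox_df).summary
            except Exception as exc:  # convergence / separation
                log.warning("Cox fit skipped: %s", exc)
    # t0-expression correlations, per line: onset among aggregate formers,
    # lifespan among cells that died
    corr_rows = []
    for line, sub in events.groupby("line"):
        formers = sub[sub["onset_h"].notna()]
        if len(formers) >= 3 and formers["t0_intensity_norm"].std() > 0:
            c = sv.onset_expression_correlation(formers, outcome_col="onset_h")
            corr_rows.append(dict(line=line, outcome="onset_h", **c))
        died = sub[sub["event"]].assign(lifespan_h=lambda d: d["time_h"])
        if len(died) >= 3 and died["t0_intensity_norm"].std() > 0:
            c = sv.onset_expression_correlation(died, outcome_col="lifespan_h")
            corr_rows.append(dict(line=line, outcome="lifespan_h", **c))
    if corr_rows:
        out["expression_correlations"] = pd.DataFrame(corr_rows)
    if events["replicate"].notna().any() and events["line"].nunique() == 2:
        try:
            fracs, frac_tests = sv.aggregate_fraction_at(events)
            out["aggregate_fractions"] = fracs
            out["aggregate_fraction_tests"] = frac_tests
        except ValueError as exc:
            log.warning("aggregate fractions skipped: %s", exc)
    out["km_all"] = sv.km_estimate(events["time_h"], events["event"]).to_frame()
    if len(early) and len(others):
        out["km_groups"] = {
            "early aggregators": sv.km_estimate(early["time_h"], early["event"]),
            "others": sv.km_estimate(others["time_h"], others["event"]),
        }
    out["cumulative_onset"] = sv.cumulative_onset(events)
    return out


def _morphology_analyses(events, track_store, stacks, params: TrackingParams) -> dict:
    half = params.patch_half_px
    size = 2 * half + 1
    soma_mask = _disk_mask(size, params.soma_mask_radius_px)
    nuclear_mask = _disk_mask(size, params.nuclear_mask_radius_px)
    rows = []
    for uid, tracks in track_store.items():
        stack = stacks[uid]
        reporter = stack.pixels[:, CHANNEL_REPORTER]
        for t in tracks:
            if t.onset_h is None:
                continue
            onset_f = int(round((t.onset_h - t.t0_offset_h) / t.frame_interval_h))
            end_f = t.end_frame
            if end_f - onset_f + 1 < MIN_AGGREGATE_FRAMES:
                label = "Unclassifiable"
            else:
                patches = np.stack(
                    [
                        _patch(
                            reporter[f].astype(np.float64),
                            int(round(t.positions[min(f, t.end_frame), 0]))
                            if np.isfinite(t.positions[min(f, t.end_frame), 0])
                            else int(round(np.nanmean(t.positions[:, 0]))),
                            int(round(t.positions[min(f, t.end_frame), 1]))
                            if np.isfinite(t.positions[min(f, t.end_frame), 1])
                            else int(round(np.nanmean(t.positions[:, 1]))),
                            half,
                        )
                        for f in range(onset_f, end_f + 1)
                    ]
                )
                call = classify_patch_series(
                    patches, soma_mask, nuclear_mask, 0, patches.shape[0] - 1,
                    t.frame_interval_h, cell_id=t.cell_id,
                    intensity_threshold_gray=params.aggregate_threshold_gray,
                    min_area_px=params.aggregate_min_area_px,
                )
                label = call.label
            lifespan = t.death_h if t.death_h is not None else np.nan
            agg_end = t.death_h if t.death_h is not None else t.censor_h
            rows.append(
                dict(
                    cell_id=t.cell_id, well_id=uid, line=t.line,
                    morphology=label, onset_h=t.onset_h,
                    lifespan_h=lifespan,
                    lifespan_time_h=agg_end,
                    died=t.death_h is not None,
                    aggregate_lifespan_h=(agg_end - t.onset_h)
                    if agg_end is not None else np.nan,
                    aggregate_censored=t.death_h is None,
                )
            )
    calls = pd.DataFrame(rows)
    out = {"calls": calls}
    if len(calls):
        try:
            out["statistics"] = morphology_statistics(calls)
        except ValueError as exc:
            log.warning("morphology statistics skipped: %s", exc)
    return out


# ----------------------------------------------------------------------
def write_report(bundle: ReportBundle, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.event_table.to_csv(outdir / "event_table.csv", index=False)
    bundle.seed_counts.to_csv(outdir / "seed_counts.csv", index=False)
    if bundle.truth is not None:
        bundle.truth.cells.to_csv(outdir / "sim_truth.csv", index=False)
    res = bundle.results
    for key in ("auc", "slopes", "km_all", "cumulative_onset", "cox", "anova",
                "expression_correlations", "aggregate_fractions"):
        if key in res:
            obj = res[key]
            if isinstance(obj, pd.DataFrame):
                obj.to_csv(outdir / f"{key}.csv")
    if "km_groups" in res:
        sv.plot_km_curves(
            res["km_groups"], outdir / "km_early_vs_others.png",
            title="early aggregators vs others",
        )
    if "morphology" in res:
        res["morphology"]["calls"].to_csv(outdir / "morphology.csv", index=False)
        stats_ = res["morphology"].get("statistics")
        if stats_:
            stats_["proportions"].to_csv(
                outdir / "morphology_proportions.csv", index=False
            )

    manifest = {
        "config": bundle.config.to_dict(),
        "config_hash": bundle.config.config_hash(),
        "seed": bundle.config.seed,
        "n_cells_tracked": int(len(bundle.event_table)),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)

    lines = ["# Pipeline summary", ""]
    lines.append(f"- config hash: `{bundle.config.config_hash()}`")
    lines.append(f"- tracked neurons: {len(bundle.event_table)}")
    if "early_vs_others" in res:
        r = res["early_vs_others"]
        lines.append(
            f"- early aggregators vs others log-rank: chi2={r.chi_square:.2f}, p={r.p:.3g}"
        )
    if "onset_by_line" in res:
        r = res["onset_by_line"]
        lines.append(
            f"- cumulative onset, line comparison: chi2={r.chi_square:.2f}, p={r.p:.3g}"
        )
    if "post_onset_by_line" in res:
        r = res["post_onset_by_line"]
        lines.append(
            f"- post-onset survival, line comparison: chi2={r.chi_square:.2f}, p={r.p:.3g}"
        )
    if "anova" in res:
        lines.append("- AUC two-way ANOVA (line x dose):")
        lines.append(res["anova"].to_string())
    (outdir / "summary.md").write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
def validate_against_truth(
    event_table: pd.DataFrame,
    truth: SimTruth,
    match_radius_px: float = 6.0,
    frame_tol: int = 1,
) -> dict:
    """Score tracked events against simulation ground truth.

    Tracks are matched to true cells by their first-frame positions
    (nearest neighbour within ``match_radius_px``).  Returns per-event
    accuracy metrics: the fraction of onset and death calls within
    ``frame_tol`` frames of truth, censored-vs-event status agreement and
    the class-label confusion counts.
    """
    dt = truth.frame_interval_h
    t0 = truth.t0_offset_h

    def snap(t):
        return t0 + np.maximum(np.ceil((np.asarray(t, float) - t0) / dt), 0) * dt

    matches = []
    for well, sub in event_table.groupby("well_id"):
        tcells = truth.cells[truth.cells["well_id"] == well]
        if not len(tcells):
            raise ValueError(f"well {well} missing from truth")
        tp = tcells[["x0_px", "y0_px"]].to_numpy(float)
        for _, row in sub.iterrows():
            d = np.linalg.norm(tp - np.array([row["x0_px"], row["y0_px"]]), axis=1)
            j = int(np.argmin(d))
            if d[j] <= match_radius_px:
                matches.append((row, tcells.iloc[j]))
    if not matches:
        return {"n_matched": 0}

    onset_ok, onset_n = 0, 0
    death_ok, death_n = 0, 0
    status_ok = 0
    for row, tc in matches:
        true_death = tc["true_death_h"]
        true_exit = tc["true_exit_h"]
        death_first = np.isfinite(true_death) and (
            not np.isfinite(true_exit) or true_death <= true_exit
        )
        pred_death = np.isfinite(row["death_h"])
        if pred_death == death_first:
            status_ok += 1
        if death_first:
            death_n += 1
            if pred_death and abs(snap(true_death) - row["death_h"]) <= frame_tol * dt + 1e-9:
                death_ok += 1
        true_onset = tc["true_onset_h"]
        observed_until = min(
            x for x in (true_death, true_exit, truth.horizon_h) if np.isfinite(x)
        )
        if np.isfinite(true_onset) and snap(true_onset) <= observed_until:
            onset_n += 1
            if np.isfinite(row["onset_h"]) and abs(
                snap(true_onset) - row["onset_h"]
            ) <= frame_tol * dt + 1e-9:
                onset_ok += 1
    n = len(matches)
    return {
        "n_matched": n,
        "match_fraction": n / len(event_table),
        "onset_within_tol": onset_ok / onset_n if onset_n else np.nan,
        "n_true_onsets": onset_n,
        "death_within_tol": death_ok / death_n if death_n else np.nan,
        "n_true_deaths": death_n,
        "status_agreement": status_ok / n,
    }
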