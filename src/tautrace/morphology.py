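"""Aggregate-morphology (strain) classification and its statistics.

Each aggregate-bearing cell's 70 x 70 px reporter patch series, restricted
to the frames from aggregation onset to cell death or the end of the
experiment, is summarised by a small set of features and assigned to one of
the strain categories: Ordered (one or a few large cytoplasmic
condensations, often compacting over time), Disordered (many small
cytoplasmic puncta that fail to coalesce), Speckles (prominent nuclear
speckling), Other (e.g. lenticular profiles), or Unclassifiable (too few
aggregate-positive frames).  "Toxic" is accepted as an input label for
interoperability with externally scored data but is never emitted.

The rules replace blinded human scoring with explicit feature thresholds
so the pipeline is automated and reproducible; the thresholds were fixed
once against the simulator's rendering archetypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .detect import detect_soma_aggregate

LABELS = ("Ordered", "Disordered", "Speckles", "Toxic", "Other", "Unclassifiable")
UNCLASSIFIABLE = "Unclassifiable"
MIN_AGGREGATE_FRAMES = 3

SPECKLES_NUCLEAR_OVERLAP = 0.5
ORDERED_LARGEST_FRACTION = 0.6
DISORDERED_MIN_PUNCTA = 5


@dataclass
class MorphologyFeatures:
    punctum_count_median: float
    largest_component_area_fraction: float
    nuclear_overlap_fraction: float
    compaction_slope_per_h: float
    frames_used: int


@dataclass
class MorphologyCall:
    cell_id: int
    label: str
    features: MorphologyFeatures | None


# ----------------------------------------------------------------------
def extract_morphology_features(
    descriptors: pd.DataFrame,
    frame_interval_h: float,
) -> MorphologyFeatures | None:
    """Summarise per-frame aggregate descriptors into call features.

    ``descriptors`` is the per-frame table produced by
    :func:`tautrace.detect.detect_soma_aggregate`, already restricted to
    the onset-to-death/end window.  Frames without an accepted component
    are ignored.  Returns None (Unclassifiable) with fewer than
    ``MIN_AGGREGATE_FRAMES`` aggregate-positive frames.

    The compaction slope is the least-squares slope of log largest-
    component area against hours; negative values indicate compaction,
    the hallmark of the Ordered archetype.
    """
    pos = descriptors[descriptors["n_components"] > 0]
    if len(pos) < MIN_AGGREGATE_FRAMES:
        return None
    t = pos["frame_index"].to_numpy(float) * frame_interval_h
    log_area = np.log(pos["largest_area_px"].to_numpy(float))
    slope = stats.linregress(t, log_area).slope if len(pos) > 1 else 0.0
    return MorphologyFeatures(
        punctum_count_median=float(pos["n_components"].median()),
        largest_component_area_fraction=float(pos["largest_area_fraction"].median()),
        nuclear_overlap_fraction=float(pos["nuclear_overlap_fraction"].median()),
        compaction_slope_per_h=float(slope),
        frames_used=int(len(pos)),
    )


def classify_morphology(features: MorphologyFeatures | None,
                        cell_id: int = -1) -> MorphologyCall:
    """Rule-based strain assignment from summary features.

    Order of precedence: nuclear speckling, then a dominant single
    condensation (Ordered), then many puncta (Disordered), else Other.
    """
    if features is None:
        return MorphologyCall(cell_id, UNCLASSIFIABLE, None)
    for v in (
        features.punctum_count_median,
        features.largest_component_area_fraction,
        features.nuclear_overlap_fraction,
    ):
        if not np.isfinite(v):
            return MorphologyCall(cell_id, UNCLASSIFIABLE, features)
    if features.nuclear_overlap_fraction > SPECKLES_NUCLEAR_OVERLAP:
        label = "Speckles"
    elif features.largest_component_area_fraction > ORDERED_LARGEST_FRACTION:
        label = "Ordered"
    elif features.punctum_count_median >= DISORDERED_MIN_PUNCTA:
        label = "Disordered"
    else:
        label = "Other"
    return MorphologyCall(cell_id, label, features)


def classify_patch_series(
    patch_stack: np.ndarray,
    soma_mask: np.ndarray,
    nuclear_mask: np.ndarray,
    onset_frame: int,
    end_frame: int,
    frame_interval_h: float,
    cell_id: int = -1,
    **detect_kwargs,
) -> MorphologyCall:
    """Classify one cell directly from its patch time series.

    Frames outside [onset_frame, end_frame] are discarded before feature
    extraction, mirroring scoring restricted to the aggregate-bearing
    window.  Classification is invariant to uniform intensity rescaling of
    the patch only insofar as the detection threshold is scaled with it;
    features themselves are ratios and counts.
    """
    sub = patch_stack[onset_frame : end_frame + 1]
    if sub.shape[0] == 0:
        return MorphologyCall(cell_id, UNCLASSIFIABLE, None)
    _, desc = detect_soma_aggregate(sub, soma_mask, nuclear_mask, **detect_kwargs)
    feats = extract_morphology_features(desc, frame_interval_h)
    return classify_morphology(feats, cell_id)


# ----------------------------------------------------------------------
def morphology_statistics(
    df: pd.DataFrame,
    group_col: str = "line",
    label_col: str = "morphology",
) -> dict:
    """Per-line strain frequencies and Ordered-vs-Disordered comparisons.

    ``df`` carries one row per classified aggregate-bearing cell with its
    strain label, line, and (where available) lifespan, onset and observed
    aggregate duration.  Unclassifiable cells are excluded throughout.
    Returns a dict with a proportions table (with SE), two-proportion
    z-tests per class between lines, and Welch t tests of lifespan, onset
    and aggregate lifespan between Ordered and Disordered cells within each
    line.  Comparisons whose strata are absent are skipped with a notice.
    """
    df = df[df[label_col] != UNCLASSIFIABLE].copy()
    if df[label_col].nunique() < 2:
        raise ValueError("need >= 2 morphology classes present")
    notices: list[str] = []

    counts = (
        df.groupby([group_col, label_col]).size().rename("n").reset_index()
    )
    totals = df.groupby(group_col).size().rename("total")
    counts = counts.join(totals, on=group_col)
    counts["proportion"] = counts["n"] / counts["total"]
    counts["se"] = np.sqrt(
        counts["proportion"] * (1 - counts["proportion"]) / counts["total"]
    )

    groups = sorted(df[group_col].unique())
    prop_tests = []
    if len(groups) == 2:
        for label in sorted(df[label_col].unique()):
            sub = counts[counts[label_col] == label]
            if set(sub[group_col]) != set(groups):
                notices.append(f"class {label} absent in one line; test skipped")
                continue
            n_evt = sub.set_index(group_col).loc[groups, "n"].to_numpy()
            n_tot = sub.set_index(group_col).loc[groups, "total"].to_numpy()
            stat, p = proportions_ztest(n_evt, n_tot)
            prop_tests.append(dict(label=label, z=float(stat), p=float(p)))

    outcome_tests = []
    has_censoring = {"lifespan_time_h", "died"}.issubset(df.columns)
    for grp in groups:
        sub = df[df[group_col] == grp]
        ordered = sub[sub[label_col] == "Ordered"]
        disordered = sub[sub[label_col] == "Disordered"]
        for col in ("lifespan_h", "onset_h", "aggregate_lifespan_h"):
            if col not in df.columns:
                continue
            if col == "lifespan_h" and has_censoring:
                # lifespan is right-censored (survivors, exits): compare by
                # log-rank rather than a t test on the dead cells only
                from .survival import log_rank

                a = ordered[["lifespan_time_h", "died"]].dropna()
                b = disordered[["lifespan_time_h", "died"]].dropna()
                if len(a) < 2 or len(b) < 2 or not (
                    a["died"].any() or b["died"].any()
                ):
                    notices.append(
                        f"{grp}: too few Ordered/Disordered cells for {col}; skipped"
                    )
                    continue
                res = log_rank(
                    a["lifespan_time_h"], a["died"].astype(bool),
                    b["lifespan_time_h"], b["died"].astype(bool),
                )
                mo = ordered[col].dropna()
                md = disordered[col].dropna()
                outcome_tests.append(
                    dict(
                        line=grp, outcome=col, t=float(res.chi_square),
                        p=float(res.p),
                        mean_ordered=float(mo.mean()) if len(mo) else np.nan,
                        mean_disordered=float(md.mean()) if len(md) else np.nan,
                        died_fraction_ordered=float(a["died"].mean()),
                        died_fraction_disordered=float(b["died"].mean()),
                        n_ordered=len(a), n_disordered=len(b),
                        test="logrank",
                    )
                )
                continue
            a = ordered[col].dropna()
            b = disordered[col].dropna()
            if len(a) < 2 or len(b) < 2:
                notices.append(
                    f"{grp}: too few Ordered/Disordered cells for {col}; skipped"
                )
                continue
            t, p = stats.ttest_ind(a, b, equal_var=False)
            outcome_tests.append(
                dict(
                    line=grp, outcome=col, t=float(t), p=float(p),
                    mean_ordered=float(a.mean()), mean_disordered=float(b.mean()),
                    n_ordered=len(a), n_disordered=len(b),
                    test="welch_t",
                )
            )

    return {
        "proportions": counts,
        "proportion_tests": pd.DataFrame(prop_tests),
        "outcome_tests": pd.DataFrame(outcome_tests),
        "notices": notices,
    }
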