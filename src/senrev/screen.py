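"""Control-anchored Z-score hit calling for the three-arm reversal screen.

Per-cell features are aggregated to well-level profiles (median per feature,
raw cell count), converted to Z scores against the siGLO control wells of the
same plate, collapsed to one Z row per (siRNA, arm), and scored against the
directional reversal signature: cell number up; cell area, nuclear area and
nuclear elongation down; nuclear roundness and cell elongation up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CONTROL_LABEL, MORPHOLOGY_FEATURES
from .synthdata import REVERSAL_SIGNATURE

FEATURES = ("cell_count",) + MORPHOLOGY_FEATURES

#: Scale factor making the median absolute deviation a consistent SD estimate.
MAD_TO_SD = 1.4826022185056018


def aggregate_wells(cells: pd.DataFrame, layout: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-cell records to one profile per layout well.

    Features are per-well medians; ``cell_count`` is the number of cell rows.
    Wells with no cells appear with count 0 and undefined (NaN) features.
    """
    known = set(zip(layout["plate"], layout["well"]))
    orphan = [
        pw for pw in zip(cells["plate"], cells["well"]) if pw not in known
    ]
    if orphan:
        raise ValueError(
            f"{len(orphan)} cell rows reference wells absent from the layout, "
            f"e.g. {orphan[0]}"
        )
    idx = pd.MultiIndex.from_frame(
        layout[["plate", "well"]].drop_duplicates(), names=["plate", "well"]
    )
    grouped = cells.groupby(["plate", "well"])
    medians = grouped[list(MORPHOLOGY_FEATURES)].median().reindex(idx)
    counts = grouped.size().reindex(idx, fill_value=0)
    out = medians.copy()
    out.insert(0, "cell_count", counts.astype(int))
    return out.reset_index()


@dataclass(frozen=True)
class ZScoreMatrix:
    """siRNA x feature Z scores with per-plate control statistics for audit.

    values: one row per (siRNA, arm), columns = features, entries = median of
    replicate-well Z values. well_z: the underlying per-well Z table.
    control_stats: per (plate, feature) control mean and SD.
    """

    values: pd.DataFrame
    well_z: pd.DataFrame
    control_stats: pd.DataFrame


def compute_zscores(
    profiles: pd.DataFrame,
    layout: pd.DataFrame,
    control_label: str = CONTROL_LABEL,
    robust: bool = False,
) -> ZScoreMatrix:
    """Z scores of well profiles against same-plate control wells.

    Z = (value - control mean) / control SD per plate and feature, using the
    unbiased sample SD over control wells (or median / 1.4826*MAD with
    ``robust``). A feature whose control SD is 0 on a plate is flagged
    undefined (NaN) there with a warning. Per-siRNA Z is the median of its
    replicate-well Z values within an arm.
    """
    merged = profiles.merge(layout, on=["plate", "well"], validate="one_to_one")
    feats = [f for f in FEATURES if f in merged.columns]
    stats_rows, z_frames = [], []
    for plate, grp in merged.groupby("plate", sort=True):
        ctrl = grp[grp["sirna"] == control_label]
        ctrl = ctrl[ctrl[feats].notna().all(axis=1)]
        if len(ctrl) < 2:
            raise ValueError(
                f"plate {plate!r} has {len(ctrl)} usable {control_label!r} "
                "control wells; >= 2 required"
            )
        z = grp.copy()
        for f in feats:
            if robust:
                mean = float(ctrl[f].median())
                sd = float(MAD_TO_SD * (ctrl[f] - mean).abs().median())
            else:
                mean = float(ctrl[f].mean())
                sd = float(ctrl[f].std(ddof=1))
            stats_rows.append((plate, f, mean, sd))
            if sd == 0:
                warnings.warn(
                    f"control SD is 0 for {f!r} on plate {plate!r}; Z undefined"
                )
                z[f] = np.nan
            else:
                z[f] = (grp[f] - mean) / sd
        z_frames.append(z)
    well_z = pd.concat(z_frames, ignore_index=True)
    control_stats = pd.DataFrame(
        stats_rows, columns=["plate", "feature", "control_mean", "control_sd"]
    )
    values = (
        well_z.groupby(["sirna", "arm"], sort=True)[feats].median().sort_index()
    )
    return ZScoreMatrix(values=values, well_z=well_z, control_stats=control_stats)


def score_reversal(
    zrow,
    signature: dict[str, int] = REVERSAL_SIGNATURE,
    z_threshold: float = 2.0,
    min_morph_features: int = 3,
):
    """Score one Z row against the reversal signature.

    Returns ``(hit, n_matched)`` where ``hit`` is True/False, or None when the
    cell-count Z is undefined (no call possible). A morphology feature matches
    when its Z has the signature sign and |Z| >= z_threshold; a hit requires
    Z(cell_count) >= z_threshold and >= min_morph_features matches.
    """
    if "cell_count" not in signature:
        raise ValueError("signature must include cell_count")
    if "cell_count" not in zrow:
        raise ValueError("Z row lacks cell_count")
    z_count = zrow["cell_count"]
    morph = [f for f in signature if f != "cell_count"]
    matched = sum(
        1
        for f in morph
        if f in zrow
        and np.isfinite(zrow[f])
        and abs(zrow[f]) >= z_threshold
        and np.sign(zrow[f]) == signature[f]
    )
    if not np.isfinite(z_count):
        return None, matched
    hit = bool(z_count >= z_threshold and matched >= min_morph_features)
    return hit, matched


def call_hits(
    z: ZScoreMatrix,
    signature: dict[str, int] = REVERSAL_SIGNATURE,
    z_threshold: float = 2.0,
    min_morph_features: int = 3,
) -> pd.DataFrame:
    """One hit call per (siRNA, arm), excluding the control pseudo-arm.

    Adds a dose-dependence flag on cell-count Z for siRNAs present at both
    the 30 nM (Group1) and 60 nM (Group1B) doses.
    """
    rows = []
    vals = z.values[z.values.index.get_level_values("arm") != "control"]
    for (sirna, arm), zrow in vals.iterrows():
        hit, matched = score_reversal(zrow, signature, z_threshold, min_morph_features)
        rows.append(
            {
                "sirna": sirna,
                "arm": arm,
                "hit": hit,
                "z_cell_count": zrow["cell_count"],
                "n_matched": matched,
            }
        )
    hits = pd.DataFrame(rows)
    hits["dose_dependent"] = pd.array([None] * len(hits), dtype="boolean")
    by_arm = z.values.reset_index().set_index(["sirna", "arm"])
    for i, row in hits.iterrows():
        if row["arm"] != "Group1":
            continue
        key_hi = (row["sirna"], "Group1B")
        if key_hi in by_arm.index:
            flag = assess_dose_dependence(
                by_arm.loc[(row["sirna"], "Group1"), "cell_count"],
                by_arm.loc[key_hi, "cell_count"],
                z_threshold=z_threshold,
            )
            hits.loc[i, "dose_dependent"] = flag
    return hits.sort_values(["sirna", "arm"], kind="mergesort").reset_index(drop=True)


def summarize_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Per-arm hit counts and rates."""
    out = (
        hits.groupby("arm")
        .agg(n_sirna=("sirna", "nunique"), n_hits=("hit", lambda s: int(s.fillna(False).sum())))
        .reset_index()
    )
    out["hit_rate"] = out["n_hits"] / out["n_sirna"]
    return out


def assess_dose_dependence(z_low: float, z_high: float, z_threshold: float = 2.0):
    """Dose-dependent iff both Z exceed the threshold in magnitude, share a
    sign, and the high dose is at least as strong; None if either undefined."""
    if not (np.isfinite(z_low) and np.isfinite(z_high)):
        return None
    return bool(
        abs(z_low) >= z_threshold
        and abs(z_high) >= z_threshold
        and np.sign(z_low) == np.sign(z_high)
        and abs(z_high) >= abs(z_low)
    )


ARM_CLASSES = ("independent", "requires-p16", "requires-p21", "multi-arm", "non-hit")


def compare_arms(hits: pd.DataFrame) -> pd.DataFrame:
    """Classify each siRNA by the arm pattern of its hits.

    A Group1 hit reverses senescence on its own ("independent") regardless of
    other arms; otherwise a hit only with co-depletion of p16 (Group2) or p21
    (Group3) is labelled accordingly; hits in both co-depletion arms but not
    alone are "multi-arm"; no hits anywhere is "non-hit".
    """
    flag = (
        hits.assign(hit=hits["hit"].fillna(False))
        .pivot_table(index="sirna", columns="arm", values="hit", aggfunc="any")
        .reindex(columns=["Group1", "Group1B", "Group2", "Group3"], fill_value=False)
        .fillna(False)
        .astype(bool)
    )
    def classify(r):
        if r["Group1"]:
            return "independent"
        if r["Group2"] and r["Group3"]:
            return "multi-arm"
        if r["Group2"]:
            return "requires-p16"
        if r["Group3"]:
            return "requires-p21"
        return "non-hit"

    out = flag.apply(classify, axis=1).rename("classification").reset_index()
    return out.sort_values("sirna", kind="mergesort").reset_index(drop=True)
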