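import numpy as np
import pandas as pd
import pytest

from senrev import (
    DEFAULT_PARAMS,
    REVERSAL_SIGNATURE,
    EffectMap,
    LayoutSpec,
    aggregate_wells,
    assess_dose_dependence,
    call_hits,
    compare_arms,
    compute_zscores,
    generate_screen,
    score_reversal,
    summarize_hits,
)
from senrev.io_formats import MORPHOLOGY_FEATURES
from senrev.screen import FEATURES


def _profiles(rows):
    return pd.DataFrame(
        rows, columns=["plate", "well", "cell_count", *MORPHOLOGY_FEATURES]
    )


def _layout(wells_sirnas, plate="P1", arm="Group1"):
    return pd.DataFrame(
        {
            "plate": plate,
            "well": [w for w, _ in wells_sirnas],
            "sirna": [s for _, s in wells_sirnas],
            "dose_nM": 30.0,
            "arm": [("control" if s == "siGLO" else arm) for _, s in wells_sirnas],
            "replicate": 1,
        }
    )


def test_aggregate_well_median_and_empty(tiny_layout):
    cells = pd.DataFrame(
        {
            "plate": "P1",
            "well": "A1",
            "cell_index": [0, 1, 2],
            **{f: [100.0, 200.0, 300.0] for f in MORPHOLOGY_FEATURES},
        }
    )
    prof = aggregate_wells(cells, tiny_layout)
    a1 = prof.set_index("well").loc["A1"]
    a2 = prof.set_index("well").loc["A2"]
    assert a1["cell_count"] == 3 and a1["cell_area"] == 200.0
    assert a2["cell_count"] == 0 and np.isnan(a2["cell_area"])


def test_aggregate_rejects_orphan_cells(tiny_layout):
    cells = pd.DataFrame(
        {
            "plate": "P1",
            "well": "B9",
            "cell_index": [0],
            **{f: [1.0] for f in MORPHOLOGY_FEATURES},
        }
    )
    with pytest.raises(ValueError, match="absent"):
        aggregate_wells(cells, tiny_layout)


def test_aggregate_matches_naive_loop(small_screen):
    cells, layout, _ = small_screen
    prof = aggregate_wells(cells, layout).set_index(["plate", "well"])
    for (plate, well) in layout[["plate", "well"]].itertuples(index=False):
        sub = cells[(cells["plate"] == plate) & (cells["well"] == well)]
        row = prof.loc[(plate, well)]
        assert row["cell_count"] == len(sub)
        for f in MORPHOLOGY_FEATURES:
            if len(sub):
                assert row[f] == pytest.approx(float(np.median(sub[f])))
            else:
                assert np.isnan(row[f])


def test_zscore_formula_forced_values():
    rows = [
        ("P1", "A1", 90, *[90.0] * 6),
        ("P1", "A2", 100, *[100.0] * 6),
        ("P1", "A3", 110, *[110.0] * 6),
        ("P1", "A4", 120, *[120.0] * 6),
        ("P1", "A5", 100, *[100.0] * 6),
    ]
    layout = _layout(
        [("A1", "siGLO"), ("A2", "siGLO"), ("A3", "siGLO"), ("A4", "siX"), ("A5", "siY")]
    )
    z = compute_zscores(_profiles(rows), layout)
    assert z.values.loc[("siX", "Group1")].tolist() == pytest.approx([2.0] * 7)
    assert z.values.loc[("siY", "Group1")].tolist() == pytest.approx([0.0] * 7)
    stats = z.control_stats.set_index("feature")
    assert stats.loc["cell_count", "control_mean"] == 100.0
    assert stats.loc["cell_count", "control_sd"] == 10.0


def test_control_self_normalisation(small_screen):
    cells, layout, _ = small_screen
    z = compute_zscores(aggregate_wells(cells, layout), layout)
    ctrl = z.well_z[z.well_z["sirna"] == "siGLO"]
    for plate, grp in ctrl.groupby("plate"):
        for f in FEATURES:
            assert abs(grp[f].mean()) < 1e-9
            assert abs(grp[f].std(ddof=1) - 1) < 1e-9


def test_zscore_scale_invariance(small_screen):
    cells, layout, _ = small_screen
    prof = aggregate_wells(cells, layout)
    z1 = compute_zscores(prof, layout)
    scaled = prof.copy()
    scaled["cell_area"] = scaled["cell_area"] * 7.3
    z2 = compute_zscores(scaled, layout)
    pd.testing.assert_frame_equal(z1.values, z2.values)


def test_zscore_matches_naive_oracle_small_plate():
    """On a 24-well plate the Z matrix equals an independently coded naive
    per-plate implementation exactly."""
    rng = np.random.default_rng(42)
    wells = [f"{r}{c}" for r in "AB" for c in range(1, 13)]
    sirnas = ["siGLO"] * 6 + [f"si{i:02d}" for i in range(18)]
    layout = _layout(list(zip(wells, sirnas)))
    rows = [
        ("P1", w, int(rng.integers(50, 150)), *rng.normal(100, 15, 6))
        for w in wells
    ]
    prof = _profiles(rows)
    z = compute_zscores(prof, layout)

    merged = prof.merge(layout, on=["plate", "well"])
    ctrl = merged[merged["sirna"] == "siGLO"]
    for _, row in merged.iterrows():
        for f in FEATURES:
            mu = ctrl[f].mean()
            sd = np.sqrt(((ctrl[f] - mu) ** 2).sum() / (len(ctrl) - 1))
            expected = (row[f] - mu) / sd
            got = z.values.loc[(row["sirna"], row["arm"]), f]
            if row["sirna"] != "siGLO":
                assert got == pytest.approx(expected, abs=1e-12)


def test_zscore_control_sd_zero_flagged():
    rows = [
        ("P1", "A1", 90, 5.0, *[100.0] * 5),
        ("P1", "A2", 110, 5.0, *[110.0] * 5),
        ("P1", "A3", 120, 5.0, *[120.0] * 5),
    ]
    layout = _layout([("A1", "siGLO"), ("A2", "siGLO"), ("A3", "siX")])
    with pytest.warns(UserWarning, match="control SD is 0"):
        z = compute_zscores(_profiles(rows), layout)
    assert np.isnan(z.values.loc[("siX", "Group1"), "cell_area"])
    assert np.isfinite(z.values.loc[("siX", "Group1"), "cell_count"])


def test_zscore_requires_two_controls(tiny_layout):
    prof = _profiles([("P1", "A1", 100, *[1.0] * 6), ("P1", "A2", 100, *[1.0] * 6)])
    with pytest.raises(ValueError, match="control wells"):
        compute_zscores(prof, tiny_layout)


def test_robust_zscore_median_mad():
    rows = [
        ("P1", "A1", 90, *[90.0] * 6),
        ("P1", "A2", 100, *[100.0] * 6),
        ("P1", "A3", 110, *[110.0] * 6),
        ("P1", "A4", 120, *[120.0] * 6),
    ]
    layout = _layout(
        [("A1", "siGLO"), ("A2", "siGLO"), ("A3", "siGLO"), ("A4", "siX")]
    )
    z = compute_zscores(_profiles(rows), layout, robust=True)
    # median 100, MAD 10 -> sd 14.826; Z = 20/14.826
    assert z.values.loc[("siX", "Group1"), "cell_count"] == pytest.approx(
        20 / 14.826022185056018
    )


def test_score_reversal_examples():
    feats = ["cell_count", "cell_area", "nuclear_area", "nuclear_elongation",
             "nuclear_roundness", "cell_elongation"]
    full = dict(zip(feats, [3, -3, -3, -3, 3, 3]))
    assert score_reversal(full) == (True, 5)
    zero = dict.fromkeys(feats, 0.0)
    assert score_reversal(zero) == (False, 0)
    count_only = dict(zero, cell_count=2.5)
    assert score_reversal(count_only) == (False, 0)
    undef = dict(full, cell_count=np.nan)
    hit, matched = score_reversal(undef)
    assert hit is None and matched == 5


def test_score_reversal_needs_cell_count():
    with pytest.raises(ValueError):
        score_reversal({"cell_area": -3.0})


def test_call_hits_recovery_and_summary(small_screen):
    cells, layout, truth = small_screen
    z = compute_zscores(aggregate_wells(cells, layout), layout)
    hits = call_hits(z)
    called = set(hits.loc[hits["hit"] == True, "sirna"])  # noqa: E712
    planted = set(truth.loc[truth["is_reverser"], "sirna"])
    assert planted <= called
    assert len(called - planted) <= 2  # <= 5% of 40
    summary = summarize_hits(hits)
    assert summary.loc[summary["arm"] == "Group1", "n_sirna"].iloc[0] == 40
    assert "control" not in set(hits["arm"])


def test_replicate_median_z_tracks_planted_effect():
    """A planted -3 SD cell-area shift is recovered as median Z within 0.5 of
    -3 across seeds."""
    lib = [f"si{i:02d}" for i in range(12)]
    eff = EffectMap(shifts={"si00": {"cell_area": -3.0}})
    zs = []
    for seed in range(20):
        cells, layout, _ = generate_screen(
            lib, LayoutSpec(arms=("Group1",), replicates=3),
            DEFAULT_PARAMS, eff, seed=200 + seed,
        )
        z = compute_zscores(aggregate_wells(cells, layout), layout)
        zs.append(z.values.loc[("si00", "Group1"), "cell_area"])
    assert abs(np.median(zs) + 3.0) < 0.5


@pytest.mark.parametrize(
    "z_low,z_high,expected",
    [
        (-2.0, -4.0, True),
        (-2.0, -1.0, False),
        (2.0, -4.0, False),
        (-4.0, -2.5, False),
        (np.nan, -4.0, None),
    ],
)
def test_dose_dependence(z_low, z_high, expected):
    assert assess_dose_dependence(z_low, z_high) is expected


def test_call_hits_flags_dose_dependence():
    lib = [f"si{i:02d}" for i in range(12)]
    eff = EffectMap(shifts={"si00": {"cell_count": 3.0, "cell_area": -3.0}})
    cells, layout, _ = generate_screen(
        lib, LayoutSpec(arms=("Group1", "Group1B"), replicates=2),
        DEFAULT_PARAMS, eff, seed=5,
    )
    z = compute_zscores(aggregate_wells(cells, layout), layout)
    hits = call_hits(z).set_index(["sirna", "arm"])
    assert hits.loc[("si00", "Group1"), "dose_dependent"] in (True, False)
    assert pd.isna(hits.loc[("si00", "Group1B"), "dose_dependent"])


def _hitframe(pattern):
    rows = []
    for sirna, arms in pattern.items():
        for arm in ("Group1", "Group2", "Group3"):
            rows.append({"sirna": sirna, "arm": arm, "hit": arm in arms})
    return pd.DataFrame(rows)


def test_compare_arms_classification():
    hits = _hitframe(
        {
            "egr2": {"Group1", "Group3"},
            "fras1": {"Group2"},
            "s100": {"Group3"},
            "both": {"Group2", "Group3"},
            "dud": set(),
        }
    )
    classes = compare_arms(hits).set_index("sirna")["classification"]
    assert classes["egr2"] == "independent"
    assert classes["fras1"] == "requires-p16"
    assert classes["s100"] == "requires-p21"
    assert classes["both"] == "multi-arm"
    assert classes["dud"] == "non-hit"
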