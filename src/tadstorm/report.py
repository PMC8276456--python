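"""Group comparison, significance tiers and the end-to-end pipeline runner.

Significance uses an unpaired two-sample parametric t test with the tier
convention ****P < 0.0001, ***P < 0.0005, **P < 0.01, *P < 0.05, N.S.
otherwise.  Summaries come in the scatter convention (mean +- sd) and the
box convention (median, quartiles, whiskers at the most extreme
observations within 1.5x the interquartile range of the box limits).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import AnalysisConfig
from .model import LocalizationTable
from .segment import DBSCANParams, dbscan
from . import simulate, spatstats

TIERS = ((1e-4, "****"), (5e-4, "***"), (1e-2, "**"), (5e-2, "*"))


def assign_tier(p: float) -> str:
    """Significance tier as a pure function of the two-sided P value."""
    if not 0 <= p <= 1:
        raise ValueError(f"P = {p} outside [0, 1]")
    for cutoff, tier in TIERS:
        if p < cutoff:
            return tier
    return "N.S."


@dataclass
class TestResult:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t: float
    df: float
    p: float
    tier: str
    variant: str


def t_test(a, b, variant: str = "student",
           labels=("a", "b")) -> TestResult:
    """Unpaired two-sample t test (Student pooled or Welch)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("zero variance in both groups")
    if variant == "student":
        res = sps.ttest_ind(a, b, equal_var=True)
        df = len(a) + len(b) - 2
    elif variant == "welch":
        res = sps.ttest_ind(a, b, equal_var=False)
        na, nb = len(a), len(b)
        df = ((va / na + vb / nb) ** 2
              / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)))
    else:
        raise ValueError(f"unknown variant '{variant}'")
    p = float(res.pvalue)
    if np.isnan(p):      # identical constant groups: no evidence at all
        t_stat, p = 0.0, 1.0
    else:
        t_stat = float(res.statistic)
    return TestResult(group_a=labels[0], group_b=labels[1],
                      n_a=len(a), n_b=len(b),
                      mean_a=float(a.mean()), mean_b=float(b.mean()),
                      sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
                      t=t_stat, df=float(df), p=p, tier=assign_tier(p),
                      variant=variant)


def summarize(df: pd.DataFrame, value: str, group: str) -> pd.DataFrame:
    """Per-group scatter (mean +- sd) and box (median/quartiles/whiskers)
    summaries."""
    rows = []
    for name, sub in df.groupby(group, sort=True):
        vals = sub[value].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            warnings.warn(f"group {name!r} is empty; omitted")
            continue
        q25, med, q75 = np.percentile(vals, [25, 50, 75])
        iqr = q75 - q25
        inside = vals[(vals >= q25 - 1.5 * iqr) & (vals <= q75 + 1.5 * iqr)]
        rows.append({group: name, "n": len(vals),
                     "mean": vals.mean(),
                     "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                     "median": med, "q25": q25, "q75": q75,
                     "whisker_lo": inside.min(), "whisker_hi": inside.max()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end pipeline

DEFAULT_PRESETS = ("g1s_peripheral", "g1_uniform", "interior")


def analyze_cell(table: LocalizationTable, config: AnalysisConfig,
                 cell_id: str = "") -> pd.DataFrame:
    """Segment one dual-color cell and compute its focus-TAD statistics.

    The TAD channel ("561") is segmented with the TAD DBSCAN parameters
    (largest cluster taken as the TAD); the focus channel ("647") with the
    focus parameters.  Returns one row per kept focus-TAD pair.
    """
    dims = "3d" if config.dimensionality == "3d" else "2d"
    seg = config.segmentation
    tp = seg["tad"]
    fp = seg["foci"]
    tads, _ = dbscan(table.select_channel("561"),
                     DBSCANParams(r=tp["r"], n_min=tp["n_min"],
                                  r_ref=tp["r_ref"]), dims=dims)
    foci_table = table.select_channel("647")
    foci, _ = dbscan(
        foci_table, DBSCANParams(r=fp["r"], n_min=fp["n_min"],
                                 r_ref=fp["r_ref"]), dims=dims)
    if not tads:
        return pd.DataFrame()
    tad = max(tads, key=lambda c: c.n_detections)
    pairs, _ = spatstats.assign_foci(foci, [tad])
    rows = []
    for fi, _ti in pairs:
        raw, norm = spatstats.barycenter_distance(
            foci[fi], tad, convention=config.convention)
        members = foci_table.subset(foci[fi].indices)
        rdd_val = spatstats.rdd(
            members, tad, tendency=config.tendency,
            normalizer="rg" if config.convention == "rg"
            else "half_major_axis", dims=dims)
        rows.append({"cell_id": cell_id, "focus_id": fi, "tad_id": 0,
                     "raw_distance_nm": raw,
                     "normalized_distance": norm, "rdd": rdd_val,
                     "convention": config.convention,
                     "focus_detections": foci[fi].n_detections,
                     "tad_detections": tad.n_detections,
                     "tad_rg_nm": tad.rg,
                     "tad_major_axis_nm": tad.major_axis})
    return pd.DataFrame(rows)


def run_pipeline(config: AnalysisConfig, out_dir=None,
                 presets=None) -> dict:
    """Simulate -> segment -> spatial statistics -> group report.

    One synthetic experiment per preset (``n_cells`` cells each), with the
    per-cell mean normalized barycenter distance as the unit of the group
    comparison.  All outputs (pair table, per-cell table, summaries,
    t tests, manifest with the resolved config and seed) are written under
    ``out_dir`` and the key results returned.
    """
    sim = config.simulation
    presets = list(presets or sim.get("presets") or DEFAULT_PRESETS)
    out_dir = Path(out_dir or config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    tad_spec = simulate.TadSpec(
        radius=float(sim["tad_radius"]),
        n_localizations=int(sim["n_tad_localizations"]),
        precision=tuple(sim["precision"]))
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(presets) * int(sim["n_cells"]))

    pair_frames = []
    for pi, preset in enumerate(presets):
        for ci in range(int(sim["n_cells"])):
            child = children[pi * int(sim["n_cells"]) + ci]
            seed = int(child.generate_state(1)[0] % (2 ** 31))
            table, _truth = simulate.simulate_cell(
                preset=preset, seed=seed, tad_spec=tad_spec,
                n_foci=int(sim["n_foci"]),
                focus_diameter=float(sim["focus_diameter"]),
                locs_per_focus=int(sim["locs_per_focus"]))
            df = analyze_cell(table, config, cell_id=f"{preset}_{ci:03d}")
            if len(df):
                df.insert(0, "preset", preset)
                pair_frames.append(df)
    pairs = pd.concat(pair_frames, ignore_index=True) if pair_frames \
        else pd.DataFrame()

    cells = (pairs.groupby(["preset", "cell_id"], sort=True)
             ["normalized_distance"].mean().reset_index()
             .rename(columns={"normalized_distance": "mean_distance"}))

    geometry = ("uniform_ball_3d" if config.dimensionality == "3d"
                else "uniform_ball_projected")
    null = spatstats.null_distance(geometry, statistic="mean",
                                   normalizer="R" if config.convention ==
                                   "half_major_axis" else "rg")

    tests = []
    for i in range(len(presets)):
        for j in range(i + 1, len(presets)):
            a = cells[cells.preset == presets[i]]["mean_distance"]
            b = cells[cells.preset == presets[j]]["mean_distance"]
            if len(a) >= 2 and len(b) >= 2:
                tests.append(asdict(t_test(a, b, labels=(presets[i],
                                                         presets[j]))))
    tests = pd.DataFrame(tests)
    summary = summarize(cells, "mean_distance", "preset") if len(cells) \
        else pd.DataFrame()

    pairs.to_csv(out_dir / "pairstats.csv", index=False)
    cells.to_csv(out_dir / "cells.csv", index=False)
    summary.to_csv(out_dir / "summary.csv", index=False)
    tests.to_csv(out_dir / "ttests.csv", index=False)
    manifest = {"config": config.to_dict(), "seed": config.seed,
                "presets": presets,
                "null": {"geometry": null.geometry, "value": null.value,
                         "statistic": null.statistic,
                         "normalizer": null.normalizer}}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {"pairs": pairs, "cells": cells, "summary": summary,
            "tests": tests, "null": null, "out_dir": out_dir}
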