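"""Group-level morphometric reporting and the end-to-end pipeline.

Aggregates qualified-cell measurements by experimental group (mean, SD, SEM),
computes percent changes versus the control group, and runs the standard
group-comparison tests (Kruskal-Wallis with Dunn's post hoc, one-way ANOVA
with Tukey's post hoc, Mann-Whitney U, Fisher's exact; significance at
p < 0.05).  Only rows with ``qualified = 1`` enter the statistics — the
qualification flag is the single gate between measurement and reporting.

:func:`run_pipeline` chains the whole workflow on synthetic fields or input
TIFFs: segment -> measure -> classify -> summarize -> compare, writing
deterministic CSV/JSON outputs (re-running an identical config reproduces
byte-identical files).
"""

from __future__ import annotations

import json
import logging
import pathlib

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .benchmark import labeled_benchmark_table
from .descriptors import measure_all
from .qc import QCClassifier, classify, train_qc
from .segmentation import segment
from .synth import (DEFAULT_FIELD_PX, DEFAULT_PIXEL_UM, GROUP_PARAMS,
                    place_population, render_scene, sample_population)

log = logging.getLogger(__name__)

SIGNIFICANCE_LEVEL = 0.05

#: Features reported in group summaries by default.
DEFAULT_SUMMARY_FEATURES = [
    "area_um2", "width_um", "length_um", "aspect_ratio",
    "perimeter_um", "circularity", "roundness", "solidity",
]


def percent_change(control_mean: float, group_mean: float) -> float:
    """100 * (group - control) / control."""
    if control_mean == 0:
        raise ValueError("control mean is zero; percent change undefined")
    return 100.0 * (group_mean - control_mean) / control_mean


def summarize_groups(measurements: pd.DataFrame,
                     features: list[str] | None = None,
                     qualified_only: bool = True,
                     group_col: str = "group",
                     n_animals: dict[str, int] | None = None) -> pd.DataFrame:
    """Per group x feature: n, mean, SD, SEM (rows with ``qualified = 1``
    only, unless ``qualified_only=False``).

    A single-cell group reports SD (and SEM) of 0.
    """
    if group_col not in measurements.columns:
        raise ValueError(f"missing group column {group_col!r}")
    df = measurements
    if qualified_only:
        if "qualified" not in df.columns:
            raise ValueError("qualified column absent; classify first or "
                             "pass qualified_only=False")
        df = df[df["qualified"] == 1]
    features = features or [f for f in DEFAULT_SUMMARY_FEATURES
                            if f in df.columns]
    missing = [f for f in features if f not in df.columns]
    if missing:
        raise ValueError(f"unknown feature(s): {', '.join(missing)}")
    rows = []
    for group, gdf in df.groupby(group_col, sort=True):
        for feat in features:
            vals = gdf[feat].to_numpy(dtype=float)
            n = len(vals)
            if n == 0:
                continue
            sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
            rows.append({
                "group": group, "feature": feat, "n_cells": n,
                "n_animals": (n_animals or {}).get(group, np.nan),
                "mean": float(vals.mean()), "sd": sd,
                "sem": sd / np.sqrt(n),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group comparisons

def _dunn_vs_control(groups: dict[str, np.ndarray], control: str) -> dict[str, float]:
    """Dunn's rank-based post hoc z-test of each group against control,
    Bonferroni-adjusted over the control comparisons."""
    names = list(groups)
    all_vals = np.concatenate([groups[g] for g in names])
    ranks = sps.rankdata(all_vals)
    n_total = all_vals.size
    # tie correction: sum(t^3 - t) over tied groups
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = float(((counts ** 3) - counts).sum())
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    mean_ranks = {}
    i = 0
    for g in names:
        k = groups[g].size
        mean_ranks[g] = ranks[i:i + k].mean()
        i += k
    m = len(names) - 1  # comparisons vs control
    out = {}
    for g in names:
        if g == control:
            continue
        se = np.sqrt(var_base * (1.0 / groups[g].size + 1.0 / groups[control].size))
        z = (mean_ranks[g] - mean_ranks[control]) / se
        out[g] = float(min(1.0, 2.0 * sps.norm.sf(abs(z)) * m))
    return out


def _tukey_vs_control(groups: dict[str, np.ndarray], control: str) -> dict[str, float]:
    import itertools

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    vals = np.concatenate(list(groups.values()))
    labs = np.concatenate([[g] * groups[g].size for g in groups])
    res = pairwise_tukeyhsd(vals, labs, alpha=SIGNIFICANCE_LEVEL)
    pairs = itertools.combinations(res.groupsunique, 2)  # tukeyhsd pair order
    out = {}
    for (g1, g2), p in zip(pairs, res.pvalues):
        if control in (g1, g2):
            other = g2 if g1 == control else g1
            out[other] = float(p)
    return out


def fisher_exact_test(table: np.ndarray) -> float:
    """Fisher's exact p-value of a 2x2 count table."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("fisher_exact requires a 2x2 count table")
    return float(sps.fisher_exact(table)[1])


def compare_groups(measurements: pd.DataFrame, feature: str,
                   test: str = "kruskal_dunn",
                   control: str = "Control",
                   group_col: str = "group",
                   qualified_only: bool = True) -> pd.DataFrame:
    """Omnibus + pairwise-vs-control comparison of one feature.

    Returns one row per group with the percent change of the group mean
    versus the control mean, the test name and the pairwise p-value
    (control row: change 0, p-value NaN).  The omnibus p-value is repeated
    in the ``omnibus_p`` column.
    """
    df = measurements
    if qualified_only and "qualified" in df.columns:
        df = df[df["qualified"] == 1]
    if feature not in df.columns:
        raise ValueError(f"unknown feature {feature!r}")
    if group_col not in df.columns:
        raise ValueError(f"missing group column {group_col!r}")
    groups = {g: gdf[feature].to_numpy(dtype=float)
              for g, gdf in df.groupby(group_col, sort=True)}
    if control not in groups:
        raise ValueError(f"control group {control!r} absent")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if test in ("kruskal_dunn", "mann_whitney"):
        small = [g for g, v in groups.items() if v.size < 2]
        if small:
            raise ValueError(f"group(s) with n < 2: {', '.join(small)}")

    others = [g for g in groups if g != control]
    if test == "kruskal_dunn":
        omnibus = float(sps.kruskal(*groups.values()).pvalue)
        pvals = _dunn_vs_control(groups, control)
    elif test == "anova_tukey":
        omnibus = float(sps.f_oneway(*groups.values()).pvalue)
        pvals = _tukey_vs_control(groups, control)
    elif test == "mann_whitney":
        pvals = {g: float(sps.mannwhitneyu(groups[g], groups[control],
                                           alternative="two-sided").pvalue)
                 for g in others}
        omnibus = min(min(pvals.values()) * len(pvals), 1.0) if pvals else np.nan
    elif test == "fisher_exact":
        pvals = {}
        for g in others:
            tab = np.array([
                [(groups[control] > 0).sum(), (groups[control] <= 0).sum()],
                [(groups[g] > 0).sum(), (groups[g] <= 0).sum()]])
            pvals[g] = fisher_exact_test(tab)
        omnibus = min(min(pvals.values()) * len(pvals), 1.0) if pvals else np.nan
    else:
        raise ValueError(f"unknown test {test!r}")

    cmean = groups[control].mean()
    rows = [{"feature": feature, "group": control,
             "n_cells": int(groups[control].size),
             "percent_change_vs_control": 0.0,
             "test_name": test, "p_value": np.nan, "omnibus_p": omnibus,
             "significant": False}]
    for g in others:
        pc = percent_change(cmean, groups[g].mean())
        rows.append({"feature": feature, "group": g,
                     "n_cells": int(groups[g].size),
                     "percent_change_vs_control": pc,
                     "test_name": test, "p_value": pvals[g],
                     "omnibus_p": omnibus,
                     "significant": bool(pvals[g] < SIGNIFICANCE_LEVEL)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline

DEFAULT_PIPELINE_CONFIG = {
    "mode": "synth",
    "groups": {"Control": "control", "Ang": "ang", "Iso": "iso", "Old": "old"},
    "n_cells_per_group": 200,
    "class_proportions": {"intact_rod": 0.94, "touching_pair": 0.03,
                          "rounded": 0.03},
    "field_size_px": list(DEFAULT_FIELD_PX),
    "pixel_size_um": DEFAULT_PIXEL_UM,
    "noise_sd": 0.05,
    "cells_per_field": 18,
    "seed": 1,
    "qc_model": None,            # path to a model JSON, or None to train
    "qc_train_n": 600,
    "test": "kruskal_dunn",
    "control_group": "Control",
    "features": ["area_um2", "width_um", "length_um", "aspect_ratio"],
    "segmentation": {},          # overrides for segment() keyword args
}


def _stage(name: str, context: str):
    """Context manager that re-raises stage failures with stage + input id."""
    import contextlib

    @contextlib.contextmanager
    def cm():
        try:
            yield
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed for "
                               f"{context}: {exc}") from exc
    return cm()


def run_pipeline(config: dict | None = None, out_dir="pipeline_out") -> pathlib.Path:
    """Execute the full workflow and write its outputs.

    Outputs in ``out_dir``: ``cells.csv`` (per-cell measurements with the
    0/1 qualified flag, full precision), ``group_summary.csv`` (2-decimal
    table) plus ``group_summary_raw.csv``, ``comparisons.csv`` and
    ``run_log.json`` (config, seeds, stage tallies).  Identical configs
    produce byte-identical outputs.
    """
    cfg = dict(DEFAULT_PIPELINE_CONFIG)
    cfg.update(config or {})
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    rng = np.random.default_rng(seed)
    run_log: dict = {"config": cfg, "package_version": __version__,
                     "images": []}

    tables = []
    if cfg["mode"] == "synth":
        for gi, (gname, gparams) in enumerate(sorted(cfg["groups"].items())):
            pop_seed = seed + 1000 * (gi + 1)
            with _stage("synth", f"group {gname}"):
                specs = sample_population(
                    gparams, int(cfg["n_cells_per_group"]),
                    cfg["class_proportions"], seed=pop_seed)
                fields = place_population(
                    specs, tuple(cfg["field_size_px"]), cfg["pixel_size_um"],
                    cells_per_field=int(cfg["cells_per_field"]),
                    seed=pop_seed + 1)
            for fi, fspecs in enumerate(fields):
                image_id = f"{gname}_f{fi:03d}"
                with _stage("render", f"image {image_id}"):
                    scene = render_scene(
                        tuple(cfg["field_size_px"]), cfg["pixel_size_um"],
                        fspecs, noise_sd=cfg["noise_sd"],
                        seed=pop_seed + 2 + fi)
                with _stage("segment", f"image {image_id}"):
                    particles = segment(scene.image, **cfg["segmentation"])
                with _stage("measure", f"image {image_id}"):
                    table = measure_all(particles)
                table.insert(0, "image_id", image_id)
                table.insert(0, "group", gname)
                tables.append(table)
                run_log["images"].append(
                    {"image_id": image_id, "group": gname,
                     "n_specs": len(fspecs),
                     "n_particles": int(particles.n_particles)})
    elif cfg["mode"] == "images":
        from .image import read_tiff

        for entry in cfg["images"]:
            image_id = pathlib.Path(entry["path"]).stem
            with _stage("read", f"image {image_id}"):
                img = read_tiff(entry["path"],
                                pixel_size_um=cfg.get("pixel_size_um"))
            with _stage("segment", f"image {image_id}"):
                particles = segment(img, **cfg["segmentation"])
            with _stage("measure", f"image {image_id}"):
                table = measure_all(particles)
            table.insert(0, "image_id", image_id)
            table.insert(0, "group", entry["group"])
            tables.append(table)
            run_log["images"].append(
                {"image_id": image_id, "group": entry["group"],
                 "n_particles": int(particles.n_particles)})
    else:
        raise ValueError(f"unknown pipeline mode {cfg['mode']!r}")

    cells = (pd.concat(tables, ignore_index=True) if tables
             else pd.DataFrame())

    with _stage("classify", "measurement table"):
        if cfg["qc_model"]:
            model = QCClassifier.load(cfg["qc_model"])
            run_log["qc"] = {"model": str(cfg["qc_model"])}
        else:
            bench = labeled_benchmark_table(
                n_cells=int(cfg["qc_train_n"]),
                pixel_size_um=cfg["pixel_size_um"],
                noise_sd=cfg["noise_sd"], seed=seed + 77)
            model, metrics = train_qc(bench, seed=seed + 78)
            model.save(out / "qc_model.json")
            run_log["qc"] = {"trained_on": int(len(bench)),
                             "metrics": metrics}
        cells = classify(model, cells)

    with _stage("summarize", "qualified cells"):
        summary = summarize_groups(cells, qualified_only=True)
    with _stage("compare", "qualified cells"):
        comparisons = pd.concat(
            [compare_groups(cells, feat, test=cfg["test"],
                            control=cfg["control_group"])
             for feat in cfg["features"]], ignore_index=True)

    cells.to_csv(out / "cells.csv", index=False)
    summary.to_csv(out / "group_summary_raw.csv", index=False)
    rounded = summary.copy()
    for c in ("mean", "sd", "sem"):
        rounded[c] = rounded[c].round(2)
    rounded.to_csv(out / "group_summary.csv", index=False)
    comp_out = comparisons.copy()
    comp_out["percent_change_vs_control"] = (
        comp_out["percent_change_vs_control"].round(2))
    comp_out.to_csv(out / "comparisons.csv", index=False)
    run_log["n_cells_measured"] = int(len(cells))
    run_log["n_cells_qualified"] = int((cells.get("qualified", pd.Series(dtype=int)) == 1).sum())
    (out / "run_log.json").write_text(
        json.dumps(run_log, indent=2, sort_keys=True, default=str))
    return out
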