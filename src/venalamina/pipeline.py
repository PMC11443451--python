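"""End-to-end study orchestration: simulate -> segment -> vdm -> depths ->
extract -> stats, reproducible from a single config and seed."""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import laminar, sampling, vdm as vdm_mod, vesselseg
from .core_io import (
    StudyConfig,
    Volume,
    write_condition_table,
    write_run_report,
    write_volume,
)
from .phantom import PhantomSpec, SubjectPhantom, generate_cohort
from .stats import (
    CellMeansMatrix,
    fit_random_intercept,
    hedges_d,
    holm_bonferroni,
    lrt_compare,
    mixed_anova,
    monotone_impute,
    paired_t,
    pearson_corr,
    permutation_welch,
    pool_imputed_anova,
    welch_t,
)
from .stats.lmm import build_distance_design

logger = logging.getLogger("venalamina")

AREA_NAMES = ["M1", "S1", "SFG", "CMF", "RMF"]


def phantom_spec_from_config(config: StudyConfig) -> PhantomSpec:
    from .phantom import MetricParams, QsmParams

    raw = dict(config.phantom)
    if "qt1" in raw:
        raw["qt1"] = MetricParams(**{**raw["qt1"], "baselines": tuple(raw["qt1"]["baselines"])})
    if "qsm" in raw:
        q = dict(raw["qsm"])
        for side in ("pos", "neg"):
            q[side] = MetricParams(**{**q[side], "baselines": tuple(q[side]["baselines"])})
        raw["qsm"] = QsmParams(**q)
    for key in ("grid_shape", "spacing"):
        if key in raw:
            raw[key] = tuple(raw[key])
    raw.setdefault("seed", config.seed)
    return PhantomSpec(**raw)


def area_name_map(n_areas: int) -> dict[int, str]:
    return {i + 1: AREA_NAMES[i] if i < len(AREA_NAMES) else f"area{i + 1}"
            for i in range(n_areas)}


def process_subject(
    subject: SubjectPhantom, config: StudyConfig
) -> tuple[pd.DataFrame, dict]:
    """Segment veins, map distances, assign depths, extract the table."""
    if not (subject.vein_mask_truth.data > 0).any():
        raise ValueError("no veins segmented: subject volume contains no veins")
    qsm = subject.qsm_volume
    prob = vesselseg.vesselness_probability(qsm, config.vesselness_scales_mm)

    # Otsu inside a dilated ribbon so background does not dominate the
    # histogram; per-subject thresholds, logged
    ribbon = (subject.inner_signed_distance.data > 0) & (
        subject.outer_signed_distance.data > 0
    )
    region = ndimage.binary_dilation(ribbon, iterations=4)
    thresholds = vesselseg.otsu_thresholds_3class(
        prob.data[region], n_bins=config.otsu_bins
    )
    vein_mask = vesselseg.hysteresis_binarize(prob, thresholds)

    distance_map = vdm_mod.euclidean_distance_map(vein_mask)
    qt1_clean = vdm_mod.exclude_vein_voxels(subject.qT1_volume, vein_mask)
    qsm_clean = vdm_mod.exclude_vein_voxels(qsm, vein_mask)

    field = laminar.compute_depth_field(
        subject.inner_signed_distance,
        subject.outer_signed_distance,
        mode=config.depth_mode,
    )
    comps = laminar.assign_compartments(field)

    n_areas = int(np.nanmax(subject.area_labels.data))
    table = sampling.extract_condition_values(
        qt1_clean,
        qsm_clean,
        distance_map,
        comps,
        subject.area_labels,
        vein_mask,
        config,
        participant_id=subject.participant_id,
        group=subject.group,
        risk=subject.risk,
        area_names=area_name_map(n_areas),
    )
    info = {
        "participant_id": subject.participant_id,
        "otsu_lower": thresholds.lower,
        "otsu_upper": thresholds.upper,
        "n_vein_voxels": int(vein_mask.data.sum()),
        "n_depth_fallback": field.n_fallback,
        "n_missing_cells": int(table["value"].isna().sum()),
    }
    return table, info


# ---------------------------------------------------------------------------
# statistics battery on a condition table


def _bin_subject_means(table: pd.DataFrame, metric: str, area: str | None = None):
    """Per-subject mean value per distance bin (averaged over the other
    factors), as a wide frame indexed by participant."""
    sub = table[table["metric"] == metric]
    if area is not None:
        sub = sub[sub["area"] == area]
    wide = sub.pivot_table(
        index="participant_id", columns="distance_bin", values="value",
        aggfunc="mean", observed=False,
    )
    bins = list(pd.unique(sub["distance_bin"]))
    meta = sub.drop_duplicates("participant_id").set_index("participant_id")
    order = list(pd.unique(sub["participant_id"]))
    return wide.reindex(index=order, columns=bins), meta.loc[order]


def _anova_block(table, metric, config, seed):
    """5-bin (imputed, pooled) and 4-bin (bin 0-2 dropped) ANOVAs."""
    cells = CellMeansMatrix.from_condition_table(table, metric)
    out = {}
    if np.isnan(cells.data).any():
        imputed = monotone_impute(cells, m=config.m_imputations, seed=seed)
        results = [mixed_anova(c) for c in imputed]
        out["anova5_pooled"] = pool_imputed_anova(results)
        out["anova5_first_imputation"] = results[0].table
    else:
        res = mixed_anova(cells)
        out["anova5_pooled"] = res.table
        out["anova5_first_imputation"] = res.table

    bins = list(cells.conditions.get_level_values("distance_bin").unique())
    cells4 = cells.drop_level("distance_bin", bins[0])
    complete = cells4.complete_case
    if complete.sum() >= 4 and len(set(cells4.groups[complete])) == 2:
        cells4 = CellMeansMatrix(
            cells4.data[complete],
            cells4.conditions,
            [s for s, c in zip(cells4.subjects, complete) if c],
            cells4.groups[complete],
        )
        out["anova4"] = mixed_anova(cells4).table
    return out


def run_statistics(table: pd.DataFrame, config: StudyConfig) -> dict[str, pd.DataFrame]:
    """The full battery: ANOVAs, post hoc, permutation, LMM, correlations."""
    outputs: dict[str, pd.DataFrame] = {}
    metrics = list(pd.unique(table["metric"]))
    areas = list(pd.unique(table["area"]))

    for mi, metric in enumerate(metrics):
        blocks = _anova_block(table, metric, config, seed=config.seed * 1000 + mi)
        for name, df in blocks.items():
            outputs[f"{name}_{metric}"] = df

    # post hoc: consecutive-bin paired tests (overall and per area), and
    # per-bin Welch group tests; one Holm family per set
    posthoc_rows = []
    perm_rows = []
    for metric in metrics:
        for area in [None] + areas:
            wide, meta = _bin_subject_means(table, metric, area)
            bins = list(wide.columns)
            fam = []
            for b1, b2 in zip(bins, bins[1:]):
                pair = wide[[b1, b2]].dropna()
                if len(pair) < 3:
                    fam.append(None)
                    continue
                res = paired_t(pair[b1].to_numpy(), pair[b2].to_numpy())
                d, ci = hedges_d(
                    pair[b1].to_numpy(), pair[b2].to_numpy(), paired=True,
                    B_boot=config.B_boot, seed=config.seed,
                )
                fam.append((f"{b1} vs {b2}", res, d, ci, len(pair)))
            ps = [f[1].p for f in fam if f]
            adj = holm_bonferroni(ps) if ps else []
            it = iter(adj)
            for f in fam:
                if f is None:
                    continue
                label, res, d, ci, n = f
                posthoc_rows.append(
                    {
                        "metric": metric, "family": "distance",
                        "area": area or "all", "comparison": label,
                        "t": res.t, "df": res.df, "p": res.p,
                        "p_holm": float(next(it)), "d": d,
                        "d_lo": ci[0], "d_hi": ci[1], "n": n,
                    }
                )

        # between-group Welch tests per bin (collapsed over areas)
        wide, meta = _bin_subject_means(table, metric, None)
        groups = meta["group"]
        fam = []
        for b in wide.columns:
            col = wide[b].dropna()
            a = col[groups.reindex(col.index) == "young"].to_numpy()
            o = col[groups.reindex(col.index) == "old"].to_numpy()
            if len(a) < 3 or len(o) < 3:
                fam.append(None)
                continue
            res = welch_t(a, o)
            d, ci = hedges_d(a, o, paired=False, B_boot=config.B_boot,
                             seed=config.seed)
            fam.append((str(b), res, d, ci, (len(a), len(o)), a, o))
        ps = [f[1].p for f in fam if f]
        adj = holm_bonferroni(ps) if ps else []
        it = iter(adj)
        for f in fam:
            if f is None:
                continue
            label, res, d, ci, n, a, o = f
            posthoc_rows.append(
                {
                    "metric": metric, "family": "age-by-bin", "area": "all",
                    "comparison": label, "t": res.t, "df": res.df, "p": res.p,
                    "p_holm": float(next(it)), "d": d, "d_lo": ci[0],
                    "d_hi": ci[1], "n": n[0] + n[1],
                }
            )
            perm_rows.append(
                {
                    "metric": metric, "bin": label,
                    "p_perm": permutation_welch(a, o, B=config.B_perm,
                                                seed=config.seed),
                    "t": res.t, "n_young": n[0], "n_old": n[1],
                }
            )
    outputs["posthoc"] = pd.DataFrame(posthoc_rows)
    outputs["permutation"] = pd.DataFrame(perm_rows)

    # random-intercept risk models in the old group, per metric and area
    lmm_rows = []
    old = table[table["group"] == "old"]
    for metric in metrics:
        for area in areas:
            sub = old[(old["metric"] == metric) & (old["area"] == area)]
            per = (
                sub.groupby(["participant_id", "distance_bin", "risk"],
                            observed=False, sort=False)["value"]
                .mean()
                .reset_index()
                .dropna()
            )
            if per.empty or per["risk"].nunique() < 2:
                continue
            counts = per.groupby("participant_id", observed=False).size()
            keep = counts[counts >= 2].index
            per = per[per["participant_id"].isin(keep)]
            if per["participant_id"].nunique() < 4:
                continue
            y = per["value"].to_numpy()
            ids = per["participant_id"].to_numpy()
            bins = per["distance_bin"].to_numpy()
            risk = per["risk"].to_numpy()
            try:
                null = fit_random_intercept(
                    y, build_distance_design(bins), ids, "value ~ bin")
                m1 = fit_random_intercept(
                    y, build_distance_design(bins, risk), ids,
                    "value ~ bin + risk")
                m2 = fit_random_intercept(
                    y, build_distance_design(bins, risk, interaction=True),
                    ids, "value ~ bin * risk")
            except (ValueError, np.linalg.LinAlgError):
                continue
            chi1, df1, p1 = lrt_compare(m1, null)
            chi2_, df2, p2 = lrt_compare(m2, null)
            lmm_rows.append(
                {
                    "metric": metric, "area": area,
                    "chi2_m1": chi1, "df_m1": df1, "p_m1": p1,
                    "chi2_m2": chi2_, "df_m2": df2, "p_m2": p2,
                    "sigma_b2": m1.sigma_b2, "sigma2": m1.sigma2,
                }
            )
    outputs["lmm"] = pd.DataFrame(lmm_rows)

    # Pearson correlations pQSM vs qT1 per group x area x bin
    corr_rows = []
    if "pQSM" in metrics and "qT1" in metrics:
        for grp in pd.unique(table["group"]):
            gtab = table[table["group"] == grp]
            for area in areas:
                wq, _ = _bin_subject_means(gtab, "qT1", area)
                wp, _ = _bin_subject_means(gtab, "pQSM", area)
                for b in wq.columns:
                    if b not in wp.columns:
                        continue
                    pair = pd.concat([wq[b], wp[b]], axis=1).dropna()
                    if len(pair) < 4:
                        continue
                    r, p = pearson_corr(pair.iloc[:, 0], pair.iloc[:, 1])
                    corr_rows.append(
                        {"group": grp, "area": area, "bin": str(b),
                         "r": r, "p": p, "n": len(pair)}
                    )
    outputs["correlations"] = pd.DataFrame(corr_rows)
    return outputs


def run_study(config: StudyConfig, out_dir=None) -> dict:
    """Run the full pipeline; returns the run report dict."""
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}, "manifest": []}

    t0 = time.time()
    spec = phantom_spec_from_config(config)
    cohort = generate_cohort(spec)
    report["stages"]["simulate"] = {
        "seconds": time.time() - t0,
        "n_subjects": len(cohort),
        "n_young": sum(s.group == "young" for s in cohort),
        "n_old": sum(s.group == "old" for s in cohort),
    }

    t0 = time.time()
    tables = []
    subject_info = []
    for subject in cohort:
        try:
            table, info = process_subject(subject, config)
        except Exception as exc:
            raise RuntimeError(
                f"stage 'extract' failed for {subject.participant_id}: {exc}"
            ) from exc
        tables.append(table)
        subject_info.append(info)
    full = pd.concat(tables, ignore_index=True)
    table_path = out / "table.tsv"
    write_condition_table(full, table_path)
    report["manifest"].append(str(table_path))
    report["stages"]["extract"] = {
        "seconds": time.time() - t0,
        "subjects": subject_info,
    }

    t0 = time.time()
    stats_out = run_statistics(full, config)
    for name, df in stats_out.items():
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.12g", na_rep="NA")
        report["manifest"].append(str(path))
    report["stages"]["stats"] = {"seconds": time.time() - t0,
                                 "outputs": sorted(stats_out)}

    write_run_report(out / "run_report.json", **report)
    return report
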