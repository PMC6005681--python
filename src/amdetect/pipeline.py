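"""Cohort-level orchestration: generate -> filter -> fit -> decode -> compare.

``run_cohort`` executes the stages in dependency order on a synthetic
cohort and emits per-stage TSV/JSON outputs plus a combined summary table
(behavioral, EFR, and decoder thresholds per group x rate) and an
optional three-panel summary figure. Re-running with the same config and
seed reproduces identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import efr as efr_mod
from . import psychometrics as psy
from .group_stats import bootstrap_group_diff
from .pattern_classifier import ClassifierConfig, classify_template
from .population_decoder import DecoderConfig, build_population_tensor, decode
from .synthetic import CohortConfig, generate_cohort
from .unit_metrics import neurometric_threshold, unit_metrics_table

log = logging.getLogger("amdetect")

ALL_STAGES = ("behavior", "units", "classify", "decode", "efr", "stats")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def behavior_stage(cohort) -> pd.DataFrame:
    """Filter, fit, and threshold every session; add per-animal TMTF fits."""
    rows = []
    included, _ = psy.filter_sessions(cohort["sessions"])
    for sess in included:
        fit = psy.fit_psychometric(sess)
        thr, flag = psy.extract_threshold(fit)
        rows.append({
            "animal_id": sess.animal_id, "group": sess.hearing_status,
            "rate_hz": sess.rate_hz,
            "threshold_db": thr if thr is not None else np.nan,
            "threshold_flag": flag,
            "fa_rate": fit.fa_rate, "lapse": psy.lapse_rate(sess),
            "max_dprime": fit.max_dprime,
        })
    df = pd.DataFrame(rows)
    tmtf_rows = []
    for (animal, group), sub in df.dropna(subset=["threshold_db"]).groupby(
            ["animal_id", "group"]):
        if len(sub) >= 2:
            fit = psy.fit_tmtf(sub["rate_hz"], sub["threshold_db"])
            tmtf_rows.append({"animal_id": animal, "group": group,
                              "A": fit.A, "b": fit.b})
    return df, pd.DataFrame(tmtf_rows)


def decode_stage(cohort, rates=(256.0, 512.0), window=(0.0, 0.4),
                 bin_width_ms=1.0, n_iterations=50, max_units=40, seed=0):
    """Population decoding per (group, rate, depth), plus decoder thresholds."""
    rows = []
    units = cohort["units"]
    for group in sorted({u.hearing_status for u in units}):
        for rate in rates:
            pool = [u for u in units
                    if u.hearing_status == group and u.rate_hz == rate]
            if len(pool) < 2:
                continue
            pool = pool[:max_units]
            depths = np.sort(pool[0].trials.loc[
                pool[0].trials["type"] == "go", "depth_db"].unique())
            try:
                tensor = build_population_tensor(
                    pool, depths, window=window, bin_width_ms=bin_width_ms,
                    seed=seed)
            except ValueError:
                continue
            cfg = DecoderConfig(n_iterations=n_iterations, seed=seed)
            for d in depths:
                res = decode(tensor, d, cfg)
                rows.append({
                    "group": group, "rate_hz": rate, "depth_db": float(d),
                    "mean_dprime": res.mean_dprime, "sd_dprime": res.sd_dprime,
                    "n_units": res.n_units,
                })
    df = pd.DataFrame(rows)
    thr_rows = []
    if not df.empty:
        for (group, rate), sub in df.groupby(["group", "rate_hz"]):
            thr, flag = neurometric_threshold(sub["depth_db"], sub["mean_dprime"])
            thr_rows.append({"group": group, "rate_hz": rate,
                             "threshold_db": thr if thr is not None else np.nan,
                             "threshold_flag": flag})
    return df, pd.DataFrame(thr_rows)


def classify_stage(cohort, n_iterations=100, max_units=8, seed=0):
    """FR-metric template classification per unit x depth (demo scale)."""
    rows = []
    for u in cohort["units"][:max_units]:
        depths = np.sort(u.trials.loc[u.trials["type"] == "go", "depth_db"].unique())
        for d in depths:
            try:
                res = classify_template(
                    u, d, ClassifierConfig(metric="fr", n_iterations=n_iterations,
                                           seed=seed))
            except ValueError:
                continue
            rows.append({
                "unit_id": u.unit_id, "group": u.hearing_status,
                "rate_hz": u.rate_hz, "depth_db": float(d),
                "metric": "fr", "dprime": res.dprime,
            })
    return pd.DataFrame(rows)


def efr_stage(cohort):
    """Per-animal EFR thresholds across rates (the brainstem TMTF)."""
    rows = []
    recs = cohort["efr"]
    animals = sorted({(r.animal_id, r.hearing_status) for r in recs})
    for animal, group in animals:
        mine = [r for r in recs if r.animal_id == animal]
        for rate in sorted({r.rate_hz for r in mine}):
            try:
                res = efr_mod.efr_threshold(mine, rate)
            except ValueError:
                continue
            rows.append({
                "animal_id": animal, "group": group, "rate_hz": rate,
                "threshold_db": res.threshold_db if res.threshold_db is not None
                else np.nan,
                "noise_floor": res.noise_floor, "flag": res.flag,
            })
    return pd.DataFrame(rows)


def stats_stage(cohort, unit_table, n_boot=2000, per_animal=30, seed=0):
    """Bootstrap Ctl-vs-HL comparisons of spontaneous FR and unit CV."""
    groups = {a: g for a, g in
              unit_table[["animal_id", "group"]].drop_duplicates().itertuples(
                  index=False)}
    out = []
    for metric in ("spont_hz", "cv", "driven_fr_hz"):
        vals = {a: sub[metric].dropna().to_numpy()
                for a, sub in unit_table.groupby("animal_id")}
        vals = {a: v for a, v in vals.items() if v.size}
        cmp_ = bootstrap_group_diff(
            vals, {a: groups[a] for a in vals}, n_boot=n_boot,
            per_animal=per_animal, seed=seed, metric=metric,
            keep_distribution=False,
        )
        out.append({
            "metric": metric, "mean_diff": cmp_.mean_diff,
            "ci_low": cmp_.ci_low, "ci_high": cmp_.ci_high,
            "significant": cmp_.significant, "n_boot": n_boot,
        })
    return pd.DataFrame(out)


def run_cohort(config: CohortConfig, out_dir, stages=ALL_STAGES,
               decode_kwargs=None, classify_kwargs=None) -> dict:
    """Execute the pipeline and write tables, figures and a run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = {}
    t_start = time.time()
    cohort = generate_cohort(config)
    log.info("stage=generate seed=%s n_units=%d elapsed=%.1fs",
             config.master_seed, len(cohort["units"]), time.time() - t_start)

    def emit(df, name):
        path = out / name
        df.to_csv(path, sep="\t", index=False)
        artifacts[name] = _checksum(path)

    summary_parts = {}
    unit_table = None
    for stage in stages:
        t0 = time.time()
        try:
            if stage == "behavior":
                behav, tmtf = behavior_stage(cohort)
                emit(behav, "behavior_thresholds.tsv")
                emit(tmtf, "behavior_tmtf.tsv")
                summary_parts["behavior"] = behav
            elif stage == "units":
                unit_table = unit_metrics_table(cohort["units"])
                emit(unit_table, "unit_metrics.tsv")
            elif stage == "classify":
                emit(classify_stage(cohort, seed=config.master_seed,
                                    **(classify_kwargs or {})),
                     "classifier_dprime.tsv")
            elif stage == "decode":
                dec, dec_thr = decode_stage(cohort, seed=config.master_seed,
                                            **(decode_kwargs or {}))
                emit(dec, "decoder_dprime.tsv")
                emit(dec_thr, "decoder_thresholds.tsv")
                summary_parts["decoder"] = dec_thr
            elif stage == "efr":
                efr_df = efr_stage(cohort)
                emit(efr_df, "efr_thresholds.tsv")
                summary_parts["efr"] = efr_df
            elif stage == "stats":
                if unit_table is None:
                    unit_table = unit_metrics_table(cohort["units"])
                emit(stats_stage(cohort, unit_table, seed=config.master_seed),
                     "group_comparisons.tsv")
        except Exception as exc:
            raise RuntimeError(
                f"stage {stage!r} failed (seed={config.master_seed}): {exc}"
            ) from exc
        log.info("stage=%s seed=%s elapsed=%.1fs", stage, config.master_seed,
                 time.time() - t0)

    summary = _summary_table(summary_parts)
    if summary is not None:
        path = out / "summary.tsv"
        summary.to_csv(path, sep="\t", index=False)
        artifacts["summary.tsv"] = _checksum(path)
        _triptych_figure(summary_parts, out / "summary.png")
        artifacts["summary.png"] = "figure"
    manifest = {
        "master_seed": config.master_seed,
        "stages": list(stages),
        "artifacts": artifacts,
        "cohort": cohort["manifest"],
        "runtime_s": round(time.time() - t_start, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {"manifest": manifest, "cohort": cohort, "summary": summary}


def _summary_table(parts):
    if "behavior" not in parts:
        return None
    behav = (parts["behavior"].groupby(["group", "rate_hz"])["threshold_db"]
             .mean().rename("behavior_threshold_db").reset_index())
    merged = behav
    if "efr" in parts and not parts["efr"].empty:
        efr = (parts["efr"].groupby(["group", "rate_hz"])["threshold_db"]
               .mean().rename("efr_threshold_db").reset_index())
        merged = merged.merge(efr, on=["group", "rate_hz"], how="outer")
    if "decoder" in parts and not parts["decoder"].empty:
        dec = parts["decoder"].rename(
            columns={"threshold_db": "decoder_threshold_db"})[
            ["group", "rate_hz", "decoder_threshold_db"]]
        merged = merged.merge(dec, on=["group", "rate_hz"], how="outer")
    return merged.sort_values(["group", "rate_hz"]).reset_index(drop=True)


def _triptych_figure(parts, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharey=False)
    panels = [("behavior", "Behavioral TMTF", "threshold_db"),
              ("efr", "EFR TMTF", "threshold_db"),
              ("decoder", "Decoder thresholds", "threshold_db")]
    colors = {"ctl": "k", "hl": "tab:orange"}
    for ax, (key, title, col) in zip(axes, panels):
        ax.set_title(title)
        ax.set_xlabel("AM rate (Hz)")
        ax.set_ylabel("Threshold (dB re 100%)")
        ax.set_xscale("log", base=2)
        if key not in parts or parts[key].empty:
            continue
        df = parts[key]
        for group, sub in df.groupby("group"):
            agg = sub.groupby("rate_hz")[col].mean()
            ax.plot(agg.index, agg.values, "o-", color=colors.get(group, None),
                    label=group)
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
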