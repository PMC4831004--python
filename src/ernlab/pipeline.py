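"""Pipeline driver: simulate -> behaviour -> first level -> second level -> decode.

Each stage writes its outputs under the run directory and records status,
timing, subject accounting and outputs in a JSON manifest.  Stages are
resumable: with resume=True a stage whose outputs already exist is skipped.
"""

from __future__ import annotations

import logging
import time
import traceback
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import decode as dec
from . import group as grp
from . import io as eio
from . import rerp
from .cohort import cohort_seeds, simulate_subject
from .config import RunConfig, config_hash, config_to_yaml
from .montage import load_montage

log = logging.getLogger("ernlab.pipeline")


def _stage(manifest, name):
    entry = {"name": name, "status": "pending", "seconds": None,
             "outputs": [], "info": {}}
    manifest["stages"].append(entry)
    return entry


def run_pipeline(config: RunConfig, resume: bool = False) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "config_hash": config_hash(config),
        "stages": [],
    }
    config_to_yaml(config, out / "config.yaml")
    montage = load_montage(config.cohort.montage)

    stages = [
        ("simulate", _run_simulate),
        ("behavior", _run_behavior),
        ("first_level", _run_first_level),
        ("second_level", _run_second_level),
        ("decode", _run_decode),
    ]
    ctx = {"config": config, "out": out, "montage": montage}
    for name, fn in stages:
        entry = _stage(manifest, name)
        t0 = time.time()
        try:
            fn(ctx, entry, resume)
            entry["status"] = entry["status"] if entry["status"] == "skipped" \
                else "ok"
        except Exception as exc:  # noqa: BLE001 - stage isolation
            entry["status"] = "failed"
            entry["info"]["error"] = f"{type(exc).__name__}: {exc}"
            log.error("stage %s failed:\n%s", name, traceback.format_exc())
            entry["seconds"] = round(time.time() - t0, 3)
            break
        entry["seconds"] = round(time.time() - t0, 3)
    eio.write_json(manifest, out / "manifest.json")
    return manifest


def _run_simulate(ctx, entry, resume):
    config, out, montage = ctx["config"], ctx["out"], ctx["montage"]
    trials_path = out / "trials.tsv"
    epo_dir = out / "epochs"
    if resume and trials_path.exists():
        entry["status"] = "skipped"
        entry["outputs"] = [str(trials_path), str(epo_dir)]
        return
    epo_dir.mkdir(exist_ok=True)
    frames = []
    for sex, sid, child, q in cohort_seeds(config.cohort, config.seed):
        rng = np.random.default_rng(child)
        tbl, epochs = simulate_subject(config.cohort, sex, sid, rng,
                                       montage=montage, baseline_quantile=q)
        frames.append(tbl)
        eio.write_epochs(epochs, epo_dir / f"{sid}.h5", seed=config.seed)
    table = pd.concat(frames, ignore_index=True)
    eio.write_trial_table(table, trials_path)
    eio.write_units_sidecar(trials_path)
    entry["outputs"] = [str(trials_path), str(epo_dir)]
    entry["info"]["n_subjects"] = table["subject_id"].nunique()


def _run_behavior(ctx, entry, resume):
    config, out = ctx["config"], ctx["out"]
    summaries_path = out / "subject_summaries.tsv"
    trials = eio.read_trial_table(out / "trials.tsv")
    summaries = beh.summarize_subjects(trials)

    # screen subjects with excessive multi-response / out-of-band proportions
    counts = trials.groupby("subject_id").agg(
        n=("rt", "size"),
        multi=("multi_response", "sum"))
    oob = trials.groupby("subject_id")["rt"].apply(
        lambda r: ((r < beh.RT_MIN) | (r > beh.RT_MAX)).sum())
    prop_multi = (counts["multi"] / counts["n"]).reindex(summaries["subject_id"])
    prop_oob = (oob / counts["n"]).reindex(summaries["subject_id"])
    def screen(values):
        try:
            return beh.grubbs_screen(values)
        except beh.ZeroVarianceError:  # e.g. contamination switched off
            return np.zeros(len(values), dtype=bool)

    excl = screen(prop_multi.to_numpy()) | screen(prop_oob.to_numpy())
    summaries["excluded"] = excl
    kept = summaries[~summaries["excluded"]]
    summaries.to_csv(summaries_path, sep="\t", index=False)

    m = config.analysis.family_size
    reports = {
        "rt": beh.behavioral_regression(
            kept, "mean_rt_correct", ["sex", "age", "n_errors"], m),
        "pes": beh.behavioral_regression(
            kept.rename(columns={"mean_rt_correct": "mean_rt"}),
            "pes_standard", ["sex", "age", "n_errors", "mean_rt"], m),
        "congruency": beh.behavioral_regression(
            kept, "congruency_effect", ["sex", "age", "n_errors"], m),
    }
    for name, rep in reports.items():
        eio.write_report_tsv(rep, out / f"regression_{name}.tsv")
        eio.write_report_json(rep, out / f"regression_{name}.json")
    entry["outputs"] = [str(summaries_path)]
    entry["info"] = {
        "subjects_in": int(len(summaries)),
        "subjects_excluded": int(excl.sum()),
        "subjects_analyzed": int(len(kept)),
        "pes_missing": int(kept["pes_standard"].isna().sum()),
    }


def _run_first_level(ctx, entry, resume):
    config, out = ctx["config"], ctx["out"]
    fl_dir = out / "first_level"
    fl_dir.mkdir(exist_ok=True)
    trials = eio.read_trial_table(out / "trials.tsv")
    filtered = beh.filter_trials(trials)
    a = config.analysis
    n_done = n_skipped = 0
    for sid, sub in filtered.groupby("subject_id", sort=True):
        dst = fl_dir / f"{sid}.h5"
        if resume and dst.exists():
            n_skipped += 1
            continue
        orig = trials[trials["subject_id"] == sid]
        epochs = eio.read_epochs(out / "epochs" / f"{sid}.h5", trials=orig)
        epochs, aligned = rerp.select_epochs_for_trials(epochs, sub)
        epochs, _ = rerp.reject_epochs_adaptive(
            epochs, aligned["accuracy"], a.reject_z_threshold,
            a.reject_max_fraction)
        _, aligned = rerp.select_epochs_for_trials(epochs, sub)
        epochs = rerp.baseline_correct(epochs, a.baseline_window)
        epochs = rerp.smooth_running_average(epochs, a.smooth_halfwidth_ms)
        X, valid = rerp.build_design_matrix(aligned)
        epochs = epochs.select(valid)
        fl = rerp.robust_fit_mass_univariate(epochs, X)
        eio.write_first_level_map(fl, dst)
        n_done += 1
    entry["outputs"] = [str(fl_dir)]
    entry["info"] = {"subjects_fit": n_done, "subjects_skipped": n_skipped}


def _load_first_level(out):
    fl_dir = Path(out) / "first_level"
    maps = [eio.read_first_level_map(p) for p in sorted(fl_dir.glob("*.h5"))]
    if not maps:
        raise FileNotFoundError("no first-level maps found")
    return maps


def _run_second_level(ctx, entry, resume):
    out = ctx["out"]
    maps = _load_first_level(out)
    summaries = pd.read_csv(out / "subject_summaries.tsv", sep="\t")
    summaries = summaries.set_index("subject_id")
    ids = [m.subject_id for m in maps]
    cov = summaries.loc[ids].reset_index()
    cov = cov.rename(columns={"mean_rt_correct": "mean_rt"})

    grand = np.nanmean(grp.stack_maps(maps, "error"), axis=0)
    ern = rerp.find_global_extremum(grand, maps[0].times,
                                   maps[0].electrode_labels, "min")
    pe = rerp.find_global_extremum(grand, maps[0].times,
                                  maps[0].electrode_labels, "max")

    result = grp.second_level_regression(maps, cov, include_rt=False)
    eio.write_group_result(result, out / "group_result.h5")
    stack = grp.stack_maps(maps, "error")
    peaks = {
        "ern": grp.peak_test(result, "sex", ern[:2], stack,
                             cov["sex"].to_numpy()),
        "pe": grp.peak_test(result, "sex", pe[:2], stack,
                            cov["sex"].to_numpy()),
    }
    rows = [{"component": k, **{kk: vv for kk, vv in v.items()
                                if kk != "groups"}} for k, v in peaks.items()]
    pd.DataFrame(rows).to_csv(out / "peak_tests.tsv", sep="\t", index=False)
    eio.write_json({"ern_peak": ern, "pe_peak": pe, "tests": peaks},
                   out / "peaks.json")
    entry["outputs"] = [str(out / "group_result.h5"),
                        str(out / "peak_tests.tsv")]
    entry["info"] = {"ern_peak": list(ern), "pe_peak": list(pe),
                     "df_resid": result.df_resid}


def _run_decode(ctx, entry, resume):
    config, out, montage = ctx["config"], ctx["out"], ctx["montage"]
    import json

    maps = _load_first_level(out)
    peaks = json.loads((out / "peaks.json").read_text())
    ern_label, ern_lat, _ = peaks["ern_peak"]
    ti = int(np.argmin(np.abs(maps[0].times - ern_lat)))
    features = np.stack([m.get("error")[:, ti] for m in maps])
    summaries = pd.read_csv(out / "subject_summaries.tsv", sep="\t")
    sex = summaries.set_index("subject_id").loc[
        [m.subject_id for m in maps], "sex"].to_numpy()
    a = config.analysis
    res = dec.decode_gender(features, sex, montage=montage,
                            n_splits=a.cv_splits,
                            test_fraction=a.test_fraction,
                            n_perm=a.n_permutations,
                            permutation_cv_splits=a.permutation_cv_splits,
                            searchlight_splits=a.searchlight_splits,
                            seed=np.random.SeedSequence(
                                [config.seed, 202]).generate_state(1)[0],
                            C=a.svm_c)
    payload = {
        "accuracy": res.accuracy,
        "permutation_p": res.permutation_p,
        "n_per_class": res.n_per_class,
        "n_permutations": res.n_permutations,
        "permutation_cv_splits": res.permutation_cv_splits,
        "feature_latency_ms": ern_lat,
        "searchlight": res.searchlight,
    }
    eio.write_json(payload, out / "decoding.json")
    topo = pd.DataFrame(sorted(res.searchlight.items()),
                        columns=["electrode", "accuracy"])
    topo.to_csv(out / "searchlight_topography.tsv", sep="\t", index=False)
    entry["outputs"] = [str(out / "decoding.json"),
                        str(out / "searchlight_topography.tsv")]
    entry["info"] = {"accuracy": res.accuracy,
                     "n_per_class": res.n_per_class}
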