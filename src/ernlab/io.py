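"""File formats: trial tables (TSV), epochs and maps (HDF5), reports.

TSV (tab-separated, UTF-8) is used for all tabular outputs to avoid locale
decimal issues; epochs are stored float32 with float64 computation upstream.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import EpochSet, FirstLevelMap, GroupResult, TRIAL_COLUMNS


class SchemaError(ValueError):
    pass


#: units of the trial-table columns, written as a sidecar JSON next to TSVs
TRIAL_UNITS = {
    "age": "years",
    "rt": "ms",
    "trial_index": "1-based position",
    "rt_mu": "ms (deterministic RT location, generator bookkeeping)",
    "rt_noise": "dimensionless multiplicative factor",
}


def write_units_sidecar(path) -> None:
    side = Path(str(path) + ".units.json")
    side.write_text(json.dumps(TRIAL_UNITS, indent=2))


# ---------------------------------------------------------------------------
# trial tables

def write_trial_table(table: pd.DataFrame, path) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"trial table missing required columns: {missing}")
    ordered = TRIAL_COLUMNS + [c for c in table.columns
                               if c not in TRIAL_COLUMNS]
    table[ordered].to_csv(path, sep="\t", index=False)


def read_trial_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {missing}")
    for col, kind in (("rt", float), ("age", float), ("trial_index", int)):
        try:
            df[col] = df[col].astype(kind)
        except (TypeError, ValueError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            rows = (df.index[bad] + 2).tolist()[:5]  # 1-based incl. header
            raise SchemaError(
                f"{path}: column {col!r} not {kind.__name__}-coercible "
                f"(rows {rows}): {exc}") from None
    df["multi_response"] = df["multi_response"].astype(bool)
    bad_rt = (df["rt"] <= 0) & df["rt"].notna()
    if bad_rt.any():
        rows = (df.index[bad_rt] + 2).tolist()[:5]
        raise SchemaError(f"{path}: non-positive RTs at rows {rows}")
    return df


# ---------------------------------------------------------------------------
# epochs

def write_epochs(epochs: EpochSet, path, seed=None, extra_attrs=None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32),
                         compression="gzip", compression_opts=1)
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("electrodes",
                         data=np.array(epochs.electrode_labels, dtype="S"))
        f.create_dataset("trial_link", data=epochs.trial_link)
        f.attrs["subject_id"] = epochs.subject_id
        f.attrs["sampling_rate"] = epochs.sampling_rate
        if seed is not None:
            f.attrs["seed"] = int(seed)
        for k, v in (extra_attrs or {}).items():
            f.attrs[k] = v


def read_epochs(path, trials: pd.DataFrame | None = None) -> EpochSet:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        times = f["times"][()]
        labels = [s.decode() for s in f["electrodes"][()]]
        link = f["trial_link"][()]
        subject_id = f.attrs["subject_id"]
        rate = float(f.attrs["sampling_rate"])
    if data.shape[0] == 0:
        raise SchemaError(f"{path}: empty epoch container (0 trials)")
    if data.shape[1] != len(labels) or data.shape[2] != len(times):
        raise SchemaError(f"{path}: dimension labels inconsistent with data")
    epochs = EpochSet(data=data, times=times, electrode_labels=labels,
                      subject_id=str(subject_id), trial_link=link,
                      sampling_rate=rate)
    if trials is not None and len(trials) > 0:
        if link.max() >= len(trials) or link.min() < 0:
            raise SchemaError(
                f"{path}: trial_link points outside the trial table "
                f"(max {link.max()} vs {len(trials)} trials)")
    return epochs


# ---------------------------------------------------------------------------
# first-level / group maps

def write_first_level_map(m: FirstLevelMap, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=m.weights.astype(np.float32),
                         compression="gzip", compression_opts=1)
        f["weights"].attrs["dims"] = "regressor x electrode x timepoint"
        f.create_dataset("times", data=m.times)
        f.create_dataset("electrodes",
                         data=np.array(m.electrode_labels, dtype="S"))
        f.create_dataset("regressor_names",
                         data=np.array(m.regressor_names, dtype="S"))
        f.attrs["subject_id"] = m.subject_id
        f.attrs["n_trials"] = m.n_trials
        f.attrs["n_nonconverged"] = m.n_nonconverged


def read_first_level_map(path) -> FirstLevelMap:
    with h5py.File(path, "r") as f:
        return FirstLevelMap(
            weights=f["weights"][()].astype(np.float64),
            regressor_names=[s.decode() for s in f["regressor_names"][()]],
            times=f["times"][()],
            electrode_labels=[s.decode() for s in f["electrodes"][()]],
            subject_id=str(f.attrs["subject_id"]),
            n_trials=int(f.attrs.get("n_trials", 0)),
            n_nonconverged=int(f.attrs.get("n_nonconverged", 0)))


def write_coupling_map(m, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("coef", data=np.asarray(m.coef, dtype=np.float32),
                         compression="gzip", compression_opts=1)
        f["coef"].attrs["dims"] = "electrode x timepoint"
        f.create_dataset("times", data=m.times)
        f.create_dataset("electrodes",
                         data=np.array(m.electrode_labels, dtype="S"))
        f.attrs["subject_id"] = m.subject_id
        f.attrs["n_error_trials"] = m.n_error_trials


def read_coupling_map(path):
    from .containers import CouplingMap

    with h5py.File(path, "r") as f:
        return CouplingMap(
            coef=f["coef"][()].astype(np.float64),
            times=f["times"][()],
            electrode_labels=[s.decode() for s in f["electrodes"][()]],
            subject_id=str(f.attrs["subject_id"]),
            n_error_trials=int(f.attrs.get("n_error_trials", 0)))


def write_group_result(g: GroupResult, path) -> None:
    with h5py.File(path, "w") as f:
        for name in ("coef", "t", "p"):
            f.create_dataset(name, data=getattr(g, name).astype(np.float32),
                             compression="gzip", compression_opts=1)
        f.create_dataset("times", data=g.times)
        f.create_dataset("electrodes",
                         data=np.array(g.electrode_labels, dtype="S"))
        f.create_dataset("predictor_names",
                         data=np.array(g.predictor_names, dtype="S"))
        f.attrs["df_resid"] = g.df_resid
        f.attrs["n_subjects"] = g.n_subjects


def read_group_result(path) -> GroupResult:
    with h5py.File(path, "r") as f:
        return GroupResult(
            coef=f["coef"][()].astype(np.float64),
            t=f["t"][()].astype(np.float64),
            p=f["p"][()].astype(np.float64),
            predictor_names=[s.decode() for s in f["predictor_names"][()]],
            times=f["times"][()],
            electrode_labels=[s.decode() for s in f["electrodes"][()]],
            df_resid=int(f.attrs["df_resid"]),
            n_subjects=int(f.attrs["n_subjects"]))


# ---------------------------------------------------------------------------
# small report helpers

def write_report_tsv(report, path) -> None:
    report.table.to_csv(path, sep="\t", index=False)


def write_report_json(report, path) -> None:
    payload = {
        "table": report.table.to_dict(orient="records"),
        "df_resid": report.df_resid,
        "n": report.n,
        "family_size": report.family_size,
        "n_dropped": report.n_dropped,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_json(obj, path) -> None:
    def default(x):
        if isinstance(x, np.ndarray):
            return x.tolist()
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        raise TypeError(type(x))

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
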