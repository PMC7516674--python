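"""Delimited-text readers and writers for pipeline objects."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .series import ECGSignal, RRIntervalSeries

__all__ = [
    "write_rr", "read_rr", "write_ecg", "read_ecg",
    "write_cohort", "read_cohort", "read_config",
]

_COHORT_DICT = {
    "subject_id": "subject identifier",
    "cvd": "outcome label (1 = cardiovascular event group)",
    "age": "years",
    "gender": "0 female / 1 male",
    "bmi": "kg/m^2",
    "height": "cm",
    "waist_hip_ratio": "percent",
    "smoking_status": "0 never / 1 current / 2 former",
    "lifetime_cigarettes": "packs/year",
    "diabetes": "0 no / 1 yes",
    "hypertension": "0 no / 1 yes",
    "ahi": "apnea-hypopnea index, events/h",
    "rdi": "respiratory disturbance index, events/h",
    "rr_file": "relative path to the subject RR series file",
}


def write_rr(path: str | Path, rr: RRIntervalSeries) -> None:
    """Write an RR series as TSV: beat index, RR in ms, artifact flag."""
    df = pd.DataFrame({
        "beat": np.arange(len(rr)),
        "rr_ms": rr.rr,
        "artifact": rr.artifact_mask.astype(int),
    })
    with open(path, "w") as fh:
        fh.write(f"# origin: {rr.origin}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_rr(path: str | Path) -> RRIntervalSeries:
    origin = "measured"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# origin:"):
            origin = first.split(":", 1)[1].strip()
        else:
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t")
    return RRIntervalSeries(df["rr_ms"].to_numpy(),
                            df["artifact"].to_numpy().astype(bool), origin=origin)


def write_ecg(path: str | Path, ecg: ECGSignal) -> None:
    """Single-column sample values with a sampling-rate header."""
    with open(path, "w") as fh:
        fh.write(f"# fs: {ecg.fs}\n# start_time: {ecg.start_time}\n")
        np.savetxt(fh, ecg.samples, fmt="%.6f")


def read_ecg(path: str | Path, fs: float | None = None) -> ECGSignal:
    start = 0.0
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            key = key.strip()
            if key == "fs":
                fs = float(val)
            elif key == "start_time":
                start = float(val)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        samples = np.loadtxt(fh)
    if fs is None:
        raise ValueError("sampling rate not found in header and not provided")
    return ECGSignal(samples, fs, start)


def write_cohort(outdir: str | Path, cohort: pd.DataFrame) -> Path:
    """Write a cohort: subject table with data dictionary + one RR file each."""
    outdir = Path(outdir)
    (outdir / "rr").mkdir(parents=True, exist_ok=True)
    table = cohort.drop(columns=["rr_series"]).copy()
    rr_files = []
    for _, rec in cohort.iterrows():
        rel = f"rr/{rec['subject_id']}.tsv"
        write_rr(outdir / rel, rec["rr_series"])
        rr_files.append(rel)
    table["rr_file"] = rr_files
    path = outdir / "cohort.tsv"
    with open(path, "w") as fh:
        for col in table.columns:
            fh.write(f"# {col}: {_COHORT_DICT.get(col, '')}\n")
        table.to_csv(fh, sep="\t", index=False)
    return path


def read_cohort(path: str | Path, load_rr: bool = True) -> pd.DataFrame:
    path = Path(path)
    table = pd.read_csv(path, sep="\t", comment="#")
    if load_rr and "rr_file" in table.columns:
        table["rr_series"] = [read_rr(path.parent / rel) for rel in table["rr_file"]]
    return table


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
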