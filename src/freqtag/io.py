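"""Cohort container I/O: HDF5 arrays with a JSON metadata sidecar.

Layout: ``cohort.h5`` holds one chunked dataset per subject/condition at
``/<subject>/<condition>`` (trials x channels x samples, microvolt);
``cohort.json`` records sampling rate, channel labels, epoch start time,
stimulus-onset sample index, condition names, and the generator seed.
Subject covariates travel as a plain CSV with header
``subject_id,aq_score``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import EpochedRecording


def save_cohort(out_dir, cohort: dict, fs: float, labels, t0: float,
                seed: int | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h5path = out / "cohort.h5"
    with h5py.File(h5path, "w") as fh:
        for subject, conditions in cohort.items():
            grp = fh.create_group(subject)
            for cond, rec in conditions.items():
                grp.create_dataset(cond, data=rec.data, chunks=True,
                                   compression="gzip", compression_opts=1)
    meta = {
        "fs": fs,
        "labels": list(labels),
        "t0": t0,
        "onset_index": int(round(-t0 * fs)),
        "subjects": sorted(cohort),
        "conditions": sorted({c for conds in cohort.values() for c in conds}),
        "seed": seed,
    }
    (out / "cohort.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return h5path


def load_cohort(in_dir) -> tuple[dict[str, dict[str, EpochedRecording]], dict]:
    src = Path(in_dir)
    meta = json.loads((src / "cohort.json").read_text())
    cohort: dict[str, dict[str, EpochedRecording]] = {}
    with h5py.File(src / "cohort.h5", "r") as fh:
        for subject in fh:
            cohort[subject] = {}
            for cond in fh[subject]:
                cohort[subject][cond] = EpochedRecording(
                    data=np.asarray(fh[subject][cond]),
                    fs=meta["fs"], labels=meta["labels"], t0=meta["t0"])
    return cohort, meta


def write_subject_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_subject_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
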