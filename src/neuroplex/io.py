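"""Plain-text file formats: matrices, time series, cohort tables, configs.

All artefacts are diffable text: square tab-separated matrices with a
matching ROI-label header row and index column (12 significant digits),
per-subject tab-separated time series with a YAML sidecar (sampling
rate, ground-truth IAF, seed), comma-separated cohort and results
tables, and YAML run configs with lossless round-trip.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import ConnectivityMatrix, RoiTimeSeriesSet
from .errors import LabelMismatchError

_FLOAT_FMT = "%.12g"


def write_matrix(m: ConnectivityMatrix, path: str | Path) -> Path:
    """Write one connectivity layer as a labelled square TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(m.values, index=m.labels, columns=m.labels)
    header = f"# modality={m.modality} band={m.band} directed={int(m.directed)}\n"
    with open(path, "w") as fh:
        fh.write(header)
        frame.to_csv(fh, sep="\t", float_format=_FLOAT_FMT)
    return path


def read_matrix(path: str | Path) -> ConnectivityMatrix:
    """Read a labelled square TSV back into a ConnectivityMatrix.

    Raises on non-square tables, row/column label mismatch and
    non-numeric cells.
    """
    path = Path(path)
    meta = {"modality": "FA", "band": "broadband", "directed": False}
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#"):
        skip = 1
        for token in first.lstrip("#").split():
            key, _, val = token.partition("=")
            if key == "directed":
                meta[key] = bool(int(val))
            elif key in meta:
                meta[key] = val
    frame = pd.read_csv(path, sep="\t", index_col=0, skiprows=skip)
    if frame.shape[0] != frame.shape[1]:
        raise ValueError(
            f"non-square matrix in {path.name}: {frame.shape[0]}x{frame.shape[1]}"
        )
    if list(frame.index.astype(str)) != list(frame.columns.astype(str)):
        raise LabelMismatchError(f"row/column label mismatch in {path.name}")
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"non-numeric cells in {path.name}")
    return ConnectivityMatrix(
        values=values,
        modality=meta["modality"],
        band=meta["band"],
        directed=meta["directed"],
        labels=list(frame.columns.astype(str)),
    )


def write_timeseries(ts: RoiTimeSeriesSet, path: str | Path) -> Path:
    """Write a subject's ROI time series as TSV plus a YAML sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(ts.data, columns=ts.labels)
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    sidecar = {
        "subject_id": ts.subject_id,
        "fs_hz": float(ts.fs_hz),
        "iaf_true_hz": None if ts.iaf_true_hz is None else float(ts.iaf_true_hz),
        "meta": {
            k: v for k, v in ts.meta.items() if isinstance(v, (int, float, str, list))
        },
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar, sort_keys=True))
    return path


def read_timeseries(path: str | Path) -> RoiTimeSeriesSet:
    """Read a subject's time series TSV and its YAML sidecar."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    sidecar_path = path.with_suffix(".yaml")
    sidecar = (
        yaml.safe_load(sidecar_path.read_text()) if sidecar_path.exists() else {}
    )
    return RoiTimeSeriesSet(
        data=frame.to_numpy(),
        labels=list(frame.columns),
        fs_hz=float(sidecar.get("fs_hz", 1.0)),
        subject_id=str(sidecar.get("subject_id", path.stem)),
        iaf_true_hz=sidecar.get("iaf_true_hz"),
        meta=sidecar.get("meta", {}) or {},
    )


def write_cohort_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_cohort_dir(cohort, directory: str | Path) -> Path:
    """Write a SyntheticCohort (time series, FA matrices, table, truth)."""
    directory = Path(directory)
    (directory / "timeseries").mkdir(parents=True, exist_ok=True)
    (directory / "structural").mkdir(parents=True, exist_ok=True)
    for ts in cohort.timeseries:
        write_timeseries(ts, directory / "timeseries" / f"{ts.subject_id}.tsv")
    for ts, mat in zip(cohort.timeseries, cohort.structural):
        write_matrix(mat, directory / "structural" / f"{ts.subject_id}_FA.tsv")
    write_cohort_table(cohort.table, directory / "cohort.csv")
    truth = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in cohort.truth.items()
    }
    truth["target_nodes"] = list(truth["target_nodes"])
    (directory / "ground_truth.yaml").write_text(yaml.safe_dump(truth))
    return directory


def read_cohort_dir(directory: str | Path):
    """Load the (timeseries, structural, table) triple written by write_cohort_dir."""
    directory = Path(directory)
    table = read_cohort_table(directory / "cohort.csv")
    timeseries, structural = [], []
    for sid in table["subject_id"]:
        timeseries.append(read_timeseries(directory / "timeseries" / f"{sid}.tsv"))
        structural.append(read_matrix(directory / "structural" / f"{sid}_FA.tsv"))
    return timeseries, structural, table


def save_config(config, path: str | Path) -> Path:
    """Serialise a RunConfig to YAML (round-trips via load_config)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return path


def load_config(path: str | Path):
    from .pipeline import RunConfig

    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))
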