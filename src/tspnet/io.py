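"""HDF5 epoch container and report export.

The container is self-describing: the data array, labels, sampling rate,
channel names, the class-name table and a mandatory provenance block
(generator config or import source, package version, seed) all live in the
file, so a reader needs no side information.
"""

from __future__ import annotations

import csv
import io as _io
import json
from pathlib import Path

import h5py
import numpy as np

from .core import CLASS_NAMES, ConfigurationError, EpochSet, ValidationError

FORMAT_VERSION = 1


def write_epoch_container(epochs: EpochSet, path, provenance: dict,
                          overwrite: bool = False) -> Path:
    """Write an :class:`EpochSet` to HDF5; provenance is mandatory."""
    if not provenance:
        raise ConfigurationError("a provenance block is required")
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True")
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["fs"] = float(epochs.fs)
        if epochs.subject_id is not None:
            f.attrs["subject_id"] = str(epochs.subject_id)
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("labels", data=epochs.labels)
        names = epochs.channel_names or tuple(
            f"ch{i}" for i in range(epochs.n_channels))
        f.create_dataset("channel_names",
                         data=np.array(names, dtype=h5py.string_dtype()))
        f.create_dataset("class_names",
                         data=np.array(CLASS_NAMES, dtype=h5py.string_dtype()))
        f.create_dataset("provenance",
                         data=json.dumps(provenance, sort_keys=True))
    return path


def read_epoch_container(path) -> EpochSet:
    """Read and validate a container; diagnostics name the first violation."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        version = f.attrs.get("format_version")
        if version != FORMAT_VERSION:
            raise ValidationError(
                f"container format version {version!r} not supported "
                f"(reader expects {FORMAT_VERSION})")
        names = tuple(n.decode() if isinstance(n, bytes) else str(n)
                      for n in f["channel_names"][()])
        subject = f.attrs.get("subject_id")
        return EpochSet(data=f["data"][()], labels=f["labels"][()],
                        fs=float(f.attrs["fs"]), channel_names=names,
                        subject_id=subject)


def read_provenance(path) -> dict:
    with h5py.File(path, "r") as f:
        return json.loads(f["provenance"][()])


# -- reports ---------------------------------------------------------------


def _report_rows(report) -> list[dict]:
    """Normalise an EvalReport or an ablation table into percent rows."""
    if hasattr(report, "as_dict"):
        report = {"result": report.as_dict()}
    rows = []
    for name, rec in report.items():
        row = {"name": name,
               "mean_pct": round(100 * rec["mean"], 1),
               "sd_pct": round(100 * rec["sd"], 1)}
        if "p_vs_tspnet" in rec:
            row["p_vs_tspnet"] = rec["p_vs_tspnet"]
        rows.append(row)
    return rows


def export_report(report, path, fmt: str = "json") -> Path:
    """Write an evaluation report as JSON (full precision) or CSV (percent).

    CSV mirrors the tabular "mean ± SD (in %)" layout with one decimal;
    JSON keeps every partition accuracy at full precision.
    """
    path = Path(path)
    if fmt == "json":
        payload = (report.as_dict() if hasattr(report, "as_dict") else report)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    elif fmt == "csv":
        rows = _report_rows(report)
        buf = _io.StringIO()
        writer = csv.DictWriter(buf, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
        path.write_text(buf.getvalue())
    else:
        raise ConfigurationError(f"unknown report format {fmt!r}")
    return path


def export_viz_scores(scores: dict, montage, path) -> Path:
    """CSV of (class, band, electrode, score) from the attribution pipeline."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["class", "band", "electrode", "score"])
        for (cls, band), vec in sorted(scores.items()):
            if vec is None:
                continue
            for name, s in zip(montage.channel_names, vec):
                writer.writerow([cls, band, name, f"{s:.6g}"])
    return path
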