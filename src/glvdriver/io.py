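"""Readers and writers for abundance tables, datasets, models, and results.

All on-disk formats are plain text: counts/metadata/biomass as TSV or CSV
(delimiter sniffed), community models as JSON, results as TSV plus a JSON
manifest with per-file checksums so a run directory is self-describing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .glv import CommunityModel
from .preprocess import AbundanceTable
from .simulate import SubjectSeries, TimeSeriesDataset

__all__ = [
    "RunConfig",
    "read_table",
    "read_abundance_table",
    "read_biomass",
    "dataset_from_table",
    "table_from_dataset",
    "write_dataset",
    "read_dataset",
    "write_results",
]


@dataclasses.dataclass
class RunConfig:
    """Settings of one pipeline invocation; YAML round-trippable."""

    command: str
    params: dict = dataclasses.field(default_factory=dict)
    seed: int | None = None
    inputs: dict = dataclasses.field(default_factory=dict)
    output_dir: str | None = None

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def read_table(path: str | Path, index_col: int = 0) -> pd.DataFrame:
    """Read a TSV/CSV table with the delimiter sniffed from the content."""
    return pd.read_csv(path, sep=None, engine="python", index_col=index_col)


def _normalize_meta(meta: pd.DataFrame) -> pd.DataFrame:
    meta = meta.copy()
    rename = {}
    for col in meta.columns:
        low = col.lower()
        if low in ("subject", "subject_id"):
            rename[col] = "subject"
        elif low == "time":
            rename[col] = "time"
        elif low == "sample_id":
            rename[col] = "sample_id"
    meta = meta.rename(columns=rename)
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    elif meta.columns[0].startswith("Unnamed"):
        meta = meta.set_index(meta.columns[0])
        meta.index.name = "sample_id"
    missing = {"subject", "time"} - set(meta.columns)
    if missing:
        raise ValueError(f"metadata lacks required columns: {sorted(missing)}")
    meta["subject"] = meta["subject"].astype(str)
    meta["time"] = meta["time"].astype(float)
    return meta


def read_abundance_table(
    counts_path: str | Path,
    metadata_path: str | Path,
    orientation: str = "auto",
) -> AbundanceTable:
    """Read counts + metadata into an :class:`AbundanceTable`.

    ``orientation`` is ``'taxa_rows'`` (the default amplicon convention,
    taxa as rows and samples as columns), ``'samples_rows'``, or ``'auto'``
    to decide from which axis overlaps the metadata sample ids.
    """
    values = read_table(counts_path)
    meta = _normalize_meta(pd.read_csv(metadata_path, sep=None, engine="python"))
    if orientation == "auto":
        col_hits = sum(1 for c in values.columns if str(c) in meta.index)
        row_hits = sum(1 for r in values.index if str(r) in meta.index)
        if col_hits >= row_hits and col_hits > 0:
            orientation = "taxa_rows"
        elif row_hits > 0:
            orientation = "samples_rows"
        else:
            raise ValueError(
                "cannot auto-detect orientation: no axis labels match the "
                "metadata sample ids; pass orientation explicitly"
            )
    if orientation == "samples_rows":
        values = values.T
    elif orientation != "taxa_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    values = values.astype(float)
    if not np.all(np.isfinite(values.to_numpy())):
        raise ValueError("counts table contains non-finite values")
    neg = np.argwhere(values.to_numpy() < 0)
    if neg.size:
        r, c = neg[0]
        raise ValueError(
            f"negative abundance at taxon {values.index[r]!r}, "
            f"sample {values.columns[c]!r}"
        )
    absent = [s for s in values.columns if s not in meta.index]
    if absent:
        raise ValueError(f"samples missing from metadata: {absent}")
    return AbundanceTable(values=values, meta=meta)


def read_biomass(path: str | Path) -> pd.Series:
    """Read a (sample_id, biomass) table into a Series."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.lower() for c in df.columns]
    if "sample_id" not in df.columns:
        df = df.rename(columns={df.columns[0]: "sample_id"})
    value_col = [c for c in df.columns if c != "sample_id"][0]
    series = df.set_index("sample_id")[value_col].astype(float)
    if (series <= 0).any():
        raise ValueError("biomass values must be positive")
    return series


# ---------------------------------------------------------------------------
# dataset <-> table conversion and on-disk layout
# ---------------------------------------------------------------------------

def _sample_id(subject: str, t: float) -> str:
    return f"{subject}_T{t:g}"


def table_from_dataset(dataset: TimeSeriesDataset) -> AbundanceTable:
    """Flatten a dataset into a taxa x samples table plus metadata."""
    cols, meta_rows = {}, []
    for subj in dataset.subjects:
        for s, t in enumerate(subj.times):
            sid = _sample_id(subj.subject, t)
            cols[sid] = subj.counts[s]
            meta_rows.append({"sample_id": sid, "subject": subj.subject, "time": t})
    values = pd.DataFrame(cols, index=pd.Index(dataset.taxa, name="taxon"))
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return AbundanceTable(values=values, meta=meta)


def dataset_from_table(table: AbundanceTable) -> TimeSeriesDataset:
    """Group a sample table into per-subject, time-sorted series."""
    subjects = []
    for subject, sub in table.meta.groupby("subject", sort=True):
        sub = sub.sort_values("time")
        counts = table.values[sub.index].to_numpy(dtype=float).T
        subjects.append(
            SubjectSeries(
                subject=str(subject),
                times=sub["time"].to_numpy(dtype=float),
                counts=counts,
            )
        )
    return TimeSeriesDataset(taxa=list(table.taxa), subjects=subjects)


def write_dataset(dataset: TimeSeriesDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write counts/metadata TSVs plus truth JSON and latents TSV if present."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = table_from_dataset(dataset)
    paths = {
        "counts": out / "counts.tsv",
        "metadata": out / "metadata.tsv",
    }
    table.values.to_csv(paths["counts"], sep="\t")
    table.meta.to_csv(paths["metadata"], sep="\t")
    if dataset.truth is not None:
        paths["truth"] = out / "truth.json"
        dataset.truth.to_json(paths["truth"])
    if all(s.latent is not None for s in dataset.subjects):
        rows = {}
        for subj in dataset.subjects:
            for s, t in enumerate(subj.times):
                rows[_sample_id(subj.subject, t)] = subj.latent[s]
        latents = pd.DataFrame(rows, index=pd.Index(dataset.taxa, name="taxon"))
        paths["latents"] = out / "latents.tsv"
        latents.to_csv(paths["latents"], sep="\t")
    return paths


def read_dataset(
    counts_path: str | Path,
    metadata_path: str | Path,
    orientation: str = "auto",
) -> TimeSeriesDataset:
    """Read counts + metadata files into a dataset (no ground truth)."""
    return dataset_from_table(read_abundance_table(counts_path, metadata_path, orientation))


# ---------------------------------------------------------------------------
# result directories
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_results(objects: Mapping[str, object], out_dir: str | Path) -> Path:
    """Write a mapping of named result objects and a checksum manifest.

    Dispatch by type: :class:`CommunityModel` -> JSON, DataFrame/Series ->
    TSV, dict -> JSON, :class:`RunConfig` -> YAML.  Returns the manifest
    path; the manifest lists every file with its SHA-256 so reruns can be
    compared byte-for-byte (only the manifest timestamp differs).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, obj in objects.items():
        if isinstance(obj, CommunityModel):
            path = out / f"{name}.json"
            obj.to_json(path)
        elif isinstance(obj, pd.DataFrame):
            path = out / f"{name}.tsv"
            obj.to_csv(path, sep="\t")
        elif isinstance(obj, pd.Series):
            path = out / f"{name}.tsv"
            obj.to_frame().to_csv(path, sep="\t")
        elif isinstance(obj, RunConfig):
            path = out / f"{name}.yaml"
            obj.to_yaml(path)
        elif isinstance(obj, dict):
            path = out / f"{name}.json"
            path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str) + "\n")
        else:
            raise TypeError(f"cannot serialize result {name!r} of type {type(obj)}")
        written.append(path)
    manifest = {
        "created": datetime.now(timezone.utc).isoformat(),
        "files": {p.name: _sha256(p) for p in sorted(written)},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest_path
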