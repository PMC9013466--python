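"""Tabular I/O: counts/sample-sheet/gene-length TSVs, GMT gene sets,
DEG tables, study manifests and run logs.

All tabular files are tab-separated UTF-8 with a header row; the first
column of a count matrix holds gene ids and the remaining columns are
samples.  Outputs are written to a temporary sibling and moved into place
on success so failed runs leave no partial files.
"""

from __future__ import annotations

import json
import os
import tempfile
import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import CountMatrix
from .meta import Study, StudySet
from .purity import MarkerPanel

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_gmt",
    "write_gmt",
    "read_deg_table",
    "write_deg_table",
    "read_study_manifest",
    "read_marker_panel",
    "default_marker_panel",
    "atomic_write",
    "write_run_log",
]


def read_counts_tsv(
    counts_path, samples_path, lengths_path=None
) -> CountMatrix:
    """Load a CountMatrix from a counts TSV and a sample-sheet TSV.

    The sample sheet needs ``sample_id`` and ``group`` columns (``study``
    optional).  Counts must be non-negative integers; duplicate ids,
    negative or fractional values and samples missing from the sheet are
    rejected with a message naming the offender.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(samples_path, sep="\t")
    if "sample_id" not in meta.columns or "group" not in meta.columns:
        raise ValueError("sample sheet must have 'sample_id' and 'group' columns")
    meta = meta.set_index("sample_id")
    lengths = None
    if lengths_path is not None:
        lt = pd.read_csv(lengths_path, sep="\t", index_col=0)
        lengths = lt.iloc[:, 0]
    return CountMatrix(counts, meta, lengths)


def write_counts_tsv(cm: CountMatrix, counts_path, samples_path) -> None:
    cm.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    cm.sample_meta.rename_axis("sample_id").to_csv(samples_path, sep="\t")


def read_gmt(path) -> dict:
    """Parse a GMT file into an ordered ``{set name: (description, genes)}``
    map; duplicate members are deduplicated with a warning."""
    sets: dict = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}, line {ln}: empty set {parts[0]!r}")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise ValueError(f"{path}, line {ln}: empty set {name!r}")
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r}")
            uniq = list(dict.fromkeys(genes))
            if len(uniq) < len(genes):
                warnings.warn(f"GMT set {name!r}: duplicate members removed")
            sets[name] = (desc, uniq)
    return sets


def write_gmt(sets: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, (desc, genes) in sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_deg_table(path) -> pd.DataFrame:
    deg = pd.read_csv(path, sep="\t", index_col=0)
    deg["significant"] = deg["significant"].astype(bool)
    return deg


def write_deg_table(deg: pd.DataFrame, path) -> None:
    deg.rename_axis("gene_id").to_csv(path, sep="\t")


def read_study_manifest(path) -> StudySet:
    """Load a StudySet from a YAML manifest.

    Layout::

        studies:
          - name: studyA
            counts: a_counts.tsv
            samples: a_samples.tsv
            comparisons:
              - [case_group, control_group]

    Relative paths resolve against the manifest's directory.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    studies = []
    for entry in doc["studies"]:
        cm = read_counts_tsv(
            path.parent / entry["counts"], path.parent / entry["samples"]
        )
        comps = [tuple(c) for c in entry["comparisons"]]
        studies.append(Study(entry["name"], cm, comps))
    return StudySet(studies)


def _panel_from_gmt(sets: dict, threshold: float = 1.0) -> MarkerPanel:
    present, absent = {}, {}
    for name, (desc, genes) in sets.items():
        if desc.startswith("expected_absent"):
            absent[name] = genes
        else:
            present[name] = genes
    return MarkerPanel(present, absent, threshold=threshold)


def read_marker_panel(path, threshold: float = 1.0) -> MarkerPanel:
    """Read a marker panel GMT; sets whose description starts with
    ``expected_absent`` are contaminant classes, all others signatures."""
    return _panel_from_gmt(read_gmt(path), threshold)


def default_marker_panel(threshold: float = 1.0) -> MarkerPanel:
    """The shipped microglia signature / contaminant panel."""
    ref = resources.files("stimskew").joinpath("data/markers.gmt")
    with resources.as_file(ref) as p:
        return read_marker_panel(p, threshold)


class atomic_write:
    """Context manager: stage outputs in a temp dir, move them into
    ``out_dir`` only if the block succeeds."""

    def __init__(self, out_dir):
        self.out_dir = Path(out_dir)

    def __enter__(self) -> Path:
        self.out_dir.mkdir(parents=True, exist_ok=True)
        self._tmp = Path(tempfile.mkdtemp(prefix=".stage-", dir=self.out_dir))
        return self._tmp

    def __exit__(self, exc_type, exc, tb):
        if exc_type is None:
            for p in sorted(self._tmp.rglob("*")):
                rel = p.relative_to(self._tmp)
                dest = self.out_dir / rel
                if p.is_dir():
                    dest.mkdir(parents=True, exist_ok=True)
                else:
                    dest.parent.mkdir(parents=True, exist_ok=True)
                    os.replace(p, dest)
        # clean up whatever remains (everything, on failure)
        for p in sorted(self._tmp.rglob("*"), reverse=True):
            p.rmdir() if p.is_dir() else p.unlink()
        self._tmp.rmdir()
        return False


def write_run_log(path, stage: str, params: dict, summary: dict) -> None:
    """Append one structured JSON line describing a pipeline stage."""
    import stimskew

    rec = {
        "stage": stage,
        "version": stimskew.__version__,
        "params": _jsonable(params),
        "summary": _jsonable(summary),
    }
    with open(path, "a", encoding="utf-8") as fh:
        fh.write(json.dumps(rec, sort_keys=True) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj
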