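"""Readers and writers tying the pipeline to files on disk.

FASTA carries the label and split in the header (``>id|label=1|split=train``)
since the upstream benchmark ships sequences and labels in varying layouts;
a two-column table (sequence, label; TSV or CSV, optional header) covers
the alternative. Every run writes a manifest recording the configuration,
seed, package version and metric outputs so a run can be reconstructed
exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import LabeledDataset, SequenceRecord

__all__ = ["read_fasta", "write_fasta", "read_labeled_table",
           "write_labeled_table", "write_manifest", "load_run_config"]

_VALID = set("ACGTN")


def _check_sequence(seq: str, where: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"{where}: invalid characters {sorted(bad)}")
    return seq


def read_fasta(path: str | Path) -> LabeledDataset:
    """Parse FASTA; label/split read from ``|key=value`` header fields.

    Records whose length differs from the first record are rejected.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    length = None
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = _check_sequence(str(rec.seq), f"{path}: record {i + 1}")
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise ValueError(
                f"{path}: record {i + 1} has length {len(seq)}, "
                f"expected {length} (mixed lengths)")
        fields = dict(part.split("=", 1) for part in
                      rec.description.split("|")[1:] if "=" in part)
        label = fields.get("label")
        records.append(SequenceRecord(
            id=rec.id.split("|")[0],
            sequence=seq,
            label=int(label) if label is not None else -1,
            split=fields.get("split")))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return LabeledDataset(records=tuple(records), name=path.stem)


def write_fasta(dataset: LabeledDataset, path: str | Path) -> None:
    recs = []
    for r in dataset.records:
        desc = f"label={r.label}"
        if r.split:
            desc += f"|split={r.split}"
        recs.append(SeqRecord(Seq(r.sequence), id=f"{r.id}|{desc}",
                              description=""))
    SeqIO.write(recs, str(path), "fasta")


def read_labeled_table(path: str | Path) -> LabeledDataset:
    """Two-column (sequence, label) table; TSV or CSV, header optional."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", header=None,
                     dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sequence, label)")
    first = str(df.iloc[0, 0]).upper()
    if set(first) - _VALID:          # header row auto-detected and skipped
        df = df.iloc[1:].reset_index(drop=True)
    records = []
    for i, row in df.iterrows():
        seq = _check_sequence(str(row.iloc[0]), f"{path}: row {i + 1}")
        raw = str(row.iloc[1]).strip()
        if raw not in {"0", "1"}:
            raise ValueError(f"{path}: row {i + 1} has non-binary label {raw!r}")
        records.append(SequenceRecord(id=f"seq_{i}", sequence=seq,
                                      label=int(raw)))
    return LabeledDataset(records=tuple(records), name=path.stem)


def write_labeled_table(dataset: LabeledDataset, path: str | Path,
                        sep: str = "\t") -> None:
    pd.DataFrame({"sequence": dataset.sequences,
                  "label": dataset.labels}).to_csv(path, sep=sep, index=False)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_manifest(output_dir: str | Path, config: dict, seed: int,
                   metrics: dict | None = None) -> Path:
    """Record everything needed to reconstruct a run."""
    from . import __version__
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "methylfusion",
        "version": __version__,
        "seed": seed,
        "config": _jsonable(config),
        "metrics": _jsonable(metrics or {}),
    }
    path = output_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def load_run_config(path: str | Path) -> dict:
    """YAML or JSON run configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        return yaml.safe_load(text)
    return json.loads(text)
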