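"""File formats and run manifests.

Expression travels as TSV/CSV with genes as rows (a gene-id first column)
and samples as columns; annotation as CSV with one row per sample; configs
as YAML; reports and manifests as JSON. Every pipeline command records a
RunManifest so each artifact can be traced to the command, config, inputs
and seeds that produced it.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

__all__ = [
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_annotation",
    "run_manifest",
    "write_manifest",
]

NA_TOKENS = ["", "NA"]
REQUIRED_ANNOT_COLUMNS = ["sample_id", "site", "lineage", "sex", "specimen_type",
                          "dataset_id"]
SEX_VOCAB = {"female", "male", "missing"}
SPECIMEN_VOCAB = {"primary", "metastatic"}


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path: str | Path) -> pd.DataFrame:
    """Gene x sample numeric matrix; '' and 'NA' parse as missing."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0,
                     na_values=NA_TOKENS, keep_default_na=False)
    if df.empty:
        raise ValueError(f"{path}: empty expression file")
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicated gene ids: {dupes}")
    non_numeric = [c for c in df.columns
                   if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric cells in samples {non_numeric}")
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return df.astype(float)


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    matrix.to_csv(path, sep=_sep_for(path), index_label="gene_id", na_rep="NA")


def read_annotation(
    path: str | Path,
    site_vocab=None,
    lineage_vocab=None,
    samples=None,
) -> pd.DataFrame:
    """Per-sample labels, validated against controlled vocabularies.

    Unknown labels are rejected with their (1-based, data) row numbers;
    ``samples``, when given, must all be present in the annotation.
    """
    path = Path(path)
    df = pd.read_csv(path, na_values=NA_TOKENS, keep_default_na=False)
    missing_cols = [c for c in REQUIRED_ANNOT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required columns {missing_cols}")
    df["sex"] = df["sex"].fillna("missing")
    errors = []
    checks = [("sex", SEX_VOCAB), ("specimen_type", SPECIMEN_VOCAB)]
    if site_vocab is not None:
        checks.append(("site", set(site_vocab)))
    if lineage_vocab is not None:
        checks.append(("lineage", set(lineage_vocab)))
    for col, vocab in checks:
        bad = ~df[col].isin(vocab)
        for row in df.index[bad]:
            errors.append(f"row {row + 1}: unknown {col} label {df.loc[row, col]!r}")
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))
    df = df.set_index("sample_id")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicated sample ids")
    if samples is not None:
        absent = [s for s in samples if s not in df.index]
        if absent:
            raise ValueError(f"{path}: samples missing from annotation: {absent[:10]}")
    return df


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, index_label="sample_id")


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_manifest(command: str, seed: int | None = None,
                 config: dict | None = None,
                 inputs: dict[str, str | Path] | None = None) -> dict:
    from . import __version__

    return {
        "command": command,
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(config or {}, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "input_hashes": {
            name: _file_hash(Path(p)) for name, p in (inputs or {}).items()
        },
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }


def write_manifest(manifest: dict, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
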