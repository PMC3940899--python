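"""Readers and writers for the package's delimited-text interchange formats.

Expression matrices travel as TSV/CSV with a header row of sample ids and a
header column of gene ids; pathways travel as GMT (one tab-separated gene set
per line: name, description, members); labels as two-column TSV. All formats
round-trip bit-exactly on ASCII inputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import GeneExpressionMatrix, LabelVector, PathwayCollection
from .errors import ParseError, ValidationError


def read_expression_matrix(path, delimiter: str = "\t") -> GeneExpressionMatrix:
    """Read a genes x samples matrix (first row sample ids, first column gene ids)."""
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            try:
                values[i, j] = float(raw[i, j])
            except (TypeError, ValueError):
                raise ParseError(
                    f"non-numeric value {raw[i, j]!r} at gene {gene_ids[i]!r}, "
                    f"sample {sample_ids[j]!r} in {path}"
                ) from None
    return GeneExpressionMatrix(values, gene_ids, sample_ids)


def write_expression_matrix(matrix: GeneExpressionMatrix, path, delimiter: str = "\t") -> None:
    matrix.to_dataframe().to_csv(path, sep=delimiter)


def read_gmt(path) -> PathwayCollection:
    """Read a GMT file: one gene set per line (name, description, members...)."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields "
                    f"(name, description, members), got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise ParseError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
    return PathwayCollection(sets, source_tag=str(path))


def write_gmt(pathways: PathwayCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in pathways.sets:
            members = sorted(pathways.sets[name])
            fh.write("\t".join([name, description, *members]) + "\n")


def read_labels(path, delimiter: str = "\t") -> pd.Series:
    """Read a two-column (sample_id, label) file; returns a Series indexed by sample id."""
    df = pd.read_csv(path, sep=delimiter, header=None, dtype=str, comment="#")
    if df.shape[1] != 2:
        raise ParseError(f"{path}: label file must have exactly 2 columns")
    series = pd.Series(df[1].to_numpy(), index=df[0].to_numpy())
    if series.index.duplicated().any():
        raise ValidationError(f"{path}: duplicate sample ids in label file")
    return series


def write_labels(labels: LabelVector, sample_ids, path, delimiter: str = "\t") -> None:
    pd.Series(labels.labels, index=list(sample_ids)).to_csv(
        path, sep=delimiter, header=False
    )


def align_labels(labels: pd.Series, sample_ids) -> LabelVector:
    """Reorder a label Series to the expression matrix's sample order."""
    missing = [s for s in sample_ids if s not in labels.index]
    if missing:
        raise ValidationError(f"samples without labels: {missing}")
    return LabelVector(labels.loc[list(sample_ids)].tolist())


def write_coordinates(coords: np.ndarray, ids, path, delimiter: str = "\t") -> None:
    """Write an embedding (rows = points, columns = component_1..component_d)."""
    cols = [f"component_{i + 1}" for i in range(coords.shape[1])]
    pd.DataFrame(np.asarray(coords), index=list(ids), columns=cols).to_csv(
        path, sep=delimiter
    )


def read_coordinates(path, delimiter: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=delimiter, index_col=0)


def write_manifest(manifest: dict, path) -> None:
    """Write the run manifest (config echo, eigenvalue spectrum, seed) as YAML or JSON."""
    path = Path(path)
    text_manifest = _jsonable(manifest)
    with open(path, "w") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(text_manifest, fh, sort_keys=True)
        else:
            json.dump(text_manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
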