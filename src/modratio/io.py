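"""File formats: sample matrices, modularization specs, edge lists.

All formats are plain delimited text. Sample matrices are TSV with one
row per sample and a header of component labels; the reference
component is the last column unless named explicitly. Expression data
follow the DREAM5 layout (first row gene identifiers, one chip per
subsequent row). Parsers reject malformed input instead of coercing it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grn import ExpressionDataset, GoldStandard, RankedInteractionList
from .samples import SampleMatrix, center_samples
from .structure import Modularization

__all__ = [
    "read_sample_matrix",
    "write_sample_matrix",
    "read_modularization",
    "write_modularization",
    "read_expression",
    "read_tf_list",
    "read_edge_list",
    "write_edge_list",
    "read_gold",
    "write_matrix_tsv",
]

FLOAT_FMT = "%.6g"


def read_sample_matrix(path: str | Path, ref_label: str | None = None) -> SampleMatrix:
    """Read a TSV sample matrix and center it; reference component last."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=float)
    except ValueError as err:
        raise ValueError(f"{path}: non-numeric or ragged body ({err})") from err
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate headers {dupes}")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no samples")
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax()) + 2  # +header +1-based
        raise ValueError(f"{path}: missing or non-numeric cell near line {bad}")
    cols = list(df.columns)
    if ref_label is not None:
        if ref_label not in cols:
            raise ValueError(f"{path}: reference label {ref_label!r} not found")
        cols = [c for c in cols if c != ref_label] + [ref_label]
        df = df[cols]
    return center_samples(df.to_numpy().T, labels=cols)


def write_sample_matrix(path: str | Path, s: SampleMatrix) -> None:
    df = pd.DataFrame(s.values.T, columns=s.labels)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_modularization(path: str | Path) -> Modularization:
    """Read a modularization spec (JSON: ref, modules, kind, label)."""
    data = json.loads(Path(path).read_text())
    return Modularization.from_sets(
        [frozenset(m) for m in data.get("modules", [])],
        ref=int(data["ref"]),
        kind=data.get("kind", "nested"),
        label=data.get("label", ""),
    )


def write_modularization(path: str | Path, m: Modularization) -> None:
    data = {
        "ref": m.ref,
        "modules": [list(t) for t in m.sorted_modules()],
        "kind": m.kind,
        "label": m.label,
    }
    Path(path).write_text(json.dumps(data, indent=1) + "\n")


def read_expression(path: str | Path, tf_labels: list[str]) -> ExpressionDataset:
    """Read a DREAM5-style expression matrix (genes in the header row)."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate gene identifiers")
    unknown = [t for t in tf_labels if t not in df.columns]
    if unknown:
        raise ValueError(f"{path}: TF labels not in expression data: {unknown}")
    flags = {g: g in set(tf_labels) for g in df.columns}
    return ExpressionDataset(matrix=df.astype(float), tf_flags=flags)


def read_tf_list(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def read_edge_list(path: str | Path) -> RankedInteractionList:
    """Read a TSV edge list TF<TAB>target<TAB>confidence, best first."""
    rows = []
    lines = Path(path).read_text().splitlines()
    for i, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{i}: expected TF<TAB>target<TAB>confidence")
        rows.append((parts[0], parts[1], float(parts[2])))
    n = len(rows)
    confs = [c for _, _, c in rows]
    if any(b > a for a, b in zip(confs, confs[1:])):
        import warnings

        warnings.warn(f"{path}: confidence column is not descending", stacklevel=2)
    edges = [(tf, tg, c, (i + 1) / n) for i, (tf, tg, c) in enumerate(rows)]
    return RankedInteractionList(edges=edges)


def write_edge_list(path: str | Path, ranked: RankedInteractionList) -> None:
    with open(path, "w") as fh:
        for tf, tg, conf, _ in ranked.edges:
            fh.write(f"{tf}\t{tg}\t{FLOAT_FMT % conf}\n")


def read_gold(path: str | Path, known_genes: set[str] | None = None) -> GoldStandard:
    """Read a gold standard TSV TF<TAB>target<TAB>{0,1}."""
    labels: dict[tuple[str, str], int] = {}
    offenders = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3 or parts[2] not in {"0", "1"}:
            raise ValueError(f"{path}:{i}: expected TF<TAB>target<TAB>0|1")
        tf, tg, lab = parts[0], parts[1], int(parts[2])
        if known_genes is not None and (tf not in known_genes or tg not in known_genes):
            offenders.append((tf, tg))
        labels[(tf, tg)] = lab
    if offenders:
        raise ValueError(f"{path}: unknown gene labels in gold standard: {offenders}")
    return GoldStandard(labels=labels)


def write_matrix_tsv(path: str | Path, matrix: np.ndarray, labels: list[str]) -> None:
    """Write a labelled square matrix (B matrix, covariance) for inspection."""
    df = pd.DataFrame(np.asarray(matrix), index=labels, columns=labels)
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)
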