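"""Readers and writers for the plain-text formats the pipeline touches.

Dialects (all UTF-8, comma-separated with a header row unless noted):

* expression CSV — first column ``id`` (cell/sample), remaining columns genes;
* Ct CSV — same layout, with ``ND`` or an empty cell marking not-detected;
* metadata / clinical CSV — first column ``id``, remaining columns covariates;
* plates CSV — long format with columns
  ``agent, condition, dose, replicate, value, is_control``;
* GMT — tab-separated: set name, description, then gene symbols (one set
  per line).

Readers validate container invariants on load and report malformed rows
with their line numbers.  Write -> read round-trips the typed objects.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CtMatrix, ExpressionMatrix, GeneSignature
from .cohort import SurvivalCohort
from .dose_response import DoseResponseSeries

__all__ = [
    "read_expression_csv",
    "write_expression_csv",
    "read_ct_csv",
    "write_ct_csv",
    "read_gmt",
    "write_gmt",
    "read_plates_csv",
    "write_plates_csv",
    "read_clinical_csv",
    "write_clinical_csv",
]

ND_SENTINEL = "ND"


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"{path}: empty or missing file")
    frame = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    frame.index.name = None
    return frame


def _to_float(frame: pd.DataFrame, path, allow_blank: bool = False) -> pd.DataFrame:
    out = {}
    for col in frame.columns:
        converted = []
        for lineno, raw in enumerate(frame[col], start=2):  # header is line 1
            text = raw.strip()
            if text in ("", ND_SENTINEL):
                if allow_blank:
                    converted.append(np.nan)
                    continue
                raise ValueError(f"{path}: line {lineno}, column {col!r}: empty cell")
            try:
                converted.append(float(text))
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}, column {col!r}: non-numeric value {text!r}"
                ) from None
        out[col] = converted
    return pd.DataFrame(out, index=frame.index)


def read_expression_csv(path, meta_path=None) -> ExpressionMatrix:
    frame = _read_table(path)
    data = _to_float(frame, path)
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, index_col=0)
        meta.index.name = None
    return ExpressionMatrix(data, meta=meta)


def write_expression_csv(expr: ExpressionMatrix, path, meta_path=None) -> None:
    expr.data.to_csv(path, index_label="id")
    if meta_path is not None and expr.meta is not None:
        expr.meta.to_csv(meta_path, index_label="id")


def read_ct_csv(path, lod: float = 24.0, meta_path=None) -> CtMatrix:
    frame = _read_table(path)
    ct = _to_float(frame, path, allow_blank=True)
    detected = ct.notna()
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, index_col=0)
        meta.index.name = None
    return CtMatrix(ct=ct, detected=detected, lod=lod, meta=meta)


def write_ct_csv(ct: CtMatrix, path, meta_path=None) -> None:
    out = ct.ct.where(ct.detected).copy()
    out = out.astype(object).where(ct.detected, ND_SENTINEL)
    out.to_csv(path, index_label="id")
    if meta_path is not None and ct.meta is not None:
        ct.meta.to_csv(meta_path, index_label="id")


def read_gmt(path) -> list[GeneSignature]:
    path = Path(path)
    signatures = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT needs name, description, >=1 gene"
                )
            name, _desc, *genes = parts
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}: line {lineno}: gene set {name!r} is empty")
            signatures.append(GeneSignature(name, tuple(genes)))
    if not signatures:
        raise ValueError(f"{path}: no gene sets found")
    return signatures


def write_gmt(signatures: list[GeneSignature], path, descriptions=None) -> None:
    descriptions = descriptions or {}
    with Path(path).open("w", encoding="utf-8") as fh:
        for sig in signatures:
            desc = descriptions.get(sig.name, "na")
            fh.write("\t".join([sig.name, desc, *sig.genes]) + "\n")


PLATE_COLUMNS = ["agent", "condition", "dose", "replicate", "value", "is_control"]


def read_plates_csv(path) -> list[DoseResponseSeries]:
    """Long-format plate table -> one series per (agent, condition).

    ``value`` is viability as a fraction of control (already normalized) for
    non-control rows; control rows (``is_control`` true) are ignored here
    and exist so raw exports can carry their reference wells.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"{path}: empty or missing file")
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in PLATE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing plate columns {missing}")
    frame = frame[~frame["is_control"].astype(bool)]
    series = []
    for (agent, condition), grp in frame.groupby(["agent", "condition"], sort=True):
        pivot = grp.pivot_table(
            index="replicate", columns="dose", values="value", aggfunc="first"
        ).sort_index(axis=1)
        if pivot.isna().any().any():
            raise ValueError(
                f"{path}: agent {agent!r} condition {condition!r}: "
                "unequal replicate count across doses"
            )
        series.append(
            DoseResponseSeries(
                agent=str(agent),
                condition=str(condition),
                doses=pivot.columns.to_numpy(dtype=float),
                viability=pivot.to_numpy(dtype=float),
            )
        )
    if not series:
        raise ValueError(f"{path}: no non-control rows")
    return series


def write_plates_csv(series_list: list[DoseResponseSeries], path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PLATE_COLUMNS)
        for s in series_list:
            for rep in range(s.n_replicates):
                for j, dose in enumerate(s.doses):
                    writer.writerow(
                        [s.agent, s.condition, repr(float(dose)), rep,
                         repr(float(s.viability[rep, j])), 0]
                    )


def read_clinical_csv(path) -> SurvivalCohort:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"{path}: empty or missing file")
    table = pd.read_csv(path, index_col=0)
    table.index.name = None
    return SurvivalCohort(table)


def write_clinical_csv(cohort: SurvivalCohort, path) -> None:
    cohort.table.to_csv(path, index_label="id")
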