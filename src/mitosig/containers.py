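"""Core in-memory containers shared across the pipeline.

All tabular containers wrap :class:`pandas.DataFrame` with rows as
cells-or-samples and columns as genes, plus an optional metadata frame
aligned on the row index.  Identifiers are case-sensitive exact strings;
no symbol aliasing is performed (mouse ``Bub1`` and human ``BUB1`` are
distinct genes to this package).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GeneSignature", "ExpressionMatrix", "CtMatrix"]


@dataclass(frozen=True)
class GeneSignature:
    """A named gene list scored as the average per-gene Z across cells/samples.

    Duplicate gene symbols are removed on construction (first occurrence
    kept), so scoring a signature is invariant to accidental repetition.
    """

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("signature name must be non-empty")
        if len(self.genes) == 0:
            raise ValueError(f"signature {self.name!r} has no genes")
        deduped = tuple(dict.fromkeys(self.genes))
        object.__setattr__(self, "genes", deduped)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


def _check_unique(index: pd.Index, what: str) -> None:
    if not index.is_unique:
        dupes = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} identifiers: {dupes[:5]}")


@dataclass
class ExpressionMatrix:
    """Cells-or-samples x genes log2 expression with optional row metadata.

    Values must be finite.  ``meta``, when given, is indexed like ``data``.
    """

    data: pd.DataFrame
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample/cell")
        _check_unique(self.data.columns, "gene")
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("expression matrix contains non-finite values")
        self.data = self.data.astype(float)
        if self.meta is not None and not self.meta.index.equals(self.data.index):
            raise ValueError("metadata index does not match expression rows")

    @property
    def genes(self) -> pd.Index:
        return self.data.columns

    @property
    def samples(self) -> pd.Index:
        return self.data.index


@dataclass
class CtMatrix:
    """Raw single-cell qPCR cycle-threshold values with a detection mask.

    ``detected`` is a boolean frame aligned with ``ct``; False marks a
    not-detected reaction (no amplification before the limit of detection).
    Ct entries where ``detected`` is True must be positive; undetected
    entries are ignored (conventionally NaN).
    """

    ct: pd.DataFrame
    detected: pd.DataFrame
    lod: float = 24.0
    meta: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.lod <= 0:
            raise ValueError("limit of detection must be positive")
        _check_unique(self.ct.index, "cell")
        _check_unique(self.ct.columns, "gene")
        if not (
            self.detected.index.equals(self.ct.index)
            and self.detected.columns.equals(self.ct.columns)
        ):
            raise ValueError("detection mask not aligned with Ct matrix")
        ct = self.ct.to_numpy(dtype=float)
        det = self.detected.to_numpy(dtype=bool)
        if np.any(det & ~(ct > 0)):
            raise ValueError("detected Ct values must be positive cycles")
        self.ct = self.ct.astype(float)
        self.detected = self.detected.astype(bool)
        if self.meta is not None and not self.meta.index.equals(self.ct.index):
            raise ValueError("metadata index does not match cells")

    @property
    def cells(self) -> pd.Index:
        return self.ct.index

    @property
    def genes(self) -> pd.Index:
        return self.ct.columns
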