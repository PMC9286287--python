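"""Expression-table I/O, low-count filtering, and the 2^-ΔΔCt utility.

Tabular convention: TSV, first column ``gene_id``, remaining columns
named ``<GROUP>_ZT<hh>`` (e.g. ``F_KO_ZT06``), where the portion before
the final ``_ZT`` is the group label and the trailing number the
Zeitgeber hour in [0, 24).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionTable",
    "parse_sample_name",
    "read_expression",
    "write_expression",
    "low_count_filter",
    "ddct_fold_change",
]

_SAMPLE_RE = re.compile(r"^(?P<group>.+)_ZT(?P<zt>\d{1,2}(?:\.\d+)?)$")


def parse_sample_name(name: str) -> tuple[str, float]:
    """Split ``<GROUP>_ZT<hh>`` into (group, ZT hour); rejects ZT ≥ 24."""
    m = _SAMPLE_RE.match(name)
    if not m:
        raise ValueError(f"sample column {name!r} does not match the GROUP_ZT## convention")
    zt = float(m.group("zt"))
    if not (0 <= zt < 24):
        raise ValueError(f"sample column {name!r}: ZT hour {zt} outside [0, 24)")
    return m.group("group"), zt


@dataclass(frozen=True)
class ExpressionTable:
    """Gene × sample abundance matrix with parsed per-sample metadata.

    ``kind`` distinguishes raw counts (filterable) from FPKM-like
    abundances (rhythm analysis input).
    """

    matrix: pd.DataFrame  # index gene_id, columns sample names
    samples: pd.DataFrame  # index sample name; columns group, zt_h
    kind: str = "abundance"

    def __post_init__(self):
        if self.kind not in ("counts", "abundance"):
            raise ValueError("kind must be 'counts' or 'abundance'")
        if self.matrix.index.duplicated().any():
            dup = self.matrix.index[self.matrix.index.duplicated()][0]
            raise ValueError(f"duplicate gene_id {dup!r}")
        if list(self.matrix.columns) != list(self.samples.index):
            raise ValueError("sample metadata must match matrix columns")
        if not np.all(np.isfinite(self.matrix.to_numpy())):
            raise ValueError("non-numeric or non-finite expression values")

    @classmethod
    def from_matrix(cls, matrix: pd.DataFrame, kind: str = "abundance") -> "ExpressionTable":
        meta = []
        for col in matrix.columns:
            group, zt = parse_sample_name(str(col))
            meta.append({"sample": str(col), "group": group, "zt_h": zt})
        samples = pd.DataFrame(meta).set_index("sample")
        return cls(matrix=matrix, samples=samples, kind=kind)

    @property
    def groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for g in self.samples["group"]:
            seen.setdefault(g, None)
        return tuple(seen)

    def group_block(self, group: str) -> tuple[np.ndarray, pd.DataFrame]:
        """(sorted ZT hours, genes × timepoints values) for one group."""
        cols = self.samples.index[self.samples["group"] == group]
        if len(cols) == 0:
            raise KeyError(f"no samples for group {group!r}")
        zts = self.samples.loc[cols, "zt_h"].to_numpy()
        order = np.argsort(zts)
        return zts[order], self.matrix[cols[order]]


def read_expression(path: str | Path, kind: str = "abundance") -> ExpressionTable:
    """Read a GROUP_ZT## TSV into a typed table; malformed headers are named."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "gene_id":
        raise ValueError(f"first column must be 'gene_id', found {df.index.name!r}")
    bad = df.columns[~df.dtypes.map(lambda d: np.issubdtype(d, np.number))]
    if len(bad):
        raise ValueError(f"non-numeric cells in column {bad[0]!r}")
    return ExpressionTable.from_matrix(df, kind=kind)


def write_expression(table: ExpressionTable, path: str | Path) -> Path:
    path = Path(path)
    table.matrix.to_csv(path, sep="\t", float_format="%.10g")
    return path


def low_count_filter(
    counts: ExpressionTable, min_total: float = 100.0, per_group: bool = False
) -> tuple[ExpressionTable, int]:
    """Remove low-expression genes from a raw-count table.

    Default reading: a gene is dropped when the sum of its raw counts
    across the timepoints of all groups combined is strictly less than
    ``min_total`` (a row summing to exactly ``min_total`` is retained).
    ``per_group=True`` instead requires the per-group sums to all fall
    below the threshold before dropping.
    """
    if counts.kind != "counts":
        raise ValueError("low-count filter applies to raw counts, not abundances")
    if per_group:
        groups = counts.groups
        sums = pd.DataFrame(
            {g: counts.matrix[counts.samples.index[counts.samples["group"] == g]].sum(axis=1)
             for g in groups}
        )
        keep = (sums >= min_total).any(axis=1)
    else:
        keep = counts.matrix.sum(axis=1) >= min_total
    filtered = ExpressionTable(
        matrix=counts.matrix.loc[keep], samples=counts.samples, kind="counts"
    )
    return filtered, int((~keep).sum())


def ddct_fold_change(
    ct_target: float,
    ct_reference: float,
    ct_target_calibrator: float,
    ct_reference_calibrator: float,
) -> float:
    """Relative qPCR quantification: 2^−ΔΔCt against a reference gene and calibrator."""
    for v in (ct_target, ct_reference, ct_target_calibrator, ct_reference_calibrator):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target - ct_reference) - (ct_target_calibrator - ct_reference_calibrator)
    return float(2.0 ** (-ddct))
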