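"""Reading, writing and filtering of amplicon count tables.

The universal input object is the :class:`CountTable`: a samples x ASVs matrix
of non-negative integer read counts.  All downstream stages (correlation
inference, cohort metrics, ecology) consume this object or matrices derived
from it.  The module also implements the feature filter applied before network
inference -- keep every ASV present in at least a given fraction of samples,
topping up with the most abundant ASVs so that a minimum number survive -- and
the two standard abundance transforms (relative abundance, centred log-ratio).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "SampleMetadata",
    "FilterReport",
    "read_count_table",
    "read_biom_json",
    "filter_features",
    "relative_abundance",
    "clr_transform",
]


class CountTable:
    """Non-negative integer sample x ASV count matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Samples as rows, ASVs as columns, integer-valued entries.

    Raises
    ------
    ValueError
        On duplicate sample/ASV identifiers, negative or non-integer counts,
        or fewer than 2 samples / 2 ASVs.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.duplicated().any():
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if data.columns.duplicated().any():
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate ASV ids: {dups}")
        if data.shape[0] < 2 or data.shape[1] < 2:
            raise ValueError(
                f"count table needs >= 2 samples and >= 2 ASVs, got {data.shape}"
            )
        arr = data.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = _first_non_numeric(data)
            raise ValueError(f"non-numeric count at sample={bad[0]!r}, asv={bad[1]!r}")
        if np.any(arr < 0):
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at sample={data.index[i]!r}, asv={data.columns[j]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise ValueError(
                f"non-integer count at sample={data.index[i]!r}, asv={data.columns[j]!r}"
            )
        self._data = data.astype(np.int64)

    # -- accessors ---------------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self._data.index)

    @property
    def asv_ids(self) -> list:
        return list(self._data.columns)

    @property
    def counts(self) -> np.ndarray:
        """Counts as an int64 array (samples x ASVs); a view, do not mutate."""
        return self._data.to_numpy()

    @property
    def shape(self) -> tuple:
        return self._data.shape

    @property
    def n_samples(self) -> int:
        return self._data.shape[0]

    @property
    def n_asvs(self) -> int:
        return self._data.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return self._data.copy()

    def select_asvs(self, asv_ids) -> "CountTable":
        return CountTable(self._data.loc[:, list(asv_ids)])

    def select_samples(self, sample_ids) -> "CountTable":
        return CountTable(self._data.loc[list(sample_ids), :])

    def __eq__(self, other) -> bool:
        return isinstance(other, CountTable) and self._data.equals(other._data)

    def __repr__(self) -> str:
        return f"CountTable({self.n_samples} samples x {self.n_asvs} ASVs)"

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_arrays(cls, counts, sample_ids, asv_ids) -> "CountTable":
        return cls(pd.DataFrame(np.asarray(counts), index=list(sample_ids),
                                columns=list(asv_ids)))

    def write_tsv(self, path) -> None:
        self._data.to_csv(path, sep="\t", index_label="sample_id")


def _first_non_numeric(data: pd.DataFrame):
    for j, col in enumerate(data.columns):
        coerced = pd.to_numeric(data[col], errors="coerce")
        bad = coerced.isna() & data[col].notna()
        if bad.any():
            return data.index[np.argmax(bad.to_numpy())], col
    return data.index[0], data.columns[0]


def read_count_table(path, orientation: str = "samples_as_rows") -> CountTable:
    """Read a TSV count table with an ID header row and ID first column.

    ``orientation`` is either ``"samples_as_rows"`` (canonical) or
    ``"features_as_rows"`` (the table is transposed on read).
    """
    if orientation not in ("samples_as_rows", "features_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "features_as_rows":
        df = df.T
    return CountTable(df)


def read_biom_json(path) -> CountTable:
    """Read a BIOM v1 (JSON) OTU/ASV table into a canonical CountTable.

    Supports both sparse and dense matrix_type.  BIOM stores features as rows
    (observations) and samples as columns; the result is transposed to the
    canonical samples x ASVs orientation.
    """
    with open(path) as fh:
        doc = json.load(fh)
    obs_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    mat = np.zeros((len(obs_ids), len(sample_ids)))
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        mat[:, :] = np.asarray(doc["data"])
    return CountTable(pd.DataFrame(mat.T, index=sample_ids, columns=obs_ids))


class SampleMetadata:
    """Per-sample environmental/contextual variables, keyed by sample id."""

    def __init__(self, data: pd.DataFrame):
        if data.index.duplicated().any():
            raise ValueError("duplicate sample ids in metadata")
        self._data = data

    @property
    def sample_ids(self) -> list:
        return list(self._data.index)

    @property
    def variables(self) -> list:
        return list(self._data.columns)

    def numeric(self, names=None) -> pd.DataFrame:
        """Numeric variable columns (coerced; non-parsable entries become NaN)."""
        cols = names if names is not None else self.variables
        return self._data[list(cols)].apply(pd.to_numeric, errors="coerce")

    def to_dataframe(self) -> pd.DataFrame:
        return self._data.copy()

    def __getitem__(self, name) -> pd.Series:
        return self._data[name]

    def aligned_to(self, sample_ids, strict: bool = True) -> "SampleMetadata":
        missing = set(sample_ids) - set(self._data.index)
        if missing:
            if strict:
                raise KeyError(f"metadata missing samples: {sorted(missing)[:5]}...")
            return SampleMetadata(self._data.reindex(list(sample_ids)))
        return SampleMetadata(self._data.loc[list(sample_ids)])

    @classmethod
    def read_tsv(cls, path) -> "SampleMetadata":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df)

    def write_tsv(self, path) -> None:
        self._data.to_csv(path, sep="\t", index_label="sample_id")


@dataclass
class FilterReport:
    """Retention bookkeeping for :func:`filter_features`."""

    n_asvs_before: int
    n_asvs_after: int
    reads_retained_fraction: float
    rule: dict = field(default_factory=dict)  # asv -> "prevalence" | "abundance_top_up"
    mode: str = "fallback"

    def to_json(self, path=None) -> str:
        payload = {
            "n_asvs_before": self.n_asvs_before,
            "n_asvs_after": self.n_asvs_after,
            "reads_retained_fraction": self.reads_retained_fraction,
            "mode": self.mode,
            "rule": self.rule,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def filter_features(
    table: CountTable,
    prevalence_min: float = 0.10,
    min_keep: int = 5000,
    mode: str = "fallback",
) -> tuple:
    """Prevalence filter with an abundance top-up.

    Keeps every ASV present (count > 0) in at least ``prevalence_min`` of
    samples.  In the default ``fallback`` mode, if fewer than ``min_keep``
    survive while the table holds at least that many ASVs, the most abundant
    remaining ASVs (by mean count over all samples) are added until
    ``min_keep`` are kept.  ``union`` mode instead always keeps the union of
    the prevalence-passing set and the ``min_keep`` most abundant ASVs.

    Returns ``(filtered_table, FilterReport)``.
    """
    if not 0 <= prevalence_min <= 1:
        raise ValueError("prevalence_min must be in [0, 1]")
    if min_keep < 0:
        raise ValueError("min_keep must be >= 0")
    if mode not in ("fallback", "union"):
        raise ValueError(f"unknown filter mode {mode!r}")

    counts = table.counts
    total_reads = counts.sum()
    if total_reads == 0:
        raise ValueError("cannot filter an all-zero count table")

    prevalence = (counts > 0).mean(axis=0)
    mean_abund = counts.mean(axis=0)
    asv_ids = np.asarray(table.asv_ids, dtype=object)

    by_prev = prevalence >= prevalence_min
    rule = {a: "prevalence" for a in asv_ids[by_prev]}

    keep = by_prev.copy()
    if mode == "union" or keep.sum() < min(min_keep, table.n_asvs):
        # rank all ASVs by mean abundance (descending, ties by original order)
        order = np.argsort(-mean_abund, kind="stable")
        if mode == "union":
            top = order[:min_keep]
            for j in top:
                if not keep[j]:
                    rule[asv_ids[j]] = "abundance_top_up"
                keep[j] = True
        else:
            need = min(min_keep, table.n_asvs) - int(keep.sum())
            for j in order:
                if need <= 0:
                    break
                if not keep[j]:
                    keep[j] = True
                    rule[asv_ids[j]] = "abundance_top_up"
                    need -= 1

    kept_ids = asv_ids[keep].tolist()
    if len(kept_ids) == 0:
        raise ValueError("feature filter removed every ASV")
    filtered = table.select_asvs(kept_ids)
    report = FilterReport(
        n_asvs_before=table.n_asvs,
        n_asvs_after=len(kept_ids),
        reads_retained_fraction=float(filtered.counts.sum() / total_reads),
        rule=rule,
        mode=mode,
    )
    return filtered, report


def relative_abundance(table: CountTable) -> pd.DataFrame:
    """Per-sample proportions; rows sum to 1. Errors on zero-depth samples."""
    counts = table.counts.astype(float)
    sums = counts.sum(axis=1)
    if np.any(sums == 0):
        bad = np.asarray(table.sample_ids, dtype=object)[sums == 0]
        raise ValueError(f"zero-sum sample(s): {bad.tolist()}")
    return pd.DataFrame(counts / sums[:, None], index=table.sample_ids,
                        columns=table.asv_ids)


def clr_transform(table: CountTable, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centred log-ratio transform of counts with a pseudocount.

    clr(x)_i = ln(x_i + pc) - mean_j ln(x_j + pc), per sample; rows sum to 0.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    logx = np.log(table.counts + pseudocount)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=table.sample_ids, columns=table.asv_ids)
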