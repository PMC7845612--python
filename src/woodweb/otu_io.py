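"""Reading, writing, filtering and partitioning of OTU count tables.

The pipeline's format boundary. Count tables are samples x OTUs with
per-sample metadata (``resource`` = tree species, ``compartment`` in
{sapwood, heartwood}, ``replicate`` = plot identifier). Supported on-disk
dialects are plain TSV (first column sample id, header row OTU ids, a
sidecar metadata TSV keyed by sample id) and BIOM JSON (v1, dense or
sparse).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

META_KEYS = ("resource", "compartment", "replicate")
COMPARTMENTS = ("sapwood", "heartwood")

TRAIT_COLUMNS = (
    "pH",
    "water_content",
    "C_content",
    "klason_lignin",
    "acid_soluble_lignin",
)


@dataclass
class OtuTable:
    """An integer samples x OTUs count matrix with sample metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, index = sample ids,
        columns = OTU ids.
    sample_meta
        DataFrame indexed like ``counts`` with columns ``resource``,
        ``compartment`` and ``replicate``.
    taxonomy
        Optional per-OTU lineage strings (Series indexed by OTU id).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    taxonomy: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        c = self.counts
        if c.shape[0] == 0 or c.shape[1] == 0:
            raise ValidationError("empty OTU table (no samples or no OTUs)")
        if c.index.has_duplicates:
            dup = c.index[c.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dup}")
        if c.columns.has_duplicates:
            dup = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate OTU ids: {dup}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(arr < 0):
            raise ValidationError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("counts must be integers")
        missing = set(c.index) - set(self.sample_meta.index)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)}")
        for key in META_KEYS:
            if key not in self.sample_meta.columns:
                raise ValidationError(f"sample metadata lacks required key {key!r}")
            if self.sample_meta.loc[c.index, key].isna().any():
                raise ValidationError(f"missing {key!r} for some samples")
        # keep metadata aligned and restricted to the table's samples
        self.sample_meta = self.sample_meta.loc[c.index]
        self.counts = c.astype(np.int64)

    # -- convenience -------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def otu_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def copy(self) -> "OtuTable":
        return OtuTable(
            self.counts.copy(),
            self.sample_meta.copy(),
            None if self.taxonomy is None else self.taxonomy.copy(),
        )

    def with_counts(self, counts: pd.DataFrame) -> "OtuTable":
        """New table sharing this table's metadata, different counts."""
        tax = None
        if self.taxonomy is not None:
            tax = self.taxonomy.reindex(counts.columns)
        return OtuTable(counts, self.sample_meta.loc[counts.index].copy(), tax)


def read_otu_table(
    path,
    format: str = "tsv",
    meta_path=None,
    taxonomy_path=None,
) -> OtuTable:
    """Read a count table (TSV or BIOM-JSON) plus sidecar metadata.

    TSV dialect: tab-separated, UTF-8, first column sample id, header row
    OTU ids. BIOM-JSON may carry sample metadata inline; a ``meta_path``
    overrides it.
    """
    if format == "tsv":
        counts = _read_counts_tsv(path)
        meta = None
    elif format in ("biom", "biom-json"):
        counts, meta = _read_biom_json(path)
    else:
        raise FormatError(f"unknown format {format!r} (use 'tsv' or 'biom-json')")

    if meta_path is not None:
        meta = read_sample_metadata(meta_path)
    if meta is None:
        raise ValidationError(
            "no sample metadata: provide meta_path or embed it in the BIOM file"
        )
    taxonomy = None
    if taxonomy_path is not None:
        tdf = pd.read_csv(taxonomy_path, sep="\t", index_col=0, dtype=str)
        taxonomy = tdf.iloc[:, 0]
    return OtuTable(counts, meta, taxonomy)


def _read_counts_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pandas raises a zoo of parse errors
        raise FormatError(f"cannot parse count TSV {path}: {exc}") from exc
    if df.shape[0] == 0:
        raise ValidationError(f"empty table body in {path}")
    df.index.name = None
    df.columns.name = None
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            line = df.index.get_loc(bad.index[0]) + 2  # header + 1-based
            raise FormatError(
                f"non-numeric count in {path}, line {line}, field {col!r}"
            )
    return df


def read_sample_metadata(path) -> pd.DataFrame:
    try:
        meta = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:
        raise FormatError(f"cannot parse metadata TSV {path}: {exc}") from exc
    meta.index.name = None
    return meta


def _read_biom_json(path):
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"invalid BIOM JSON in {path}: {exc}") from exc
    try:
        otu_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        n_otus, n_samples = doc["shape"]
        mtype = doc.get("matrix_type", "dense")
        mat = np.zeros((n_otus, n_samples))
        if mtype == "dense":
            mat[:] = np.asarray(doc["data"], dtype=float)
        elif mtype == "sparse":
            for i, j, v in doc["data"]:
                mat[int(i), int(j)] = v
        else:
            raise FormatError(f"unsupported BIOM matrix_type {mtype!r}")
    except (KeyError, TypeError, IndexError) as exc:
        raise FormatError(f"malformed BIOM document {path}: {exc}") from exc
    # BIOM rows are observations (OTUs); the pipeline wants samples x OTUs
    counts = pd.DataFrame(mat.T, index=sample_ids, columns=otu_ids)
    meta = None
    if all(c.get("metadata") for c in doc["columns"]):
        meta = pd.DataFrame(
            [c["metadata"] for c in doc["columns"]], index=sample_ids
        )
    return counts, meta


def write_otu_table(table: OtuTable, path, meta_path=None) -> None:
    """Write counts (and optionally metadata) in the TSV dialect."""
    table.counts.to_csv(path, sep="\t", index_label="sample_id")
    if meta_path is not None:
        table.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")


def read_trait_table(path) -> pd.DataFrame:
    """Per-resource wood trait table (TSV keyed by resource name)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValidationError(f"non-finite trait values in {path}")
    if df.index.has_duplicates:
        raise ValidationError("duplicate resource names in trait table")
    return df


def filter_rare_otus(table: OtuTable, max_total: int) -> OtuTable:
    """Drop every OTU whose total count across all samples is <= max_total.

    ``max_total=3`` removes singletons, doubletons and tripletons; the
    sample set and all retained counts are unchanged.
    """
    if max_total < 0:
        raise ValidationError("max_total must be >= 0")
    totals = table.otu_totals()
    keep = totals.index[totals > max_total]
    dropped = table.n_otus - len(keep)
    if dropped:
        log.info("filter_rare_otus: dropped %d OTUs with total <= %d", dropped, max_total)
    return table.with_counts(table.counts[keep])


def split_table(table: OtuTable, key: str) -> dict[str, OtuTable]:
    """Partition samples by a metadata key into disjoint sub-tables.

    Per split, OTUs with an all-zero column are silently dropped (they
    cannot enter any network); the drop count is logged.
    """
    if key not in table.sample_meta.columns:
        raise ValidationError(f"unknown metadata key {key!r}")
    out: dict[str, OtuTable] = {}
    for value, meta_part in table.sample_meta.groupby(key, sort=True):
        counts = table.counts.loc[meta_part.index]
        nonzero = counts.columns[counts.sum(axis=0) > 0]
        n_dropped = counts.shape[1] - len(nonzero)
        if n_dropped:
            log.info("split_table[%s=%s]: dropped %d all-zero OTUs", key, value, n_dropped)
        out[value] = table.with_counts(counts[nonzero])
    return out
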