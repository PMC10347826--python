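"""Readers and writers for every external artifact the pipeline touches.

All downstream modules operate on the in-memory domain types defined here
(:class:`OtuTable`, :class:`EnvTable`, :class:`PhyloTree`); files are only
parsed/serialized in this module.  Supported formats: OTU tables as TSV
(OTU rows, sample columns — orientation auto-detected) or BIOM 1.0 JSON;
trees as Newick; sample metadata, environmental and trait tables as TSV;
results as TSV or JSON.
"""

from __future__ import annotations

import io
import json
import math
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import skbio

from .errors import (
    DuplicateIdError,
    EmptyInputError,
    FormatError,
    MissingMetadataError,
    NegativeCountError,
)

FRACTIONS = ("micro", "nano", "pico")

ENV_VARIABLES = ("temperature", "salinity", "NOX", "PO4", "NH4", "SiOH4")

NA_STRINGS = ("", "NA")


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dupes = set(), []
        for x in ids:
            if x in seen:
                dupes.append(x)
            seen.add(x)
        raise DuplicateIdError(f"duplicate {what} id(s): {sorted(set(dupes))!r}")


@dataclass
class OtuTable:
    """Integer read counts, samples x OTUs, with per-sample size-fraction labels.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers (row labels of ``counts``).
    otu_ids : list of str
        Unique OTU identifiers (column labels of ``counts``).
    counts : ndarray of int64, shape (n_samples, n_otus)
        Non-negative read counts.
    fraction : list of str
        Per-sample size-fraction label, one of ``FRACTIONS``.
    taxonomy : dict, optional
        OTU id -> semicolon-separated ranked lineage string
        (``Supergroup;Division;...``); "unclassified" allowed at any rank.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray
    fraction: list[str]
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = list(map(str, self.sample_ids))
        self.otu_ids = list(map(str, self.otu_ids))
        self.fraction = list(map(str, self.fraction))
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise FormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            as_int = np.asarray(counts, dtype=np.int64)
            if not np.allclose(as_int, counts, rtol=0, atol=0):
                raise NegativeCountError("counts must be integral read counts")
            counts = as_int
        counts = counts.astype(np.int64, copy=True)
        if counts.size and counts.min() < 0:
            raise NegativeCountError("counts must be non-negative")
        self.counts = counts
        if len(self.fraction) != len(self.sample_ids):
            raise MissingMetadataError("every sample needs exactly one fraction label")
        bad = sorted(set(self.fraction) - set(FRACTIONS))
        if bad:
            raise FormatError(f"unknown size-fraction label(s): {bad!r}")
        if self.taxonomy is not None:
            self.taxonomy = {str(k): str(v) for k, v in self.taxonomy.items()}

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def total_reads(self) -> np.ndarray:
        """Total reads per OTU, summed over all samples."""
        return self.counts.sum(axis=0)

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def occurrence(self) -> np.ndarray:
        """Number of samples each OTU occurs in (count > 0)."""
        return (self.counts > 0).sum(axis=0)

    def relative_abundance(self) -> np.ndarray:
        """Per-sample relative abundances; all-zero samples stay all-zero."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(sums > 0, self.counts / np.where(sums > 0, sums, 1), 0.0)
        return rel

    # -- subsetting ------------------------------------------------------

    def subset_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            otu_ids=list(self.otu_ids),
            counts=self.counts[idx, :],
            fraction=[self.fraction[i] for i in idx],
            taxonomy=dict(self.taxonomy) if self.taxonomy else None,
        )

    def subset_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        pos = {o: j for j, o in enumerate(self.otu_ids)}
        idx = [pos[o] for o in otu_ids]
        tax = None
        if self.taxonomy is not None:
            tax = {o: self.taxonomy[o] for o in otu_ids if o in self.taxonomy}
        return OtuTable(
            sample_ids=list(self.sample_ids),
            otu_ids=[self.otu_ids[j] for j in idx],
            counts=self.counts[:, idx],
            fraction=list(self.fraction),
            taxonomy=tax,
        )

    def samples_of_fraction(self, fraction: str) -> "OtuTable":
        keep = [s for s, f in zip(self.sample_ids, self.fraction) if f == fraction]
        return self.subset_samples(keep)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
            and self.fraction == other.fraction
            and (self.taxonomy or {}) == (other.taxonomy or {})
        )


@dataclass
class EnvTable:
    """Per-sample environmental measurements; missing values allowed (NaN)."""

    sample_ids: list[str]
    values: pd.DataFrame  # index = sample_ids, numeric columns

    def __post_init__(self) -> None:
        self.sample_ids = list(map(str, self.sample_ids))
        _check_unique(self.sample_ids, "sample")
        df = pd.DataFrame(self.values)
        df.index = pd.Index(self.sample_ids)
        self.values = df.astype(float)

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, sample_ids: Sequence[str]) -> "EnvTable":
        missing = [s for s in sample_ids if s not in set(self.sample_ids)]
        if missing:
            raise MissingMetadataError(f"samples absent from env table: {missing!r}")
        return EnvTable(list(sample_ids), self.values.loc[list(sample_ids)])


@dataclass
class PhyloTree:
    """Rooted tree with branch lengths whose tips are OTU ids (skbio-backed)."""

    tree: skbio.TreeNode

    def __post_init__(self) -> None:
        tips = [t.name for t in self.tree.tips()]
        if any(t is None for t in tips):
            raise FormatError("all tips must be labeled")
        _check_unique(tips, "tip")
        for node in self.tree.traverse(include_self=False):
            bl = node.length
            if bl is None:
                node.length = 0.0
            elif not math.isfinite(bl):
                raise ValueError(f"non-finite branch length on node {node.name!r}")
            elif bl < 0:
                raise ValueError(f"negative branch length {bl} on node {node.name!r}")

    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.tips())

    def sheared(self, tip_names: Sequence[str]) -> "PhyloTree":
        return PhyloTree(self.tree.shear(list(tip_names)))

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_sample_metadata(path: str | os.PathLike) -> pd.DataFrame:
    """Read a sample metadata TSV (first column sample id, `fraction` column)."""
    md = pd.read_csv(path, sep="\t", dtype=str, index_col=0,
                     na_values=list(NA_STRINGS), keep_default_na=False)
    md.index = md.index.astype(str)
    if md.index.has_duplicates:
        raise DuplicateIdError("duplicate sample ids in metadata")
    if "fraction" not in md.columns:
        raise FormatError("metadata must contain a 'fraction' column")
    return md


def _counts_frame_from_tsv(path: str | os.PathLike) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message wrapped
        raise FormatError(f"cannot parse OTU table {path}: {exc}") from exc
    if df.empty and df.shape[1] == 0:
        raise EmptyInputError(f"OTU table {path} has no data columns")
    return df


def _coerce_counts(df: pd.DataFrame) -> np.ndarray:
    values = df.to_numpy()
    try:
        numeric = values.astype(np.float64)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric count cell in OTU table: {exc}") from exc
    if not np.isfinite(numeric).all():
        raise FormatError("non-finite count cell in OTU table")
    ints = np.rint(numeric)
    if not np.array_equal(ints, numeric):
        raise NegativeCountError("counts must be integers (reads)")
    if ints.size and ints.min() < 0:
        raise NegativeCountError("counts must be non-negative")
    return ints.astype(np.int64)


def read_otu_table(
    path: str | os.PathLike,
    format: str = "tsv",
    sample_metadata_path: str | os.PathLike | None = None,
    sample_metadata: pd.DataFrame | None = None,
    taxonomy_path: str | os.PathLike | None = None,
) -> OtuTable:
    """Read an OTU count table plus sample metadata into a validated OtuTable.

    TSV orientation (OTU rows vs sample rows) is auto-detected by matching
    header tokens against the metadata sample ids; ambiguity is an error.
    """
    if sample_metadata is None:
        if sample_metadata_path is None:
            raise MissingMetadataError("sample metadata (fraction labels) is required")
        sample_metadata = read_sample_metadata(sample_metadata_path)
    md = sample_metadata
    md_samples = set(md.index.astype(str))

    if format == "tsv":
        df = _counts_frame_from_tsv(path)
        cols = set(map(str, df.columns))
        rows = set(map(str, df.index))
        cols_match = len(cols & md_samples) > 0
        rows_match = len(rows & md_samples) > 0
        if cols_match and rows_match:
            raise FormatError("ambiguous orientation: both axes match metadata sample ids")
        if not cols_match and not rows_match:
            raise MissingMetadataError("no axis of the OTU table matches metadata sample ids")
        if rows_match:  # samples are rows already
            sample_axis, otu_axis = df.index, df.columns
            counts = _coerce_counts(df)
        else:  # canonical on-disk layout: OTU rows, sample columns
            sample_axis, otu_axis = df.columns, df.index
            counts = _coerce_counts(df).T
        sample_ids = [str(s) for s in sample_axis]
        otu_ids = [str(o) for o in otu_axis]
    elif format == "biom":
        sample_ids, otu_ids, counts, biom_tax = _read_biom_json(path)
    else:
        raise FormatError(f"unknown OTU table format {format!r}")

    _check_unique(sample_ids, "sample")
    _check_unique(otu_ids, "OTU")
    missing = sorted(set(sample_ids) - md_samples)
    if missing:
        raise MissingMetadataError(f"samples without metadata: {missing!r}")
    fraction = [str(md.loc[s, "fraction"]) for s in sample_ids]

    taxonomy: dict[str, str] | None = None
    if format == "biom" and biom_tax:
        taxonomy = biom_tax
    if taxonomy_path is not None:
        taxonomy = read_taxonomy(taxonomy_path)
    if taxonomy is not None:
        taxonomy = {o: taxonomy[o] for o in otu_ids if o in taxonomy}

    return OtuTable(sample_ids, otu_ids, counts, fraction, taxonomy)


def _read_biom_json(path: str | os.PathLike):
    """Minimal BIOM 1.0 (JSON) reader: rows = OTUs, columns = samples."""
    with open(path) as fh:
        doc = json.load(fh)
    try:
        otu_ids = [str(r["id"]) for r in doc["rows"]]
        sample_ids = [str(c["id"]) for c in doc["columns"]]
        shape = tuple(doc["shape"])
        mtype = doc.get("matrix_type", "sparse")
        data = doc["data"]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"not a BIOM 1.0 JSON file: missing {exc}") from exc
    if shape != (len(otu_ids), len(sample_ids)):
        raise FormatError("BIOM shape does not match row/column lists")
    mat = np.zeros(shape, dtype=np.float64)
    if mtype == "dense":
        mat[:] = np.asarray(data, dtype=np.float64)
    else:
        for i, j, v in data:
            mat[int(i), int(j)] = v
    ints = np.rint(mat)
    if not np.array_equal(ints, mat) or (ints.size and ints.min() < 0):
        raise NegativeCountError("BIOM counts must be non-negative integers")
    taxonomy: dict[str, str] = {}
    for r in doc["rows"]:
        meta = r.get("metadata") or {}
        tax = meta.get("taxonomy")
        if tax:
            taxonomy[str(r["id"])] = ";".join(tax) if isinstance(tax, list) else str(tax)
    return sample_ids, otu_ids, ints.astype(np.int64).T, taxonomy


def read_taxonomy(path: str | os.PathLike) -> dict[str, str]:
    """Two-column TSV: OTU id, semicolon-separated ranked lineage."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=0)
    if df.shape[1] < 2:
        raise FormatError("taxonomy TSV needs >= 2 columns (otu_id, lineage)")
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        raise DuplicateIdError("duplicate OTU ids in taxonomy")
    return dict(zip(ids, df.iloc[:, 1].astype(str)))


def division_of(lineage: str | None) -> str:
    """Extract the Division rank (2nd field) from a PR2-style lineage.

    Missing/unresolved lineages map to the pseudo-group ``"unclassified"``
    so that unannotated OTUs can still be reported as a group.
    """
    if not lineage:
        return "unclassified"
    parts = [p.strip() for p in str(lineage).split(";")]
    if len(parts) < 2 or not parts[1] or parts[1].lower() == "unclassified":
        return "unclassified"
    return parts[1]


def read_tree(path: str | os.PathLike) -> PhyloTree:
    """Read a Newick tree; duplicate tips and negative branch lengths are errors."""
    tree = skbio.TreeNode.read(str(path), format="newick")
    return PhyloTree(tree)


def write_tree(tree: PhyloTree, path: str | os.PathLike) -> None:
    tree.tree.write(str(path), format="newick")


def read_env_table(path: str | os.PathLike) -> EnvTable:
    df = pd.read_csv(path, sep="\t", index_col=0,
                     na_values=list(NA_STRINGS), keep_default_na=False)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        raise DuplicateIdError("duplicate sample ids in env table")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric env value: {exc}") from exc
    return EnvTable(list(df.index), df)


def read_aux_tables(
    trait_path: str | os.PathLike,
    env_path: str | os.PathLike,
    modality_order_path: str | os.PathLike | None = None,
):
    """Read the trait table and environmental table -> (TraitTable, EnvTable)."""
    from .traits import read_trait_table  # local import: traits depends on io types

    traits = read_trait_table(trait_path, modality_order_path)
    env = read_env_table(env_path)
    return traits, env


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.10g"


def write_otu_table(
    table: OtuTable,
    path: str | os.PathLike,
    metadata_path: str | os.PathLike | None = None,
) -> None:
    """Write counts as TSV (OTU rows, sample columns) and optional metadata TSV."""
    df = pd.DataFrame(table.counts.T, index=table.otu_ids, columns=table.sample_ids)
    df.index.name = "otu_id"
    df.to_csv(path, sep="\t")
    if metadata_path is not None:
        md = pd.DataFrame({"fraction": table.fraction}, index=table.sample_ids)
        md.index.name = "sample_id"
        md.to_csv(metadata_path, sep="\t")


def _as_frame(result_object) -> pd.DataFrame:
    if isinstance(result_object, pd.DataFrame):
        return result_object
    if hasattr(result_object, "to_frame"):
        return result_object.to_frame()
    raise FormatError(
        f"cannot serialize object of type {type(result_object).__name__}"
    )


def write_results(result_object, path: str | os.PathLike, format: str = "tsv") -> None:
    """Serialize a pipeline result table deterministically (TSV or JSON).

    Floats are written at 10 significant digits; writing the same object
    twice produces byte-identical files.
    """
    df = _as_frame(result_object)
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT,
                  lineterminator="\n")
    elif format == "json":
        records = json.loads(df.to_json(orient="records", double_precision=10))
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        raise FormatError(f"unknown results format {format!r}")


def read_results(path: str | os.PathLike, format: str = "tsv") -> pd.DataFrame:
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        with open(path) as fh:
            return pd.DataFrame(json.load(fh))
    raise FormatError(f"unknown results format {format!r}")
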