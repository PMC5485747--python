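"""Data model and text I/O: expression studies, sample metadata, gene sets.

Expression matrices are pandas DataFrames with genes as rows and samples as
columns, assumed already on a log-like scale (as deposited array matrices
typically are); no log transform is applied anywhere in the package.
All on-disk formats are plain tab-separated UTF-8 text with ``.`` decimals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

EPITHELIAL = "epithelial"
MESENCHYMAL = "mesenchymal"
PHENOTYPES = (EPITHELIAL, MESENCHYMAL)

METADATA_COLUMNS = ["sample_id", "study_id", "phenotype", "replicate_of"]


class DataModelError(ValueError):
    """Raised when an input violates the data-model invariants."""


@dataclass
class ExpressionStudy:
    """One study's genes x samples expression matrix.

    Parameters
    ----------
    study_id : str
        Unique study identifier (e.g. a GEO series accession).
    platform_id : str
        Array platform tag; informational only.
    values : pandas.DataFrame
        Real-valued matrix, index = gene identifiers, columns = sample ids.
        Must be complete (no NaN) and free of duplicate gene ids.
    """

    study_id: str
    platform_id: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise DataModelError(
                f"study {self.study_id!r}: duplicate gene identifiers {dups[:5]}"
            )
        if self.values.isna().any().any():
            raise DataModelError(f"study {self.study_id!r}: missing values present")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SampleMetadata:
    """Per-sample phenotype, study membership and replicate structure."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.table.columns]
        if missing:
            raise DataModelError(f"metadata missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        bad = set(self.table["phenotype"]) - set(PHENOTYPES)
        if bad:
            raise DataModelError(f"unknown phenotype labels: {sorted(bad)}")
        if self.table["sample_id"].duplicated().any():
            dups = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise DataModelError(f"duplicate sample ids in metadata: {dups.tolist()[:5]}")
        known = set(self.table["sample_id"])
        refs = self.table["replicate_of"].dropna()
        refs = refs[refs != ""]
        unresolved = sorted(set(refs) - known)
        if unresolved:
            raise DataModelError(f"replicate_of references unknown samples: {unresolved[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def phenotype_vector(self, samples: Sequence[str]) -> pd.Series:
        """Phenotype labels aligned to ``samples`` (errors on unknown ids)."""
        lookup = self.table.set_index("sample_id")["phenotype"]
        missing = [s for s in samples if s not in lookup.index]
        if missing:
            raise DataModelError(f"samples without metadata: {missing[:5]}")
        return lookup.reindex(samples)

    def study_vector(self, samples: Sequence[str]) -> pd.Series:
        lookup = self.table.set_index("sample_id")["study_id"]
        missing = [s for s in samples if s not in lookup.index]
        if missing:
            raise DataModelError(f"samples without metadata: {missing[:5]}")
        return lookup.reindex(samples)


@dataclass
class IntegratedMatrix:
    """Merged matrix over the common gene set, column-aligned to metadata."""

    values: pd.DataFrame
    metadata: SampleMetadata
    per_study_gene_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        meta_ids = self.metadata.table.set_index("sample_id")
        missing = [s for s in self.values.columns if s not in meta_ids.index]
        if missing:
            raise DataModelError(f"integrated columns without metadata: {missing[:5]}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def phenotype(self) -> pd.Series:
        return self.metadata.phenotype_vector(self.samples)

    @property
    def study(self) -> pd.Series:
        return self.metadata.study_vector(self.samples)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), insertion-ordered."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [name for name, genes in self.sets.items() if not genes]
        if empty:
            raise DataModelError(f"empty gene sets: {empty[:5]}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def restrict(self, background: set[str]) -> "GeneSetCollection":
        """Intersect every set with ``background``, dropping emptied sets."""
        kept = {
            name: genes & background
            for name, genes in self.sets.items()
            if genes & background
        }
        return GeneSetCollection(
            sets=kept,
            descriptions={n: self.descriptions.get(n, "") for n in kept},
        )


def collapse_probes(
    probe_values: pd.DataFrame, probe_to_gene: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse a probes x samples matrix to genes x samples by median.

    Each probe maps to at most one gene; probes absent from the map are
    dropped.  When several probes map to one gene the per-sample median
    represents that gene (midpoint of the two central values for even
    counts).  Gene rows come out in lexicographic order.
    """
    mapped = probe_values.index.map(lambda p: probe_to_gene.get(p))
    keep = mapped.notna()
    if not keep.any():
        raise DataModelError("no probe maps to any gene; probe collapsing impossible")
    sub = probe_values.loc[keep].copy()
    sub.index = pd.Index(mapped[keep], name="gene_id")
    collapsed = sub.groupby(level=0).median()
    return collapsed.sort_index()


def intersect_and_merge(
    studies: Sequence[ExpressionStudy], metadata: SampleMetadata
) -> IntegratedMatrix:
    """Merge studies into one matrix over the exact common gene intersection.

    Columns are concatenated in the given study order; gene rows are sorted
    lexicographically so the merge is invariant to input row order.
    """
    if len(studies) < 2:
        raise DataModelError("need at least two studies to merge")
    counts = {s.study_id: len(s.genes) for s in studies}
    common: set[str] | None = None
    for s in studies:
        gset = set(s.genes)
        common = gset if common is None else common & gset
    assert common is not None
    if not common:
        raise DataModelError(
            "empty gene intersection across studies; per-study gene counts: "
            + ", ".join(f"{k}={v}" for k, v in counts.items())
        )
    seen: set[str] = set()
    for s in studies:
        overlap = seen & set(s.samples)
        if overlap:
            raise DataModelError(
                f"duplicate sample ids across studies: {sorted(overlap)[:5]}"
            )
        seen |= set(s.samples)
    genes = sorted(common)
    merged = pd.concat([s.values.loc[genes] for s in studies], axis=1)
    # validates that every column has a metadata row
    return IntegratedMatrix(values=merged, metadata=metadata, per_study_gene_counts=counts)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file: ``name<TAB>description<TAB>gene...`` per line.

    Duplicate genes within a set are deduplicated; a duplicate set name or a
    line with fewer than three fields is an error naming the line number.
    """
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataModelError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name, desc, *genes = fields
            if name in sets:
                raise DataModelError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            members = {g for g in genes if g}
            sets[name] = members
            descriptions[name] = desc
    if not sets:
        warnings.warn(f"GMT file {path} contains no gene sets", stacklevel=2)
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def write_expression_tsv(values: pd.DataFrame, path: str | Path) -> None:
    """Write a genes x samples matrix; first column ``gene_id``, full precision."""
    out = values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    # round_trip parsing: write/read must reproduce doubles bit-identically
    df = pd.read_csv(path, sep="\t", index_col="gene_id", float_precision="round_trip")
    if df.isna().any().any():
        raise DataModelError(f"{path}: missing values in expression matrix")
    return df


def write_metadata_tsv(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.table.to_csv(path, sep="\t", index=False, na_rep="")


def read_metadata_tsv(path: str | Path) -> SampleMetadata:
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    table["replicate_of"] = table["replicate_of"].replace("", np.nan)
    return SampleMetadata(table=table)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines ignored."""
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")
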