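"""Readers, validation and rarefaction for OTU tables and companion inputs.

The canonical in-memory containers are thin wrappers around pandas /
dendropy objects: an :class:`OTUTable` holds a samples x OTUs integer count
matrix; metadata, taxonomy, qPCR and hydrochemistry tables are plain
DataFrames with validated schemas; trees are ``dendropy.Tree`` objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COMPARTMENTS = ("soil", "seepage", "groundwater")
FRACTIONS = ("F01", "F02", "bulk")
ASSEMBLAGES = ("HTL", "HTU", "none")

METADATA_COLUMNS = ("sample_id", "compartment", "site", "time_point",
                    "fraction", "assemblage")
QPCR_COLUMNS = ("site", "time_point", "fraction", "gene_copies_per_L")
TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus")


class ValidationError(ValueError):
    """Input violates a structural invariant (duplicate ids, bad values)."""


class FormatError(ValueError):
    """Input file cannot be parsed under the requested dialect."""


@dataclass
class OTUTable:
    """Samples x OTUs matrix of non-negative integer read counts.

    Sample and OTU identifiers are opaque strings; any compartment or
    filter-fraction semantics live in the metadata table, not here.
    """

    counts: pd.DataFrame  # index = sample ids, columns = OTU ids

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> "OTUTable":
        df = self.counts
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate OTU ids: {dups}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("counts must be numeric")
        if np.any(arr < 0):
            raise FormatError("negative counts present")
        if not np.allclose(arr, np.round(arr)):
            raise FormatError("non-integer counts present")
        self.counts = df.astype(np.int64)
        self.counts.index.name = "sample"
        self.counts.columns.name = None
        return self

    # -- accessors -------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_samples(self, sample_ids) -> "OTUTable":
        return OTUTable(self.counts.loc[list(sample_ids)].copy())

    def drop_empty_otus(self) -> "OTUTable":
        keep = self.counts.sum(axis=0) > 0
        return OTUTable(self.counts.loc[:, keep].copy())

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="sample")


def read_otu_table(path, dialect: str = "auto") -> OTUTable:
    """Read a tab-separated OTU table.

    ``plain-tsv``: first column sample id, header row of OTU ids.
    ``mothur-shared``: leading ``label``, ``Group``, ``numOtus`` columns
    (the first and third are dropped, ``Group`` becomes the sample id).
    ``auto`` sniffs the mothur dialect from those three leading columns.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns.size < 2:
        raise FormatError(f"{path}: fewer than two columns")
    lead = [c.lower() for c in df.columns[:3]]
    is_shared = lead == ["label", "group", "numotus"]
    if dialect == "auto":
        dialect = "mothur-shared" if is_shared else "plain-tsv"
    if dialect == "mothur-shared":
        if not is_shared:
            raise FormatError(
                f"{path}: expected leading label/Group/numOtus columns")
        df = df.drop(columns=df.columns[[0, 2]])
        df = df.set_index(df.columns[0])
    elif dialect == "plain-tsv":
        df = df.set_index(df.columns[0])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df.index = df.index.astype(str)
    df.index.name = "sample"
    return OTUTable(df)


def read_metadata(path) -> pd.DataFrame:
    """Read per-sample metadata (CSV) and validate categorical fields."""
    df = pd.read_csv(path, dtype=str)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"metadata missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in metadata")
    bad = set(df["compartment"]) - set(COMPARTMENTS)
    if bad:
        raise ValidationError(f"unknown compartments: {sorted(bad)}")
    bad = set(df["fraction"]) - set(FRACTIONS)
    if bad:
        raise ValidationError(f"unknown fractions: {sorted(bad)}")
    soil_bad = df[(df["compartment"] == "soil") & (df["fraction"] != "bulk")]
    if len(soil_bad):
        raise ValidationError(
            f"soil samples must be bulk: {soil_bad['sample_id'].tolist()}")
    return df.set_index("sample_id", drop=False)


def read_taxonomy(path) -> pd.DataFrame:
    """Read an OTU taxonomy table (TSV: otu_id + ranked lineage columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "otu_id" not in df.columns:
        raise FormatError("taxonomy table needs an 'otu_id' column")
    if df["otu_id"].duplicated().any():
        raise ValidationError("duplicate otu_id in taxonomy")
    for rank in TAXONOMY_RANKS:
        if rank not in df.columns:
            df[rank] = "unclassified"
    return df.set_index("otu_id").fillna("unclassified")


def read_qpcr(path) -> pd.DataFrame:
    """Read a qPCR table (CSV: site, time_point, fraction, gene_copies_per_L)."""
    df = pd.read_csv(path, dtype={"site": str, "time_point": str,
                                  "fraction": str})
    missing = set(QPCR_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"qPCR table missing columns: {sorted(missing)}")
    if (df["gene_copies_per_L"] <= 0).any():
        raise ValidationError("qPCR gene copies must be positive")
    return df


def read_hydrochem(path) -> pd.DataFrame:
    """Read hydrochemistry (CSV: site, time_point, one column per parameter).

    Missing values stay as NaN; parameter columns must be unique (pandas
    enforces this on read by mangling, so we check explicitly).
    """
    df = pd.read_csv(path, dtype={"site": str, "time_point": str})
    for col in ("site", "time_point"):
        if col not in df.columns:
            raise FormatError(f"hydrochemistry table missing {col!r}")
    return df.set_index(["site", "time_point"])


def read_tree(path) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValidationError("tree has a missing branch length")
        if edge.length < 0:
            raise ValidationError("tree has a negative branch length")
    return tree


def validate_bundle(table: OTUTable, metadata: pd.DataFrame | None = None,
                    taxonomy: pd.DataFrame | None = None,
                    tree: dendropy.Tree | None = None) -> None:
    """Cross-reference checks among the inputs of one analysis."""
    if metadata is not None:
        missing = set(table.sample_ids) - set(metadata.index)
        if missing:
            raise ValidationError(
                f"samples absent from metadata: {sorted(missing)[:5]}")
    if taxonomy is not None:
        missing = set(table.otu_ids) - set(taxonomy.index)
        if missing:
            raise ValidationError(
                f"OTUs absent from taxonomy: {sorted(missing)[:5]}")
    if tree is not None:
        tips = {t.label for t in tree.taxon_namespace}
        missing = set(table.otu_ids) - tips
        if missing:
            raise ValidationError(
                f"OTUs absent from tree tips: {sorted(missing)[:5]}")


# ---------------------------------------------------------------------------
# rarefaction and relative abundance


def rarefy(table: OTUTable, depth: int, seed=None) -> OTUTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped (and logged).
    Subsampling draws each read at most once (multivariate hypergeometric),
    so rarefied counts never exceed the originals.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=1)
    keep = totals >= depth
    dropped = list(table.counts.index[~keep])
    if dropped:
        logger.info("rarefy: dropping %d samples below depth %d: %s",
                    len(dropped), depth, dropped)
    if not keep.any():
        raise ValueError(f"no sample reaches depth {depth}")
    sub = table.counts.loc[keep]
    out = np.empty(sub.shape, dtype=np.int64)
    for i, (_, row) in enumerate(sub.iterrows()):
        out[i] = rng.multivariate_hypergeometric(row.to_numpy(), depth)
    return OTUTable(pd.DataFrame(out, index=sub.index, columns=sub.columns))


def relative_abundance(table: OTUTable) -> pd.DataFrame:
    """Per-sample relative abundances; every row sums to 1."""
    totals = table.counts.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(
            f"zero-total samples: {list(zero.index)}")
    return table.counts.div(totals, axis=0)
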