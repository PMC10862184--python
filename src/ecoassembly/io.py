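"""Readers, writers and in-memory containers for the pipeline's formats.

On disk, community tables follow the common OTU-table dialect: tab-separated,
OTUs as rows, samples as columns, first header cell either ``#OTU ID`` or a
bare label. In memory, tables are samples x OTUs (the community-ecology
convention for distance computation). Trees are newick, parsed with
scikit-bio. All writers prepend ``"# key=value"`` provenance lines recording
package version, config hash and seed.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from ._util import check_unique, logger, provenance_lines, strip_provenance

__all__ = [
    "CommunityTable",
    "TaxonomyTable",
    "SampleMetadata",
    "DissimilarityMatrix",
    "FormatError",
    "read_community_table",
    "write_community_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_tree",
    "write_tree",
    "read_metadata",
    "write_metadata",
    "align_inputs",
]

TAXONOMIC_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
LAYERS = ("surface", "subsurface")
METADATA_REQUIRED = ("site", "layer", "latitude", "longitude", "elevation")


class FormatError(ValueError):
    """An input file violates the expected dialect."""


@dataclass
class CommunityTable:
    """Integer read-count matrix, samples x OTUs.

    Parameters
    ----------
    data : pandas.DataFrame
        Non-negative integer counts; index = sample ids, columns = OTU ids.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        check_unique(self.data.index, "sample")
        check_unique(self.data.columns, "OTU")
        vals = self.data.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.isfinite(vals)):
                raise FormatError("counts must be finite")
            if np.any(np.abs(vals - np.round(vals)) > 1e-6):
                raise FormatError("counts must be integers")
            self.data = self.data.round().astype(np.int64)
        if (self.data.to_numpy() < 0).any():
            raise FormatError("counts must be non-negative")

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_otus(self) -> int:
        return self.data.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalised fractions; all-zero samples stay all-zero (flagged)."""
        totals = self.data.sum(axis=1)
        zero = totals == 0
        if zero.any():
            logger.warning("relative_abundance: %d all-zero sample(s)", int(zero.sum()))
        safe = totals.replace(0, 1)
        return self.data.div(safe, axis=0)

    def select_samples(self, sample_ids: Sequence[str]) -> "CommunityTable":
        return CommunityTable(self.data.loc[list(sample_ids)].copy())

    def select_otus(self, otu_ids: Sequence[str]) -> "CommunityTable":
        return CommunityTable(self.data.loc[:, list(otu_ids)].copy())


@dataclass
class TaxonomyTable:
    """otu_id -> ranked lineage (kingdom..genus); missing ranks empty strings."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        check_unique(self.data.index, "OTU")
        for rank in self.data.columns:
            if rank not in TAXONOMIC_RANKS:
                raise FormatError(f"unknown taxonomic rank column: {rank!r}")
        self.data = self.data.fillna("")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    def lineage(self, otu_id: str) -> dict[str, str]:
        return self.data.loc[otu_id].to_dict()


@dataclass
class SampleMetadata:
    """Per-sample site, layer, coordinates, elevation and environment vector.

    The environment block holds every extra numeric column (pH, TP, TC, TK,
    TN, NO3, NH4, C:N, MC, AP, AMT, ...); missing values stay missing and are
    excluded pairwise downstream.
    """

    data: pd.DataFrame
    layer_aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        check_unique(self.data.index, "sample")
        for col in METADATA_REQUIRED:
            if col not in self.data.columns:
                raise FormatError(f"metadata missing required column: {col!r}")
        layers = self.data["layer"].map(lambda v: self.layer_aliases.get(v, v))
        bad = sorted(set(layers) - set(LAYERS))
        if bad:
            raise FormatError(
                f"layer value(s) {bad} not in {list(LAYERS)}; configure an alias map"
            )
        self.data = self.data.assign(layer=layers)
        lat = self.data["latitude"].astype(float)
        lon = self.data["longitude"].astype(float)
        if ((lat < -90) | (lat > 90)).any():
            raise FormatError("latitude outside [-90, 90]")
        if ((lon < -180) | (lon > 180)).any():
            raise FormatError("longitude outside [-180, 180]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def environment_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in METADATA_REQUIRED]

    def environment(self) -> pd.DataFrame:
        return self.data[self.environment_columns].astype(float)

    def select_samples(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.data.loc[list(sample_ids)].copy())


class DissimilarityMatrix:
    """Square symmetric pairwise matrix with axis labels and a metric name.

    NaN entries mark flagged (undefined) pairs, e.g. Bray-Curtis against an
    all-zero sample; the diagonal is always zero.
    """

    def __init__(self, values, ids: Sequence[str], metric: str = ""):
        values = np.asarray(values, dtype=float)
        ids = list(ids)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if values.shape[0] != len(ids):
            raise ValueError("ids do not match matrix dimension")
        check_unique(ids, "axis")
        with np.errstate(invalid="ignore"):
            asym = np.nanmax(np.abs(values - values.T)) if values.size else 0.0
        if values.size and asym > 1e-9:
            raise ValueError("matrix is not symmetric")
        np.fill_diagonal(values, 0.0)
        self.values = values
        self.ids = ids
        self.metric = metric

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def filter(self, ids: Sequence[str]) -> "DissimilarityMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DissimilarityMatrix(self.values[np.ix_(idx, idx)], list(ids), self.metric)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.ids.index(pair[0]), self.ids.index(pair[1])
        return float(self.values[i, j])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    with open(path) as fh:
        body = strip_provenance(fh)
    if not body:
        raise FormatError(f"{path}: empty file")
    return pd.read_csv(_stdio.StringIO("".join(body)), sep="\t", index_col=0, dtype=str)


def read_community_table(path) -> CommunityTable:
    """Read a TSV OTU table (OTUs x samples on disk) into samples x OTUs."""
    raw = _read_tsv(path)
    otu_ids = [str(i) for i in raw.index]
    check_unique(otu_ids, "OTU")
    check_unique(raw.columns, "sample")
    mat = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        for i, cell in enumerate(raw[col]):
            try:
                v = float(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-numeric count at OTU {otu_ids[i]!r}, sample {col!r}: {cell!r}"
                ) from None
            if not np.isfinite(v) or v < 0:
                raise FormatError(
                    f"negative or non-finite count at OTU {otu_ids[i]!r}, sample {col!r}"
                )
            mat[i, j] = v
    frame = pd.DataFrame(
        np.round(mat).astype(np.int64).T, index=list(raw.columns), columns=otu_ids
    )
    return CommunityTable(frame)


def write_community_table(table: CommunityTable, path, seed: int | None = None, **extra) -> None:
    with open(path, "w") as fh:
        for line in provenance_lines(seed=seed, **extra):
            fh.write(line + "\n")
        table.data.T.to_csv(fh, sep="\t", index_label="#OTU ID")


def read_taxonomy(path) -> TaxonomyTable:
    raw = _read_tsv(path)
    raw.columns = [c.lower() for c in raw.columns]
    keep = [c for c in raw.columns if c in TAXONOMIC_RANKS]
    return TaxonomyTable(raw[keep])


def write_taxonomy(taxonomy: TaxonomyTable, path, seed: int | None = None, **extra) -> None:
    with open(path, "w") as fh:
        for line in provenance_lines(seed=seed, **extra):
            fh.write(line + "\n")
        taxonomy.data.to_csv(fh, sep="\t", index_label="#OTU ID")


def read_tree(path) -> TreeNode:
    """Parse a rooted newick tree; missing branch lengths become 0."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise FormatError(f"{path}: unparseable newick ({exc})") from exc
    tips = [t.name for t in tree.tips()]
    if any(t is None for t in tips):
        raise FormatError(f"{path}: tree has unlabelled tips")
    check_unique(tips, "tree tip")
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
        if node.length < 0:
            raise FormatError("negative branch length")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_metadata(path, layer_aliases: dict[str, str] | None = None) -> SampleMetadata:
    raw = _read_tsv(path)
    for col in METADATA_REQUIRED:
        if col not in raw.columns:
            raise FormatError(f"metadata missing required column: {col!r}")
    out = raw.copy()
    for col in out.columns:
        if col == "layer" or col == "site":
            continue
        out[col] = pd.to_numeric(out[col], errors="coerce")
    return SampleMetadata(out, layer_aliases=layer_aliases or {})


def write_metadata(metadata: SampleMetadata, path, seed: int | None = None, **extra) -> None:
    with open(path, "w") as fh:
        for line in provenance_lines(seed=seed, **extra):
            fh.write(line + "\n")
        metadata.data.to_csv(fh, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

@dataclass
class WorkingSet:
    """Mutually consistent table / tree / metadata / taxonomy."""

    table: CommunityTable
    tree: TreeNode | None = None
    metadata: SampleMetadata | None = None
    taxonomy: TaxonomyTable | None = None
    dropped_otus: list[str] = field(default_factory=list)
    dropped_samples: list[str] = field(default_factory=list)


def align_inputs(
    table: CommunityTable,
    tree: TreeNode | None = None,
    metadata: SampleMetadata | None = None,
    taxonomy: TaxonomyTable | None = None,
) -> WorkingSet:
    """Restrict OTUs to the table/tree intersection and samples to those with
    metadata; every drop is logged. Taxonomy is optional and never drops OTUs
    (missing lineages read as Unclassified downstream)."""
    otus = list(table.otu_ids)
    if tree is not None:
        tips = {t.name for t in tree.tips()}
        keep = [o for o in otus if o in tips]
        if not keep:
            raise ValueError("empty OTU intersection between table and tree")
        dropped_otus = [o for o in otus if o not in tips]
        otus = keep
    else:
        dropped_otus = []

    samples = list(table.sample_ids)
    if metadata is not None:
        have = set(metadata.sample_ids)
        keep_s = [s for s in samples if s in have]
        if not keep_s:
            raise ValueError("no sample of the table has metadata")
        dropped_samples = [s for s in samples if s not in have]
        samples = keep_s
    else:
        dropped_samples = []

    if dropped_otus:
        logger.info(
            "align_inputs: dropped %d OTU(s) absent from tree: %s",
            len(dropped_otus), ", ".join(dropped_otus[:10]) + ("..." if len(dropped_otus) > 10 else ""),
        )
    if dropped_samples:
        logger.info(
            "align_inputs: dropped %d sample(s) without metadata: %s",
            len(dropped_samples), ", ".join(dropped_samples),
        )

    sub = table.select_samples(samples).select_otus(otus)
    out_tree = tree.shear(otus) if tree is not None else None
    out_meta = metadata.select_samples(samples) if metadata is not None else None
    return WorkingSet(
        table=sub,
        tree=out_tree,
        metadata=out_meta,
        taxonomy=taxonomy,
        dropped_otus=dropped_otus,
        dropped_samples=dropped_samples,
    )
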