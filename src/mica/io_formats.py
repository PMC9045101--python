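"""Standard file formats and validated in-memory containers.

Everything downstream consumes these types: an integer OTU count table
(samples x OTUs), a sample metadata table, a rooted phylogeny over OTU tip
labels, and a symmetric distance matrix. Files are plain text: TSV for
tables and matrices, newick for trees.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

__all__ = [
    "OTUTable",
    "MetadataTable",
    "DistanceMatrix",
    "ValidationError",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "read_newick",
    "write_newick",
    "relative_abundance",
    "rarefy",
    "validate_tree",
    "prune_to_intersection",
]


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


def _check_unique(ids, kind: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {kind} identifier: {i!r}")
        seen.add(i)


@dataclass
class OTUTable:
    """Integer count matrix, samples x OTUs.

    Invariants: unique sample and OTU ids, non-negative integer counts,
    at least one sample and one OTU, and every sample has at least one read.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if counts.size == 0:
            raise ValidationError("table must have at least 1 sample and 1 OTU")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            bad = np.argwhere(~np.isclose(counts, rounded, atol=1e-9))
            if bad.size:
                r, c = bad[0]
                raise ValidationError(
                    f"non-integer count at sample {self.sample_ids[r]!r}, "
                    f"OTU {self.otu_ids[c]!r}: {counts[r, c]!r}"
                )
            counts = rounded.astype(np.int64)
        neg = np.argwhere(counts < 0)
        if neg.size:
            r, c = neg[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[r]!r}, "
                f"OTU {self.otu_ids[c]!r}: {counts[r, c]}"
            )
        empty = np.flatnonzero(counts.sum(axis=1) == 0)
        if empty.size:
            raise ValidationError(
                f"sample {self.sample_ids[empty[0]]!r} has zero total counts"
            )
        self.counts = counts.astype(np.int64)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "OTUTable":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy())

    def select_samples(self, sample_ids) -> "OTUTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OTUTable(list(sample_ids), list(self.otu_ids), self.counts[idx])


@dataclass
class MetadataTable:
    """Per-sample metadata: group label, coordinates, climate, extras.

    Only columns an analysis touches are validated; everything else is
    passed through untouched.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.name is None:
            self.data.index.name = "sample_id"
        self.data.index = self.data.index.astype(str)
        _check_unique(list(self.data.index), "sample")
        if "latitude" in self.data.columns:
            lat = pd.to_numeric(self.data["latitude"])
            if ((lat < -90) | (lat > 90)).any():
                raise ValidationError("latitude outside [-90, 90]")
        if "longitude" in self.data.columns:
            lon = pd.to_numeric(self.data["longitude"])
            if ((lon < -180) | (lon > 180)).any():
                raise ValidationError("longitude outside [-180, 180]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def require_samples(self, sample_ids) -> None:
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")

    def column(self, name: str, sample_ids=None) -> pd.Series:
        if name not in self.data.columns:
            raise ValidationError(f"metadata column {name!r} not found")
        col = self.data[name]
        if sample_ids is not None:
            self.require_samples(sample_ids)
            col = col.loc[list(sample_ids)]
        return col


@dataclass
class DistanceMatrix:
    """Symmetric non-negative matrix with zero diagonal, keyed by ids."""

    ids: list[str]
    values: np.ndarray
    _SYM_TOL: float = field(default=1e-12, repr=False)

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        _check_unique(self.ids, "distance-matrix")
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.all(np.isfinite(v)):
            raise ValidationError("distance matrix contains non-finite values")
        if np.abs(v - v.T).max(initial=0.0) > self._SYM_TOL:
            raise ValidationError("distance matrix is not symmetric within 1e-12")
        v = (v + v.T) / 2.0
        if np.any(np.diag(v) != 0):
            raise ValidationError("distance matrix diagonal must be exactly 0")
        if np.any(v < 0):
            raise ValidationError("distance matrix contains negative values")
        self.values = v

    @property
    def shape(self):
        return self.values.shape

    def to_skbio(self) -> skbio.DistanceMatrix:
        return skbio.DistanceMatrix(self.values, ids=self.ids)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", index_label="id"
        )

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))


def read_otu_table(path, orientation: str = "otus_as_rows") -> OTUTable:
    """Read a tab-separated OTU count table.

    ``orientation`` declares the file layout: ``"otus_as_rows"`` (the common
    dialect, default) or ``"samples_as_rows"``. The returned table is always
    samples x OTUs.
    """
    if orientation not in ("otus_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    if df.empty:
        raise ValidationError(f"empty OTU table: {path}")
    if orientation == "otus_as_rows":
        df = df.T
    for axis_ids, kind in ((df.index, "sample"), (df.columns, "OTU")):
        dupes = axis_ids[axis_ids.duplicated()]
        if len(dupes):
            raise ValidationError(f"duplicate {kind} identifier: {dupes[0]!r}")
    return OTUTable.from_dataframe(df)


def write_otu_table(table: OTUTable, path, orientation: str = "otus_as_rows") -> None:
    df = table.to_dataframe()
    if orientation == "otus_as_rows":
        df = df.T
        df.index.name = "otu_id"
    else:
        df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_metadata(path, sep: str | None = None) -> MetadataTable:
    """Read sample metadata from CSV or TSV (sniffed from the header line)."""
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return MetadataTable(df)


def validate_tree(tree: skbio.TreeNode) -> skbio.TreeNode:
    tips = [t.name for t in tree.tips()]
    _check_unique(tips, "tip")
    if not tips:
        raise ValidationError("tree has no tips")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValidationError(
                f"missing branch length above node {node.name or '<internal>'!r}"
            )
        if node.length < 0:
            raise ValidationError(f"negative branch length: {node.length}")
    return tree


def read_newick(path_or_string) -> skbio.TreeNode:
    """Read a single rooted newick tree with branch lengths.

    Accepts a path or a literal newick string. Every branch must carry a
    length and tip labels must be unique.
    """
    src = path_or_string
    if isinstance(src, str) and src.lstrip().startswith("("):
        src = io.StringIO(src)
    tree = skbio.TreeNode.read(src, format="newick")
    if tree.length is None:
        tree.length = 0.0  # root edge is irrelevant to patristic distances
    return validate_tree(tree)


def write_newick(tree: skbio.TreeNode, path) -> None:
    tree.write(path, format="newick")


def tip_distance_matrix(tree: skbio.TreeNode) -> DistanceMatrix:
    """Patristic (sum of branch length) distances between all tips."""
    tips = [t.name for t in tree.tips()]
    if len(tips) == 1:
        return DistanceMatrix(tips, np.zeros((1, 1)))
    dm = tree.tip_tip_distances()
    return DistanceMatrix(list(dm.ids), np.asarray(dm.data, dtype=float))


def relative_abundance(table: OTUTable) -> np.ndarray:
    """Row-normalized counts; each row sums to 1."""
    totals = table.counts.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValidationError(
            f"sample {table.sample_ids[zero[0]]!r} has zero total counts"
        )
    return table.counts / totals[:, None]


def rarefy(table: OTUTable, depth: int, seed: int, drop_shallow: bool = True) -> OTUTable:
    """Random subsample without replacement to a common depth.

    Optional preprocessing; analyses default to relative abundances instead.
    Samples with fewer than ``depth`` reads are dropped (or an error is
    raised when ``drop_shallow`` is false).
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    keep_rows, rarefied = [], []
    for i, sid in enumerate(table.sample_ids):
        row = table.counts[i]
        total = row.sum()
        if total < depth:
            if drop_shallow:
                continue
            raise ValidationError(f"sample {sid!r} has {total} < depth {depth} reads")
        pool = np.repeat(np.arange(table.n_otus), row)
        chosen = rng.choice(pool, size=depth, replace=False)
        rarefied.append(np.bincount(chosen, minlength=table.n_otus))
        keep_rows.append(sid)
    if not rarefied:
        raise ValidationError("no sample reaches the rarefaction depth")
    return OTUTable(keep_rows, list(table.otu_ids), np.vstack(rarefied))


def prune_to_intersection(table: OTUTable, tree: skbio.TreeNode):
    """Restrict a table and tree to their common OTU set.

    Returns ``(table, tree, dropped_otu_ids)``. Opt-in alternative to the
    default hard error when table OTUs are missing from the phylogeny.
    """
    tips = {t.name for t in tree.tips()}
    keep = [o for o in table.otu_ids if o in tips]
    dropped = [o for o in table.otu_ids if o not in tips]
    if not keep:
        raise ValidationError("no OTUs shared between table and tree")
    cols = [table.otu_ids.index(o) for o in keep]
    counts = table.counts[:, cols]
    nonempty = counts.sum(axis=1) > 0
    if not nonempty.all():
        bad = [s for s, ok in zip(table.sample_ids, nonempty) if not ok]
        raise ValidationError(f"samples emptied by pruning: {bad}")
    pruned_table = OTUTable(list(table.sample_ids), keep, counts)
    pruned_tree = tree.shear(keep)
    return pruned_table, pruned_tree, dropped
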