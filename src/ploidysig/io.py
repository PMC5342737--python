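"""Core data containers and readers/writers for every file format the pipeline touches.

All expression values are exchanged on log2 scale.  Readers validate eagerly and
raise :class:`~ploidysig.errors.FormatError` naming the file, line and field at
fault rather than silently coercing; missing values are not supported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError

logger = logging.getLogger(__name__)

PLOIDY_CLASSES = ("diploid", "polyploid")


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene-by-sample matrix of log2 expression values.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by gene id, columns by sample id, float values.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r} in expression matrix")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r} in expression matrix")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise FormatError("non-numeric values in expression matrix")
        if values.size and not np.isfinite(values).all():
            g, s = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"non-finite value at gene {idx[g]!r}, sample {cols[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(sample_ids)])


def read_expression(path, linear: bool = False) -> ExpressionMatrix:
    """Read a tab-separated expression matrix (first column gene ids).

    ``linear=True`` declares the file to be on linear scale and applies
    log2(x + 1) on load, so that all in-memory matrices share the log2 scale.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise FormatError(f"{path}: cannot parse expression matrix: {exc}") from exc
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise FormatError(
                f"{path}: non-numeric cell at gene {row!r}, sample {col!r}"
            )
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    df = df.astype(float)
    if linear:
        if (df.to_numpy() < 0).any():
            raise FormatError(f"{path}: negative value in linear-scale matrix")
        df = np.log2(df + 1.0)
    mat = ExpressionMatrix(df)
    if not np.isfinite(mat.values).all():
        raise FormatError(f"{path}: non-finite value in expression matrix")
    return mat


def write_expression(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix as TSV preserving >=12 significant digits."""
    matrix.data.to_csv(path, sep="\t", float_format="%.15g", index_label="gene_id")


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

SHEET_COLUMNS = ["sample_id", "species", "tissue", "ploidy_class", "replicate"]


@dataclass
class SampleSheet:
    """Per-sample metadata: species, tissue, ploidy class and replicate index."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SHEET_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns {missing}")
        if self.data["sample_id"].duplicated().any():
            dup = self.data["sample_id"][self.data["sample_id"].duplicated()].iloc[0]
            raise FormatError(f"duplicate sample id {dup!r} in sample sheet")
        bad = set(self.data["ploidy_class"]) - set(PLOIDY_CLASSES)
        if bad:
            raise FormatError(
                f"unknown ploidy_class {sorted(bad)}; expected one of {PLOIDY_CLASSES}"
            )
        # ploidy class must be constant within a (species, tissue) condition
        nun = self.data.groupby(["species", "tissue"])["ploidy_class"].nunique()
        mixed = nun[nun > 1]
        if len(mixed) and not self._single_condition():
            cond = mixed.index[0]
            raise DesignError(f"condition {cond} mixes ploidy classes")

    def _single_condition(self) -> bool:
        # A purified 2n-vs-4n dataset is one (species, tissue) with both classes;
        # there the condition label must include the ploidy class.
        return self.data.groupby(["species", "tissue"]).ngroups == 1

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def conditions(self) -> list[tuple]:
        """Ordered unique condition keys."""
        if self._single_condition():
            keys = self.data[["species", "tissue", "ploidy_class"]].drop_duplicates()
            return [tuple(r) for r in keys.itertuples(index=False)]
        keys = self.data[["species", "tissue"]].drop_duplicates()
        return [tuple(r) for r in keys.itertuples(index=False)]

    def samples_for(self, condition) -> list[str]:
        condition = tuple(condition)
        d = self.data
        if len(condition) == 3:
            m = (
                (d["species"] == condition[0])
                & (d["tissue"] == condition[1])
                & (d["ploidy_class"] == condition[2])
            )
        else:
            m = (d["species"] == condition[0]) & (d["tissue"] == condition[1])
        return list(d.loc[m, "sample_id"])

    def condition_meta(self, condition) -> dict:
        samples = self.samples_for(condition)
        if not samples:
            raise DesignError(f"condition {condition} has no samples")
        row = self.data[self.data["sample_id"] == samples[0]].iloc[0]
        return {
            "species": row["species"],
            "tissue": row["tissue"],
            "ploidy_class": row["ploidy_class"],
        }

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        sheet_ids = set(self.sample_ids)
        mat_ids = set(matrix.sample_ids)
        if sheet_ids != mat_ids:
            raise DesignError(
                f"sample sheet / matrix mismatch: only-in-sheet={sorted(sheet_ids - mat_ids)[:5]}, "
                f"only-in-matrix={sorted(mat_ids - sheet_ids)[:5]}"
            )


def read_sample_sheet(path) -> SampleSheet:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: cannot parse sample sheet: {exc}") from exc
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ortholog table
# ---------------------------------------------------------------------------

@dataclass
class OrthologTable:
    """Strict one-to-one ortholog mapping between two species.

    Cross-species set operations are keyed on ``group_id``; the table maps a
    group to its gene id in each species.
    """

    data: pd.DataFrame  # columns group_id, gene_a, gene_b

    def __post_init__(self) -> None:
        for col in ("group_id", "gene_a", "gene_b"):
            if col not in self.data.columns:
                raise FormatError(f"ortholog table missing column {col!r}")
            if self.data[col].duplicated().any():
                dup = self.data[col][self.data[col].duplicated()].iloc[0]
                raise FormatError(
                    f"ortholog table not one-to-one: {dup!r} repeated in {col}"
                )
        overlap = set(self.data["gene_a"]) & set(self.data["gene_b"])
        if overlap:
            raise FormatError(
                f"gene id {sorted(overlap)[0]!r} appears in both species columns"
            )

    @property
    def group_ids(self) -> list[str]:
        return list(self.data["group_id"])

    def b_to_group(self) -> dict:
        return dict(zip(self.data["gene_b"], self.data["group_id"]))

    def a_to_group(self) -> dict:
        return dict(zip(self.data["gene_a"], self.data["group_id"]))


def read_orthologs(path) -> OrthologTable:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: cannot parse ortholog table: {exc}") from exc
    return OrthologTable(df)


def write_orthologs(table: OrthologTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """term_id -> (description, member gene ids)."""

    terms: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, (_, members) in self.terms.items():
            if not members:
                raise FormatError(f"term {term!r} has no members")

    def __len__(self) -> int:
        return len(self.terms)

    def members(self, term_id) -> frozenset:
        return self.terms[term_id][1]

    def items(self):
        return self.terms.items()


def read_gene_sets(path) -> GeneSetCollection:
    """Read GMT: term, description, then member ids, tab-separated."""
    terms: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >=3"
                )
            term, desc, members = fields[0], fields[1], fields[2:]
            members = [m for m in members if m]
            uniq = list(dict.fromkeys(members))
            if len(uniq) < len(members):
                logger.warning(
                    "%s:%d: term %s has duplicated members; deduplicated",
                    path, lineno, term,
                )
            if term in terms:
                raise FormatError(f"{path}:{lineno}: duplicate term id {term!r}")
            terms[term] = (desc, frozenset(uniq))
    return GeneSetCollection(terms)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term, (desc, members) in collection.items():
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# edge list (STRING-style)
# ---------------------------------------------------------------------------

@dataclass
class EdgeList:
    """Undirected weighted edges, weights in [0, 1], duplicates collapsed to max."""

    data: pd.DataFrame  # columns node_a, node_b, weight

    def __post_init__(self) -> None:
        w = self.data["weight"]
        if len(w) and ((w < 0) | (w > 1)).any():
            bad = w[(w < 0) | (w > 1)].iloc[0]
            raise FormatError(f"edge weight {bad} outside [0, 1]")


def _canonicalize_edges(df: pd.DataFrame, origin: str) -> pd.DataFrame:
    self_loops = df["node_a"] == df["node_b"]
    if self_loops.any():
        warnings.warn(
            f"{origin}: dropped {int(self_loops.sum())} self-edge(s)", stacklevel=2
        )
        df = df[~self_loops]
    a = df[["node_a", "node_b"]].min(axis=1)
    b = df[["node_a", "node_b"]].max(axis=1)
    out = pd.DataFrame({"node_a": a, "node_b": b, "weight": df["weight"].to_numpy()})
    out = (
        out.groupby(["node_a", "node_b"], as_index=False)["weight"]
        .max()
        .sort_values(["node_a", "node_b"])
        .reset_index(drop=True)
    )
    return out


def read_edge_list(path) -> EdgeList:
    """Read a 3-column edge TSV.

    Weights may be floats in [0, 1] or STRING combined scores in [0, 1000];
    the integer dialect is auto-detected (any value > 1 => divide all by 1000).
    """
    try:
        df = pd.read_csv(
            path, sep=r"\s+", header=None, names=["node_a", "node_b", "weight"],
            dtype={"node_a": str, "node_b": str},
        )
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: cannot parse edge list: {exc}") from exc
    if len(df) and df.iloc[0]["weight"] == "weight":  # optional header row
        df = df.iloc[1:].reset_index(drop=True)
    try:
        df["weight"] = df["weight"].astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric weight: {exc}") from exc
    if len(df) and (df["weight"] > 1).any():
        df["weight"] = df["weight"] / 1000.0
        if (df["weight"] > 1).any():
            bad = df["weight"][df["weight"] > 1].iloc[0] * 1000
            raise FormatError(
                f"{path}: weight {bad} exceeds 1000 in combined-score dialect"
            )
    if len(df) and (df["weight"] < 0).any():
        raise FormatError(f"{path}: negative edge weight")
    return EdgeList(_canonicalize_edges(df, str(path)))


def write_edge_list(edges: EdgeList, path) -> None:
    edges.data.to_csv(path, sep="\t", index=False, header=False,
                      float_format="%.6g")


def edge_list_from_records(records) -> EdgeList:
    """Build an EdgeList from (node_a, node_b, weight) triples."""
    df = pd.DataFrame(records, columns=["node_a", "node_b", "weight"])
    df["weight"] = df["weight"].astype(float)
    return EdgeList(_canonicalize_edges(df, "<records>"))


# ---------------------------------------------------------------------------
# gene lists / interactome
# ---------------------------------------------------------------------------

def read_gene_list(path) -> set:
    """One gene id per line; blank lines ignored."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def interactome_coverage(interactome, universe) -> dict:
    """Report how an interactant list overlaps a declared gene universe."""
    interactome, universe = set(interactome), set(universe)
    inside = interactome & universe
    return {
        "n_interactants": len(interactome),
        "n_in_universe": len(inside),
        "n_outside_universe": len(interactome - universe),
        "background_proportion": len(inside) / len(universe) if universe else float("nan"),
    }
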