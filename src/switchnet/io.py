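"""Readers and writers for the delimited formats the pipeline touches.

All inputs are plain text: an expression matrix (genes in rows, header row of
sample ids), a two-column sample annotation (sample_id, group), GMT gene-set
collections, two/three-column regulator-gene edge tables, and one-id-per-line
gene lists.  Gene identifiers are treated as opaque strings; no probe/symbol
mapping is attempted beyond an optional max-mean collapse helper.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("case", "control")

#: Matrices whose maximum value is below this are assumed to already be on a
#: log2 scale; anything larger is treated as linear and log2(x+1) transformed.
LOG2_MAX_HEURISTIC = 30.0


class FormatError(ValueError):
    """Raised when an input file violates the expected layout."""


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with a case/control design.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by gene id, columns by sample id.  Stored on a log2
        scale (see ``log2_scale``).
    groups : pandas.Series
        Maps every sample id to ``"case"`` or ``"control"``.
    log2_scale : bool
        True when ``values`` are log2 expression.  Loaders convert linear
        data with ``log2(x + 1)``.
    """

    values: pd.DataFrame
    groups: pd.Series
    log2_scale: bool = True

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if not isinstance(self.groups, pd.Series):
            self.groups = pd.Series(dict(self.groups))
        dup = self.values.index[self.values.index.duplicated()]
        if len(dup):
            raise FormatError(f"duplicate gene id(s): {', '.join(map(str, dup.unique()))}")
        dup = self.values.columns[self.values.columns.duplicated()]
        if len(dup):
            raise FormatError(f"duplicate sample id(s): {', '.join(map(str, dup.unique()))}")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise FormatError(f"samples without group annotation: {', '.join(missing)}")
        bad = set(self.groups.loc[list(self.values.columns)]) - set(GROUPS)
        if bad:
            raise FormatError(f"unknown group label(s): {sorted(bad)}; expected {GROUPS}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise FormatError("expression matrix contains non-finite values")
        # keep only annotation for present samples, in matrix order
        self.groups = self.groups.loc[list(self.values.columns)]

    # -- convenience views -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def case_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == "case"])

    @property
    def control_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == "control"])

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = [g for g in self.gene_ids if g in set(genes)]
        return ExpressionMatrix(self.values.loc[genes], self.groups.copy(), self.log2_scale)

    def n_per_group(self) -> dict[str, int]:
        return {g: int((self.groups == g).sum()) for g in GROUPS}


def _sniff_delimiter(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_expression(matrix_path, annotation_path, *, delimiter: str | None = None,
                    scale: str | None = None) -> ExpressionMatrix:
    """Read a delimited expression table plus its sample annotation.

    ``scale`` may be ``"log2"``, ``"linear"`` or None (auto: values with a
    maximum >= 30 are taken as linear and log2(x+1) transformed).
    """
    delim = delimiter or _sniff_delimiter(matrix_path)
    raw = pd.read_csv(matrix_path, sep=delim, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    dup = raw.index[raw.index.duplicated()]
    if len(dup):
        raise FormatError(f"duplicate gene id(s) in {matrix_path}: "
                          f"{', '.join(map(str, dup.unique()))}")
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(values.isna().to_numpy() & raw.notna().to_numpy())
    if len(bad):
        r, c = bad[0]
        raise FormatError(
            f"non-numeric cell in {matrix_path} at gene {values.index[r]!r}, "
            f"sample {values.columns[c]!r}: {raw.iat[r, c]!r}")
    if values.isna().to_numpy().any():
        r, c = np.argwhere(values.isna().to_numpy())[0]
        raise FormatError(f"missing value in {matrix_path} at gene {values.index[r]!r}, "
                          f"sample {values.columns[c]!r}")

    groups = read_annotation(annotation_path)
    unknown = [s for s in groups.index if s not in set(values.columns)]
    if unknown:
        raise FormatError(f"annotation references unknown sample(s): {', '.join(unknown)}")

    if scale not in (None, "log2", "linear"):
        raise ValueError("scale must be 'log2', 'linear' or None")
    if scale is None:
        scale = "log2" if values.to_numpy().max() < LOG2_MAX_HEURISTIC else "linear"
        logger.info("expression scale auto-detected as %s", scale)
    if scale == "linear":
        if (values.to_numpy() < 0).any():
            raise FormatError("linear-scale matrix contains negative values")
        values = np.log2(values + 1.0)
    return ExpressionMatrix(values, groups, log2_scale=True)


def read_annotation(path, *, delimiter: str | None = None) -> pd.Series:
    """Read a two-column (sample_id, group) table; the header row is optional."""
    delim = delimiter or _sniff_delimiter(path)
    tab = pd.read_csv(path, sep=delim, header=None, dtype=str)
    if tab.shape[1] < 2:
        raise FormatError(f"annotation {path} needs two columns (sample_id, group)")
    if str(tab.iloc[0, 1]).strip().lower() not in GROUPS:  # header row
        tab = tab.iloc[1:]
    groups = pd.Series(tab.iloc[:, 1].str.strip().str.lower().to_numpy(),
                       index=tab.iloc[:, 0].str.strip())
    bad = set(groups) - set(GROUPS)
    if bad:
        raise FormatError(f"unknown group label(s) in {path}: {sorted(bad)}")
    if groups.index.duplicated().any():
        raise FormatError(f"duplicate sample id(s) in {path}")
    return groups


def write_expression(expr: ExpressionMatrix, matrix_path, annotation_path,
                     *, delimiter: str = "\t") -> None:
    expr.values.to_csv(matrix_path, sep=delimiter, index_label="gene")
    ann = pd.DataFrame({"sample_id": expr.sample_ids,
                        "group": expr.groups.loc[expr.sample_ids].to_numpy()})
    ann.to_csv(annotation_path, sep=delimiter, index=False)


def collapse_max_mean(expr: ExpressionMatrix, probe_to_gene: dict) -> ExpressionMatrix:
    """Collapse probe-level rows to genes, keeping the probe with max mean expression."""
    means = expr.values.mean(axis=1)
    best: dict[str, str] = {}
    for probe in expr.gene_ids:
        gene = probe_to_gene.get(probe)
        if gene is None:
            continue
        if gene not in best or means[probe] > means[best[gene]]:
            best[gene] = probe
    if not best:
        raise ValueError("no probe maps to a gene")
    values = expr.values.loc[list(best.values())]
    values.index = list(best.keys())
    return ExpressionMatrix(values, expr.groups.copy(), expr.log2_scale)


# ---------------------------------------------------------------------------
# gene-set collections (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets: ``sets[name] = (description, member tuple)``."""

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> tuple[str, ...]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >=3 tab-separated "
                                  f"fields, got {len(fields)}")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = tuple(dict.fromkeys(m for m in fields[2:] if m))
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# regulator-gene edge tables
# ---------------------------------------------------------------------------

INTERACTION_KINDS = ("tf", "mirna", "chemical")


@dataclass
class InteractionTable:
    """Regulator->gene edges from one or more source databases."""

    edges: pd.DataFrame  # columns: regulator, gene, source
    kind: str = "tf"

    def __post_init__(self) -> None:
        if self.kind not in INTERACTION_KINDS:
            raise ValueError(f"kind must be one of {INTERACTION_KINDS}")
        required = ["regulator", "gene", "source"]
        missing = [c for c in required if c not in self.edges.columns]
        if missing:
            raise FormatError(f"edge table missing column(s): {', '.join(missing)}")
        if (self.edges["source"].astype(str).str.len() == 0).any():
            raise FormatError("empty source tag in edge table")
        ndup = int(self.edges.duplicated(subset=required).sum())
        if ndup:
            logger.warning("collapsing %d duplicated (regulator, gene, source) edges", ndup)
            self.edges = self.edges.drop_duplicates(subset=required, ignore_index=True)
        self.edges = self.edges[required].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.edges)


def read_edge_table(path, kind: str, *, delimiter: str | None = None) -> InteractionTable:
    delim = delimiter or _sniff_delimiter(path)
    tab = pd.read_csv(path, sep=delim, dtype=str)
    tab.columns = [c.strip().lower() for c in tab.columns]
    for col in ("regulator", "gene"):
        if col not in tab.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if "source" not in tab.columns:
        tab["source"] = "user"
    return InteractionTable(tab[["regulator", "gene", "source"]], kind=kind)


def write_edge_table(table: InteractionTable, path, *, delimiter: str = "\t") -> None:
    table.edges.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# gene lists
# ---------------------------------------------------------------------------

def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
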