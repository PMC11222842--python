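"""Abundance and phenotype tables: I/O, normalisation, taxonomic collapse, carcass traits.

The canonical in-memory layout is taxon x sample (taxa as rows).  Readers
accept both orientations and normalise.  Two TSV dialects are understood:
a plain matrix with one header row of identifiers, and the QIIME2
feature-table export dialect whose header starts with ``#OTU ID`` and which
may carry a trailing ``taxonomy`` column of semicolon-delimited lineages.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "PhenotypeTable",
    "read_abundance_table",
    "write_abundance_table",
    "read_phenotype_table",
    "write_phenotype_table",
    "to_relative",
    "collapse_to_level",
    "derive_carcass_traits",
]

#: Fixed label for taxa that lack a name at the requested rank.
UNCLASSIFIED = "unclassified"

#: Conventional rank prefixes used in semicolon-delimited lineages
#: (QIIME/Greengenes style ``g__Bacteroides`` as well as bare names).
RANK_ORDER = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = {r: r[0] + "__" for r in RANK_ORDER}

MEASURED_WEIGHT_COLUMNS = (
    "body_weight",
    "dressed_weight",
    "eviscerated_weight",
    "breast_muscle_weight",
    "leg_muscle_weight",
)

DERIVED_PERCENT_COLUMNS = (
    "dressed_percentage",
    "eviscerated_yield_percentage",
    "leg_muscle_percentage",
    "breast_muscle_percentage",
)


@dataclass
class AbundanceTable:
    """Taxon-by-sample abundance matrix with optional taxonomy strings.

    Parameters
    ----------
    values : ndarray, shape (n_taxa, n_samples)
        Non-negative counts or relative abundances.
    taxon_ids, sample_ids : list of str
        Unique, ordered identifiers for rows and columns.
    mode : {"counts", "relative"}
        In ``relative`` mode every sample column sums to 1.
    level : str
        Taxonomic rank tag of the rows (e.g. ``genus``).
    taxonomy : list of str or None
        Per-taxon semicolon-delimited lineage strings.
    """

    values: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]
    mode: str = "counts"
    level: str = "genus"
    taxonomy: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.validate()

    # -- basic protocol ------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        v = self.values
        if v.ndim != 2:
            raise ValueError("values must be a 2-D taxon x sample matrix")
        if v.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {v.shape} does not match {len(self.taxon_ids)} taxa "
                f"x {len(self.sample_ids)} samples"
            )
        if v.size == 0:
            raise ValueError("empty abundance table")
        _check_unique(self.taxon_ids, "taxon id")
        _check_unique(self.sample_ids, "sample id")
        if not np.all(np.isfinite(v)):
            raise ValueError("abundance values must be finite")
        if (v < 0).any():
            it, js = np.argwhere(v < 0)[0]
            raise ValueError(
                f"negative abundance at taxon {self.taxon_ids[it]!r}, "
                f"sample {self.sample_ids[js]!r}"
            )
        if self.mode not in ("counts", "relative"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "counts":
            if not np.allclose(v, np.round(v), atol=1e-6):
                raise ValueError("counts mode requires integer values")
        else:
            colsum = v.sum(axis=0)
            bad = np.where(np.abs(colsum - 1.0) > 1e-9)[0]
            if bad.size:
                j = int(bad[0])
                raise ValueError(
                    f"relative-mode column {self.sample_ids[j]!r} sums to "
                    f"{colsum[j]:.12g}, expected 1"
                )
        if self.taxonomy is not None and len(self.taxonomy) != len(self.taxon_ids):
            raise ValueError("taxonomy length does not match taxon count")

    def to_frame(self) -> pd.DataFrame:
        """Taxon x sample DataFrame view (copy)."""
        return pd.DataFrame(self.values.copy(), index=self.taxon_ids, columns=self.sample_ids)

    def select_samples(self, sample_ids: list[str]) -> "AbundanceTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return AbundanceTable(
            self.values[:, idx],
            list(self.taxon_ids),
            list(sample_ids),
            mode=self.mode,
            level=self.level,
            taxonomy=list(self.taxonomy) if self.taxonomy is not None else None,
        )


@dataclass
class PhenotypeTable:
    """Per-sample growth-performance and carcass traits.

    Raw weights are in grams; derived traits are percentages.  Dressed and
    eviscerated-yield percentages are expressed relative to live body
    weight; breast/leg muscle percentages relative to eviscerated weight.
    """

    data: pd.DataFrame  # index = sample ids

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in MEASURED_WEIGHT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype table lacks columns: {missing}")
        _check_unique(list(df.index), "sample id")
        w = df[list(MEASURED_WEIGHT_COLUMNS)].to_numpy(dtype=float)
        if not np.all(np.isfinite(w)) or (w <= 0).any():
            raise ValueError("all weights must be positive and finite")
        if (df["eviscerated_weight"] > df["dressed_weight"] + 1e-9).any():
            bad = df.index[df["eviscerated_weight"] > df["dressed_weight"] + 1e-9][0]
            raise ValueError(f"eviscerated > dressed weight for sample {bad!r}")
        if (df["dressed_weight"] > df["body_weight"] + 1e-9).any():
            bad = df.index[df["dressed_weight"] > df["body_weight"] + 1e-9][0]
            raise ValueError(f"dressed > body weight for sample {bad!r}")
        for c in DERIVED_PERCENT_COLUMNS:
            if c in df.columns:
                p = df[c].to_numpy(dtype=float)
                if (p <= 0).any() or (p > 100).any():
                    raise ValueError(f"{c} outside (0, 100]")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def traits(self) -> list[str]:
        return [c for c in self.data.columns]

    def trait(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what}: {x!r}")
        seen.add(x)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_abundance_table(
    path,
    orientation: str = "taxa_rows",
    mode: str = "counts",
    level: str = "genus",
) -> AbundanceTable:
    """Read a tab-delimited abundance matrix.

    Accepts a plain matrix (one header row of identifiers) or the QIIME2
    export dialect (leading ``#`` comment lines, a ``#OTU ID`` header and an
    optional trailing ``taxonomy`` column).  ``orientation`` states whether
    the file rows are taxa (``taxa_rows``) or samples (``samples_rows``);
    the returned table is always taxon x sample.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    with open(path, "rt", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    # QIIME2 exports start with '# Constructed from biom file' then '#OTU ID\t...'
    header_idx = None
    for i, line in enumerate(lines):
        if not line.strip():
            continue
        if line.startswith("#OTU ID"):
            header_idx = i
            break
        if not line.startswith("#"):
            header_idx = i
            break
    if header_idx is None:
        raise ValueError(f"empty table in {path}")
    # pandas mangles duplicate header fields; detect them on the raw line
    _check_unique([f for f in lines[header_idx].split("\t")[1:] if f.strip()],
                  "header identifier")
    body = "\n".join(lines[header_idx:])
    df = pd.read_csv(io.StringIO(body), sep="\t", header=0, index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty table in {path}")
    df.index = df.index.astype(str)

    taxonomy = None
    tax_col = [c for c in df.columns if c.strip().lower() == "taxonomy"]
    if tax_col and orientation == "taxa_rows":
        taxonomy = [str(x) for x in df[tax_col[0]]]
        df = df.drop(columns=tax_col)

    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric cell {cell!r} at row {df.index[i]!r}, "
                    f"column {col!r} in {path}"
                ) from None

    row_ids = [str(x) for x in df.index]
    col_ids = [str(x) for x in df.columns]
    if orientation == "samples_rows":
        values = values.T
        taxon_ids, sample_ids = col_ids, row_ids
    else:
        taxon_ids, sample_ids = row_ids, col_ids
    return AbundanceTable(values, taxon_ids, sample_ids, mode=mode, level=level,
                          taxonomy=taxonomy)


def write_abundance_table(table: AbundanceTable, path, orientation: str = "taxa_rows") -> None:
    """Write a tab-delimited abundance matrix (UTF-8, LF line endings)."""
    df = table.to_frame()
    if table.taxonomy is not None and orientation == "taxa_rows":
        df = df.copy()
        df["taxonomy"] = table.taxonomy
    if orientation == "samples_rows":
        if table.taxonomy is not None:
            raise ValueError("taxonomy column requires taxa_rows orientation")
        df = df.T
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index_label="id", lineterminator="\n")


def read_phenotype_table(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", header=0, index_col=0)
    df.index = df.index.astype(str)
    return PhenotypeTable(df)


def write_phenotype_table(table: PhenotypeTable, path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        table.data.to_csv(fh, sep="\t", index_label="sample_id", lineterminator="\n")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Convert a counts table to per-sample relative abundances."""
    if table.mode == "relative":
        return table
    totals = table.values.sum(axis=0)
    zero = np.where(totals <= 0)[0]
    if zero.size:
        raise ValueError(
            f"sample {table.sample_ids[int(zero[0])]!r} has zero total count"
        )
    rel = table.values / totals
    # squash round-off so the relative-mode invariant holds exactly enough
    rel = rel / rel.sum(axis=0)
    return AbundanceTable(rel, list(table.taxon_ids), list(table.sample_ids),
                          mode="relative", level=table.level,
                          taxonomy=list(table.taxonomy) if table.taxonomy else None)


def _rank_from_lineage(lineage: str, rank: str) -> str:
    """Extract the name at ``rank`` from a semicolon-delimited lineage.

    Understands prefixed fields (``g__Bacteroides``) and falls back to
    positional parsing for bare 7-rank lineages.  Empty or missing names
    map to the shared unclassified bucket.
    """
    if rank not in RANK_PREFIXES:
        raise ValueError(f"unknown rank {rank!r}")
    fields = [f.strip() for f in lineage.split(";")]
    prefix = RANK_PREFIXES[rank]
    for f in fields:
        if f.lower().startswith(prefix):
            name = f[len(prefix):].strip()
            return name if name else UNCLASSIFIED
    # bare positional lineage
    if not any("__" in f for f in fields):
        pos = RANK_ORDER.index(rank)
        if pos < len(fields) and fields[pos]:
            return fields[pos]
    return UNCLASSIFIED


def collapse_to_level(table: AbundanceTable, rank: str) -> AbundanceTable:
    """Sum taxa sharing the same name at ``rank``; unnamed taxa pool into
    a single ``unclassified`` bucket.  Per-sample totals are conserved and
    output taxa are sorted lexicographically."""
    if table.taxonomy is None:
        raise ValueError("collapse requires taxonomy strings")
    names = [_rank_from_lineage(lin, rank) for lin in table.taxonomy]
    order = sorted(set(names))
    out = np.zeros((len(order), table.n_samples))
    pos = {n: i for i, n in enumerate(order)}
    for row, name in enumerate(names):
        out[pos[name]] += table.values[row]
    if table.mode == "relative":
        out = out / out.sum(axis=0)
    return AbundanceTable(out, order, list(table.sample_ids), mode=table.mode,
                          level=rank)


# ---------------------------------------------------------------------------
# carcass traits
# ---------------------------------------------------------------------------

def derive_carcass_traits(raw: pd.DataFrame) -> PhenotypeTable:
    """Attach derived carcass percentages to a table of measured weights.

    dressed% and eviscerated-yield% are relative to live body weight;
    leg/breast muscle% relative to eviscerated weight (the denominator
    convention of the Chinese poultry carcass standard NY/T 823-2004).

    ``raw`` must be indexed by sample id with the five measured-weight
    columns in grams.
    """
    missing = [c for c in MEASURED_WEIGHT_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"missing weight columns: {missing}")
    df = raw[list(MEASURED_WEIGHT_COLUMNS)].astype(float).copy()
    df.index = raw.index.astype(str)
    df["dressed_percentage"] = df["dressed_weight"] / df["body_weight"] * 100.0
    df["eviscerated_yield_percentage"] = df["eviscerated_weight"] / df["body_weight"] * 100.0
    df["leg_muscle_percentage"] = df["leg_muscle_weight"] / df["eviscerated_weight"] * 100.0
    df["breast_muscle_percentage"] = df["breast_muscle_weight"] / df["eviscerated_weight"] * 100.0
    return PhenotypeTable(df)
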