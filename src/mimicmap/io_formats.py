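"""Readers and writers for every external format the pipeline touches.

All tabular inputs and outputs are plain TSV so that runs are diff-able and
bit-stable.  Expression matrices are probes x samples on log2 scale; sample
groups and probe annotations are two-column TSV; gene sets are GMT; curated
gene lists are one-symbol-per-line or CSV with a symbol column.  GEO
series-matrix files are supported through a thin converter to the TSV matrix
form.

Gene symbols are matched case-insensitively after uppercasing and no alias or
identifier-mapping service is consulted; an optional user-supplied alias table
can be applied before matching (:func:`apply_alias_map`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "ExpressionDataset",
    "HMGList",
    "GeneSet",
    "GeneSetCollection",
    "normalize_symbol",
    "apply_alias_map",
    "read_expression_dataset",
    "write_expression_dataset",
    "read_gmt",
    "write_gmt",
    "read_hmg_list",
    "check_hmg_pair",
    "read_series_matrix",
    "write_tsv",
    "FLOAT_FORMAT",
]

#: Fixed float serialization for every TSV the package writes (6 significant
#: digits), so reruns are byte-identical.
FLOAT_FORMAT = "%.6g"

GO_CATEGORIES = ("pathway", "MF", "CC", "BP")


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


def normalize_symbol(symbol: str) -> str:
    """Uppercase and strip a gene symbol.  Idempotent."""
    return str(symbol).strip().upper()


def apply_alias_map(symbols: Mapping[str, str] | Iterable[str],
                    alias: Mapping[str, str]):
    """Rewrite symbols through a user-supplied alias table (old -> preferred).

    Accepts either a probe->symbol mapping (returns the rewritten mapping) or
    an iterable of symbols (returns a list).  Aliases are applied after
    normalization; symbols without an alias entry pass through unchanged.
    """
    norm_alias = {normalize_symbol(k): normalize_symbol(v) for k, v in alias.items()}
    if isinstance(symbols, Mapping):
        return {k: norm_alias.get(normalize_symbol(v), normalize_symbol(v))
                for k, v in symbols.items()}
    return [norm_alias.get(normalize_symbol(s), normalize_symbol(s)) for s in symbols]


def write_tsv(frame: pd.DataFrame, path, *, index: bool = False) -> None:
    """Write a DataFrame as TSV with the package-wide float format."""
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# ExpressionDataset
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """One accession's probe x sample log2 expression matrix.

    Parameters
    ----------
    dataset_id : accession-style identifier (e.g. ``"GSE36133"``).
    platform_id : array platform identifier (may be empty).
    values : DataFrame of log2 intensities, probes as index, samples as
        columns.  NaN marks missing measurements.
    probe_to_gene : probe id -> gene symbol; an empty symbol means the probe
        has no annotation.
    sample_groups : sample id -> group label (e.g. ``"poorly_diff"`` /
        ``"well_diff"`` or ``"tumour"`` / ``"non_tumour"``).
    """

    dataset_id: str
    platform_id: str
    values: pd.DataFrame
    probe_to_gene: dict[str, str]
    sample_groups: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(
                f"{self.dataset_id}: duplicate probe id {dup!r}")
        missing = [s for s in self.values.columns if s not in self.sample_groups]
        if missing:
            raise ValidationError(
                f"{self.dataset_id}: sample {missing[0]!r} has no group label")
        labels = {self.sample_groups[s] for s in self.values.columns}
        if len(labels) < 2:
            raise ValidationError(
                f"{self.dataset_id}: need >=2 distinct group labels, got {sorted(labels)}")
        if np.isinf(self.values.to_numpy(dtype=float, na_value=np.nan)).any():
            raise ValidationError(
                f"{self.dataset_id}: infinite expression values (must be finite or NaN)")
        self.probe_to_gene = {
            str(p): normalize_symbol(g) if str(g).strip() else ""
            for p, g in self.probe_to_gene.items()
        }

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    def samples_in_group(self, label: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_groups[s] == label]

    def group_labels(self) -> list[str]:
        return sorted({self.sample_groups[s] for s in self.values.columns})


def _read_two_column_tsv(path, what: str) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                fields = fields + [""]
            key, value = fields[0].strip(), fields[1].strip()
            # tolerate a header row
            if i == 1 and key.lower() in {"sample", "sample_id", "probe", "probe_id", "id"}:
                continue
            out[key] = value
    if not out:
        raise FormatError(f"{path}: empty {what} file")
    return out


def _parse_numeric_matrix(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.shape[1] == 0:
        raise FormatError(f"{path}: expression matrix has no sample columns")
    raw.index = raw.index.map(str)
    values = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    na_tokens = {"", "na", "nan", "null", "none"}
    bad = values.isna() & raw.notna() & ~raw.apply(
        lambda col: col.str.strip().str.lower().isin(na_tokens))
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {raw.iat[r, c]!r} at probe "
            f"{raw.index[r]!r}, sample {raw.columns[c]!r}")
    return values.astype(float)


def read_expression_dataset(matrix_path, groups_path, annot_path=None, *,
                            dataset_id: str | None = None,
                            platform_id: str = "",
                            log2_transform: str = "auto") -> ExpressionDataset:
    """Read a probe x sample TSV matrix plus its group and annotation files.

    ``log2_transform`` mimics GEO2R auto-detection: ``"auto"`` applies
    log2(x + 1) when the matrix maximum exceeds 50, ``"on"`` always applies
    it, ``"off"`` never does.  Probes with no annotation entry get an empty
    symbol.  A sample missing from the groups file is a validation error
    naming that sample; a non-numeric cell is a parse error with its
    row/column coordinates.
    """
    if log2_transform not in ("auto", "on", "off"):
        raise ValueError(f"log2_transform must be auto|on|off, got {log2_transform!r}")
    values = _parse_numeric_matrix(matrix_path)
    groups = _read_two_column_tsv(groups_path, "sample-group")
    missing = [s for s in values.columns if s not in groups]
    if missing:
        raise ValidationError(
            f"{groups_path}: sample {missing[0]!r} missing from groups file")
    annot: dict[str, str] = {}
    if annot_path is not None:
        with open(annot_path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                probe = fields[0].strip()
                symbol = fields[1].strip() if len(fields) > 1 else ""
                if i == 1 and probe.lower() in {"probe", "probe_id", "id", "id_ref"}:
                    continue
                annot[probe] = symbol
    probe_to_gene = {p: annot.get(p, "") for p in values.index}
    finite_max = np.nanmax(values.to_numpy()) if values.size else 0.0
    if log2_transform == "on" or (log2_transform == "auto" and finite_max > 50):
        values = np.log2(values + 1.0)
    return ExpressionDataset(
        dataset_id=dataset_id or Path(matrix_path).stem,
        platform_id=platform_id,
        values=values,
        probe_to_gene=probe_to_gene,
        sample_groups=groups,
    )


def write_expression_dataset(dataset: ExpressionDataset, matrix_path,
                             groups_path, annot_path) -> None:
    """Write the three TSV files :func:`read_expression_dataset` consumes."""
    frame = dataset.values.copy()
    frame.index.name = "probe_id"
    frame.to_csv(matrix_path, sep="\t", float_format=FLOAT_FORMAT)
    with open(groups_path, "w") as fh:
        for sample in dataset.values.columns:
            fh.write(f"{sample}\t{dataset.sample_groups[sample]}\n")
    with open(annot_path, "w") as fh:
        for probe in dataset.values.index:
            fh.write(f"{probe}\t{dataset.probe_to_gene.get(str(probe), '')}\n")


# ---------------------------------------------------------------------------
# Gene lists and gene sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HMGList:
    """A curated directional metabolic gene list (tumour-derived)."""

    direction: str  # "up" | "down"
    genes: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValidationError(f"direction must be up|down, got {self.direction!r}")
        object.__setattr__(self, "genes",
                           frozenset(normalize_symbol(g) for g in self.genes if str(g).strip()))
        if not self.genes:
            raise ValidationError("empty gene list")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.genes


def read_hmg_list(path, direction: str, *, source: str = "") -> HMGList:
    """Read a gene list: one symbol per line, or CSV with a symbol column.

    Symbols are uppercased and deduplicated.  An empty file is an error.
    """
    text = Path(path).read_text().strip()
    if not text:
        raise FormatError(f"{path}: empty gene list file")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = [f.strip().lower() for f in lines[0].replace("\t", ",").split(",")]
    symbol_cols = [i for i, h in enumerate(header)
                   if h in {"symbol", "gene", "gene_symbol", "gene.symbol"}]
    if symbol_cols:
        col = symbol_cols[0]
        genes = []
        for ln in lines[1:]:
            fields = ln.replace("\t", ",").split(",")
            if col < len(fields) and fields[col].strip():
                genes.append(fields[col])
    else:
        genes = [ln.replace("\t", ",").split(",")[0] for ln in lines]
    return HMGList(direction=direction, genes=frozenset(genes),
                   source=source or str(path))


def check_hmg_pair(up: HMGList, down: HMGList) -> None:
    """Validate that the up and down lists are disjoint."""
    if up.direction != "up" or down.direction != "down":
        raise ValidationError("expected an (up, down) pair of lists")
    shared = up.genes & down.genes
    if shared:
        raise ValidationError(
            f"{len(shared)} symbol(s) appear in both the up and down lists, "
            f"e.g. {sorted(shared)[0]!r}")


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    name: str
    category: str  # pathway | MF | CC | BP
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.category not in GO_CATEGORIES:
            raise ValidationError(
                f"{self.term_id}: category must be one of {GO_CATEGORIES}")
        object.__setattr__(self, "genes",
                           frozenset(normalize_symbol(g) for g in self.genes if str(g).strip()))
        if not self.genes:
            raise ValidationError(f"{self.term_id}: empty gene set")


@dataclass
class GeneSetCollection:
    """GMT-backed collection of term sets across annotation categories."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, geneset: GeneSet) -> None:
        if geneset.term_id in self.sets:
            raise ValidationError(f"duplicate term id {geneset.term_id!r}")
        self.sets[geneset.term_id] = geneset

    def merge(self, other: "GeneSetCollection") -> "GeneSetCollection":
        merged = GeneSetCollection(dict(self.sets))
        for gs in other.sets.values():
            merged.add(gs)
        return merged

    def by_category(self, category: str) -> list[GeneSet]:
        return [gs for gs in self.sets.values() if gs.category == category]

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneSetCollection) and self.sets == other.sets


def read_gmt(path, category: str = "pathway") -> GeneSetCollection:
    """Read a GMT file (term, description, tab-separated members).

    The annotation category applies to the whole file; read several files and
    :meth:`GeneSetCollection.merge` them to mix categories.
    """
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
            term, desc, members = fields[0], fields[1], fields[2:]
            members = [m for m in members if m.strip()]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {term!r} has no members")
            collection.add(GeneSet(term_id=term, name=desc or term,
                                   category=category, genes=frozenset(members)))
    if not collection.sets:
        raise FormatError(f"{path}: empty GMT file")
    return collection


def write_gmt(collection: GeneSetCollection, path,
              category: str | None = None) -> None:
    """Write (optionally one category of) a collection as GMT, sorted for
    byte-stable output."""
    with open(path, "w") as fh:
        for term_id in sorted(collection.sets):
            gs = collection.sets[term_id]
            if category is not None and gs.category != category:
                continue
            fh.write("\t".join([gs.term_id, gs.name, *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# GEO series-matrix converter
# ---------------------------------------------------------------------------

def read_series_matrix(path):
    """Thin converter from a GEO series-matrix file to matrix + metadata.

    Header lines beginning ``!`` are skipped except ``!Sample_title`` and
    ``!Sample_geo_accession``; the expression table between
    ``!series_matrix_table_begin`` and ``!series_matrix_table_end`` is parsed
    into a probes x samples DataFrame.  Returns ``(values, sample_titles)``
    where ``sample_titles`` maps sample id (GSM accession) to its title.
    """
    titles: list[str] = []
    accessions: list[str] = []
    table_lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!Sample_title"):
                titles = [f.strip().strip('"') for f in line.split("\t")[1:]]
            elif line.startswith("!Sample_geo_accession"):
                accessions = [f.strip().strip('"') for f in line.split("\t")[1:]]
    if not table_lines:
        raise FormatError(f"{path}: no series_matrix_table found")
    from io import StringIO
    values = pd.read_csv(StringIO("\n".join(table_lines)), sep="\t", index_col=0)
    values.index = [str(i).strip('"') for i in values.index]
    values.columns = [str(c).strip('"') for c in values.columns]
    if not accessions:
        accessions = list(values.columns)
    sample_titles = dict(zip(accessions, titles)) if titles else {a: a for a in accessions}
    return values.astype(float), sample_titles
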