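"""Core containers and file formats for the biclustering benchmark pipeline.

An expression matrix is genes x samples (TSV, header row of sample ids,
first column of gene ids).  Sample-type labels come as a two-column TSV,
gene sets as Broad-dialect GMT, and bicluster results as a versioned JSON
exchange document so that results of external tools can be imported and
evaluated with the same machinery as the built-in methods.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("bicbench")

BICLUSTER_SCHEMA_VERSION = "1.0"


class ExpressionMatrix:
    """Real-valued genes x samples matrix with NaN marking missing entries.

    Backed by a float DataFrame (rows = genes, columns = samples); gene and
    sample identifiers are opaque, case-sensitive strings and must be unique
    within their axis.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if data.columns.has_duplicates:
            dup = data.columns[data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        self.data = data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)

    @classmethod
    def from_arrays(
        cls,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        values: np.ndarray,
    ) -> "ExpressionMatrix":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(gene_ids), len(sample_ids)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"({len(gene_ids)}, {len(sample_ids)})"
            )
        return cls(pd.DataFrame(values, index=list(gene_ids), columns=list(sample_ids)))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g, s = self.shape
        return f"ExpressionMatrix({g} genes x {s} samples, {self.n_missing} missing)"


class SampleTypeLabels:
    """Assignment of sample ids to type labels; `t` counts distinct labels."""

    def __init__(self, assignment: Mapping[str, str]):
        if not assignment:
            raise ValueError("empty label assignment")
        self.assignment = dict(assignment)

    @property
    def t(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def types(self) -> list[str]:
        """Distinct labels in first-appearance order."""
        seen: dict[str, None] = {}
        for lab in self.assignment.values():
            seen.setdefault(lab, None)
        return list(seen)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignment)

    def samples_of_type(self, label: str) -> frozenset[str]:
        return frozenset(s for s, l in self.assignment.items() if l == label)

    def __len__(self) -> int:
        return len(self.assignment)


@dataclass(frozen=True)
class Bicluster:
    """A submatrix: a subset of genes and a subset of samples, chosen jointly."""

    genes: frozenset[str]
    samples: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "genes", frozenset(self.genes))
        object.__setattr__(self, "samples", frozenset(self.samples))
        if not self.genes:
            raise ValueError("bicluster with empty gene set")
        if not self.samples:
            raise ValueError("bicluster with empty sample set")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass
class BiclusterSet:
    """Ordered bicluster list tagged with the producing method and parameters."""

    method_name: str
    parameters: dict = field(default_factory=dict)
    biclusters: list[Bicluster] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.biclusters)

    def __iter__(self):
        return iter(self.biclusters)

    def __len__(self) -> int:
        return len(self.biclusters)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


class GeneSetCollection:
    """Named gene sets (GMT); carries tissue-specific lists or GO-like categories."""

    def __init__(self, sets: Iterable[GeneSet]):
        self.sets: dict[str, GeneSet] = {}
        for s in sets:
            if s.name in self.sets:
                raise ValueError(f"duplicate gene-set name: {s.name!r}")
            self.sets[s.name] = s

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def union(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.sets.values():
            out |= s.genes
        return frozenset(out)


@dataclass
class BenchmarkConfig:
    """Evaluation settings: significance level, resample count, filter sizes."""

    alpha: float = 0.05
    n_resamples: int = 1000
    seed: int = 0
    min_genes: int = 10
    min_samples: int = 10
    top_n: int = 40

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def load_expression_matrix(path, missing_token: str = "NA") -> ExpressionMatrix:
    """Read a genes x samples TSV; `missing_token` entries become NaN.

    The header row carries sample ids (its first cell is ignored); each
    subsequent row starts with a gene id.  Duplicate ids and ragged rows are
    hard errors — never silently repaired.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln != ""]
    if not lines:
        raise ValueError(f"{path}: empty expression file")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    width = len(header)
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != width:
            raise ValueError(
                f"{path}: ragged row at line {lineno} "
                f"({len(fields)} fields, expected {width})"
            )
        gene_ids.append(fields[0])
        row = []
        for tok in fields[1:]:
            if tok == missing_token:
                row.append(np.nan)
            else:
                try:
                    row.append(float(tok))
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: non-numeric value {tok!r} at line {lineno}"
                    ) from exc
        rows.append(row)
    if len(set(sample_ids)) != len(sample_ids):
        dup = next(s for s in sample_ids if sample_ids.count(s) > 1)
        raise ValueError(f"{path}: duplicate sample id: {dup!r}")
    if len(set(gene_ids)) != len(gene_ids):
        seen: set[str] = set()
        dup = next(g for g in gene_ids if g in seen or seen.add(g))
        raise ValueError(f"{path}: duplicate gene id: {dup!r}")
    values = np.array(rows, dtype=float).reshape(len(gene_ids), len(sample_ids))
    return ExpressionMatrix.from_arrays(gene_ids, sample_ids, values)


def save_expression_matrix(
    m: ExpressionMatrix, path, missing_token: str = "NA"
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(m.sample_ids) + "\n")
        for gid, row in zip(m.gene_ids, m.values):
            toks = [missing_token if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(gid + "\t" + "\t".join(toks) + "\n")


def load_gene_sets(path) -> GeneSetCollection:
    """Read Broad-dialect GMT: name TAB description TAB member ids."""
    sets: list[GeneSet] = []
    names: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if ln == "":
                continue
            fields = ln.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: GMT line {lineno} has {len(fields)} fields, need >= 3"
                )
            name, desc = fields[0], fields[1]
            if name in names:
                raise ValueError(f"{path}: duplicate gene-set name {name!r} at line {lineno}")
            names.add(name)
            members = frozenset(g for g in fields[2:] if g != "")
            if not members:
                raise ValueError(f"{path}: gene set {name!r} at line {lineno} is empty")
            sets.append(GeneSet(name, desc, members))
    return GeneSetCollection(sets)


def save_gene_sets(coll: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in coll:
            fh.write("\t".join([s.name, s.description] + sorted(s.genes)) + "\n")


def load_sample_labels(path, skip_header: bool = False) -> SampleTypeLabels:
    """Read a two-column TSV of (sample id, type label)."""
    assignment: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if skip_header:
        lines = lines[1:]
    if not lines:
        raise ValueError(f"{path}: no sample labels found")
    for lineno, ln in enumerate(lines, start=1):
        fields = ln.split("\t")
        if len(fields) != 2:
            raise ValueError(f"{path}: line {lineno} has {len(fields)} fields, need 2")
        sid, lab = fields
        if sid in assignment:
            raise ValueError(f"{path}: duplicate sample id {sid!r} at line {lineno}")
        assignment[sid] = lab
    return SampleTypeLabels(assignment)


def save_sample_labels(labels: SampleTypeLabels, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, lab in labels.assignment.items():
            fh.write(f"{sid}\t{lab}\n")


def save_bicluster_set(bs: BiclusterSet, path) -> None:
    """Write the versioned JSON exchange document (arrays preserve order)."""
    doc = {
        "schema_version": BICLUSTER_SCHEMA_VERSION,
        "method_name": bs.method_name,
        "parameters": bs.parameters,
        "biclusters": [
            {"genes": sorted(b.genes), "samples": sorted(b.samples)}
            for b in bs.biclusters
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_bicluster_set(path) -> BiclusterSet:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    version = doc.get("schema_version")
    if version != BICLUSTER_SCHEMA_VERSION:
        raise ValueError(
            f"{path}: unknown bicluster schema version {version!r} "
            f"(expected {BICLUSTER_SCHEMA_VERSION!r})"
        )
    bics = [
        Bicluster(frozenset(entry["genes"]), frozenset(entry["samples"]))
        for entry in doc["biclusters"]
    ]
    return BiclusterSet(
        method_name=doc.get("method_name", ""),
        parameters=doc.get("parameters", {}),
        biclusters=bics,
    )


# ---------------------------------------------------------------------------
# Preprocessing filters
# ---------------------------------------------------------------------------


def drop_missing_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Exclude every gene with at least one missing entry (no imputation)."""
    keep = ~m.data.isna().any(axis=1)
    removed = [g for g, k in zip(m.gene_ids, keep) if not k]
    if removed:
        logger.info("drop_missing_genes: removed %d genes: %s%s",
                    len(removed), ", ".join(removed[:10]),
                    " ..." if len(removed) > 10 else "")
    if not keep.any():
        raise ValueError("all genes contain missing values; empty matrix")
    return ExpressionMatrix(m.data.loc[keep].copy())


def variance_filter(m: ExpressionMatrix, min_var: float = 1.0) -> ExpressionMatrix:
    """Discard genes whose across-sample variance is below `min_var`.

    Sample variance (ddof=1); "variance >= min_var keeps", preserving gene
    order.  Requires a matrix with no missing entries.
    """
    if m.n_missing:
        raise ValueError("variance_filter requires a matrix without missing entries")
    var = m.data.var(axis=1, ddof=1)
    keep = var >= min_var
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("variance_filter: removed %d genes below variance %g",
                    n_removed, min_var)
    if not keep.any():
        raise ValueError(f"variance filter at {min_var} removed every gene")
    return ExpressionMatrix(m.data.loc[keep].copy())
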