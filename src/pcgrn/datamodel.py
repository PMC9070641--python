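"""Tabular data structures and I/O for expression-based network inference.

This module holds the containers the rest of the pipeline operates on —
a genes × samples expression matrix with time-course metadata, a raw count
matrix, the regulator/structural gene catalog, and GMT-style named gene
sets used for per-process reporting — together with their tab-separated
readers/writers and the counts-per-million low-expression prefilter.

Expression values are assumed to be *already normalized* (e.g. TMM-scaled
log-CPM).  No normalization is applied or required here; correlations
downstream are scale-invariant per gene, but the caller owns any
between-sample normalization.

All tables are UTF-8, tab-separated; lines starting with ``#`` are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CountMatrix",
    "GeneCatalog",
    "ProcessMap",
    "ROLE_REGULATOR",
    "ROLE_STRUCTURAL",
    "ROLE_ALIASES",
    "read_expression_table",
    "write_expression_table",
    "read_count_table",
    "cpm_filter",
    "read_gene_catalog",
    "write_gene_catalog",
    "read_process_map",
    "write_process_map",
]

ROLE_REGULATOR = "regulator"
ROLE_STRUCTURAL = "structural"

#: Accepted spellings for the two gene roles in catalog files.
ROLE_ALIASES: Dict[str, str] = {
    "regulator": ROLE_REGULATOR,
    "regulatory": ROLE_REGULATOR,
    "tf": ROLE_REGULATOR,
    "transcription_factor": ROLE_REGULATOR,
    "structural": ROLE_STRUCTURAL,
    "structure": ROLE_STRUCTURAL,
    "target": ROLE_STRUCTURAL,
}

_META_COLUMNS = ("time_point", "replicate", "condition")

# default float format: enough digits for exact float64 round-trips in text
_FLOAT_FMT = "%.17g"


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: Set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Genes × samples matrix of finite normalized expression values.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns;
    ``sample_meta`` is indexed by sample id with columns ``time_point``,
    ``replicate`` and ``condition``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(list(self.values.index), "gene")
        _check_unique(list(self.values.columns), "sample")
        arr = self.values.to_numpy(dtype=float, copy=False)
        if not np.all(np.isfinite(arr)):
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )
        missing = [s for s in self.values.columns if s not in self.sample_meta.index]
        if missing:
            raise ValueError(f"samples missing metadata: {missing}")
        for col in ("time_point", "replicate"):
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample metadata lacks required column {col!r}")
        if "condition" not in self.sample_meta.columns:
            self.sample_meta = self.sample_meta.assign(condition="")
        # keep metadata aligned and restricted to the matrix's samples
        self.sample_meta = self.sample_meta.loc[list(self.values.columns)]

    @property
    def gene_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def vector(self, gene_id: str) -> np.ndarray:
        """Expression profile of one gene across all samples."""
        if gene_id not in self.values.index:
            raise KeyError(f"gene not in matrix: {gene_id!r}")
        return self.values.loc[gene_id].to_numpy(dtype=float)

    def submatrix(self, gene_ids: Sequence[str]) -> np.ndarray:
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return self.values.loc[list(gene_ids)].to_numpy(dtype=float)


@dataclass
class CountMatrix:
    """Genes × samples matrix of non-negative integer read counts."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(list(self.counts.index), "gene")
        _check_unique(list(self.counts.columns), "sample")
        arr = self.counts.to_numpy()
        if not np.all(np.isfinite(arr.astype(float))):
            raise ValueError("counts contain non-finite values")
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr.astype(float))):
            raise ValueError("counts must be integral")

    @property
    def gene_ids(self) -> List[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.counts.columns)


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, index_col=0)
    df.index = df.index.astype(str)
    return df


def _read_sample_meta(meta_path) -> pd.DataFrame:
    meta = pd.read_csv(meta_path, sep="\t", comment="#", dtype=str)
    if "sample_id" not in meta.columns:
        raise ValueError("sample metadata must have a 'sample_id' column")
    for col in ("time_point", "replicate"):
        if col not in meta.columns:
            raise ValueError(f"sample metadata must have a {col!r} column")
    if "condition" not in meta.columns:
        meta["condition"] = ""
    _check_unique(list(meta["sample_id"]), "sample")
    return meta.set_index("sample_id")[list(_META_COLUMNS)]


def read_expression_table(path, meta_path=None) -> ExpressionMatrix:
    """Read a genes × samples expression TSV (first column gene id).

    ``meta_path`` points to a TSV with columns sample_id, time_point,
    replicate and optionally condition.  If omitted, placeholder metadata is
    synthesized (each sample its own time point, replicate 1) — adequate only
    for exploratory use, since real time/replicate structure is then lost.
    Duplicated ids and non-numeric cells raise with the offender named.
    """
    raw = _read_table(path)
    dup = raw.index[raw.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene id: {dup[0]!r}")
    numeric = {}
    for col in raw.columns:
        conv = pd.to_numeric(raw[col], errors="coerce")
        bad = conv.index[conv.isna()]
        if len(bad):
            raise ValueError(
                f"non-numeric expression value at gene {bad[0]!r}, sample {col!r}: "
                f"{raw.loc[bad[0], col]!r}"
            )
        numeric[col] = conv.astype(float)
    values = pd.DataFrame(numeric, index=raw.index)
    if meta_path is not None:
        meta = _read_sample_meta(meta_path)
        missing = [s for s in values.columns if s not in meta.index]
        if missing:
            raise ValueError(f"samples missing metadata: {missing}")
    else:
        meta = pd.DataFrame(
            {
                "time_point": [str(i + 1) for i in range(values.shape[1])],
                "replicate": ["1"] * values.shape[1],
                "condition": [""] * values.shape[1],
            },
            index=values.columns,
        )
    return ExpressionMatrix(values=values, sample_meta=meta)


def write_expression_table(
    matrix: ExpressionMatrix, path, meta_path=None, float_fmt: str = _FLOAT_FMT
) -> None:
    """Write the expression TSV (and optionally the sample-metadata TSV)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        arr = matrix.values.to_numpy(dtype=float)
        for g, row in zip(matrix.gene_ids, arr):
            fh.write(g + "\t" + "\t".join(float_fmt % v for v in row) + "\n")
    if meta_path is not None:
        meta = matrix.sample_meta.reset_index(names="sample_id")
        meta.to_csv(meta_path, sep="\t", index=False)


def read_count_table(path) -> CountMatrix:
    """Read a genes × samples raw-count TSV."""
    raw = _read_table(path)
    dup = raw.index[raw.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene id: {dup[0]!r}")
    numeric = {}
    for col in raw.columns:
        conv = pd.to_numeric(raw[col], errors="coerce")
        bad = conv.index[conv.isna()]
        if len(bad):
            raise ValueError(
                f"non-numeric count at gene {bad[0]!r}, sample {col!r}"
            )
        numeric[col] = conv
    return CountMatrix(counts=pd.DataFrame(numeric, index=raw.index))


def cpm_filter(
    counts: CountMatrix, min_cpm: float = 1.0, min_samples: int = 1
) -> Tuple[List[str], List[str]]:
    """Partition genes by the counts-per-million low-expression filter.

    A gene is kept iff its CPM (count × 1e6 / library size) is ≥ ``min_cpm``
    in at least ``min_samples`` samples; the boundary is inclusive.  Returns
    ``(kept, dropped)`` gene-id lists in the input order; together they
    partition the input genes.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    arr = counts.counts.to_numpy(dtype=float)
    libsize = arr.sum(axis=0)
    for j, s in enumerate(libsize):
        if s <= 0:
            raise ValueError(
                f"sample {counts.sample_ids[j]!r} has zero library size"
            )
    cpm = arr * 1e6 / libsize[np.newaxis, :]
    ok = (cpm >= min_cpm).sum(axis=1) >= min_samples
    kept = [g for g, k in zip(counts.gene_ids, ok) if k]
    dropped = [g for g, k in zip(counts.gene_ids, ok) if not k]
    return kept, dropped


@dataclass
class GeneCatalog:
    """Partition of gene ids into regulator (TF) vs structural roles."""

    role_by_gene: Dict[str, str]
    family_by_gene: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, role in self.role_by_gene.items():
            if role not in (ROLE_REGULATOR, ROLE_STRUCTURAL):
                raise ValueError(
                    f"gene {g!r} has unknown role {role!r}; "
                    f"expected {ROLE_REGULATOR!r} or {ROLE_STRUCTURAL!r}"
                )
        for g in self.family_by_gene:
            if self.role_by_gene.get(g) != ROLE_REGULATOR:
                raise ValueError(
                    f"family label on non-regulator gene {g!r}"
                )

    @property
    def regulators(self) -> List[str]:
        return sorted(
            g for g, r in self.role_by_gene.items() if r == ROLE_REGULATOR
        )

    @property
    def structural(self) -> List[str]:
        return sorted(
            g for g, r in self.role_by_gene.items() if r == ROLE_STRUCTURAL
        )

    def __len__(self) -> int:
        return len(self.role_by_gene)


def read_gene_catalog(path) -> GeneCatalog:
    """Read a gene catalog TSV: gene_id, role[, family].

    Role tokens are matched case-insensitively against the alias table
    (``TF`` is a regulator alias, ``target`` a structural one).  A gene
    listed twice with conflicting roles is an error.
    """
    roles: Dict[str, str] = {}
    families: Dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() in ("gene_id", "gene"):  # optional header
                continue
            if len(parts) < 2:
                raise ValueError(
                    f"line {lineno}: expected gene_id<TAB>role, got {line!r}"
                )
            gene, token = parts[0], parts[1].strip().lower()
            if token not in ROLE_ALIASES:
                raise ValueError(
                    f"line {lineno}: unknown role {parts[1]!r} for gene "
                    f"{gene!r}; accepted tokens: {sorted(ROLE_ALIASES)}"
                )
            role = ROLE_ALIASES[token]
            if gene in roles and roles[gene] != role:
                raise ValueError(
                    f"gene {gene!r} listed with conflicting roles "
                    f"{roles[gene]!r} and {role!r}"
                )
            roles[gene] = role
            if len(parts) >= 3 and parts[2]:
                families[gene] = parts[2]
    return GeneCatalog(role_by_gene=roles, family_by_gene=families)


def write_gene_catalog(catalog: GeneCatalog, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("gene_id\trole\tfamily\n")
        for g in sorted(catalog.role_by_gene):
            fam = catalog.family_by_gene.get(g, "")
            fh.write(f"{g}\t{catalog.role_by_gene[g]}\t{fam}\n")


@dataclass
class ProcessMap:
    """Named gene sets (GMT-style), e.g. biological processes → member genes.

    Sets may overlap; every set has at least one member.
    """

    sets: Dict[str, Set[str]]
    descriptions: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"process {name!r} has no members")


def read_process_map(path) -> ProcessMap:
    """Read a GMT file: name<TAB>description<TAB>member1<TAB>member2..."""
    sets: Dict[str, Set[str]] = {}
    desc: Dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not any(p for p in parts[2:]):
                raise ValueError(
                    f"line {lineno}: process {parts[0]!r} has an empty member list"
                )
            name = parts[0]
            if name in sets:
                raise ValueError(f"duplicate process name {name!r}")
            sets[name] = {p for p in parts[2:] if p}
            desc[name] = parts[1]
    return ProcessMap(sets=sets, descriptions=desc)


def write_process_map(pmap: ProcessMap, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for name in sorted(pmap.sets):
            members = "\t".join(sorted(pmap.sets[name]))
            fh.write(f"{name}\t{pmap.descriptions.get(name, '')}\t{members}\n")
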