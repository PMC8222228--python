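"""Domain types and I/O for replicated RNA-seq time-course experiments.

The experimental unit is an *accession* (a plant line: domesticated ``D``,
wild ``W`` or cross ``C``) sequenced at an ordered grid of time points
(e.g. days after anthesis, DAA) with at least two biological replicates per
time.  Counts live in a genes x libraries matrix keyed to a design table;
gene annotations carry the gene-model length (needed for FPKM) and a
transcription-factor flag; GO annotations map genes to terms in the three
ontology aspects (BP, CC, MF).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

ACC_TYPES = ("D", "W", "C")
GO_ASPECTS = ("BP", "CC", "MF")
_GO_ID_RE = re.compile(r"^GO:\d{7}$")

__all__ = [
    "Design",
    "LibraryInfo",
    "CountMatrix",
    "GeneAnnotation",
    "GOMap",
    "FilterReport",
    "read_design",
    "read_count_table",
    "write_count_table",
    "read_count_mtx",
    "write_count_mtx",
    "read_annotation",
    "read_go_map",
    "filter_consistent_genes",
]


@dataclass(frozen=True)
class Design:
    """Time grid and accession roster of a time-course experiment.

    Parameters
    ----------
    times
        Strictly increasing time points (at least two).
    accessions
        ``(acc_key, acc_type, acc_name)`` triples; two-character keys,
        type in ``{"D", "W", "C"}``.
    replicates_per_point
        Biological replicates per accession x time combination (>= 2).
    """

    times: tuple[float, ...]
    accessions: tuple[tuple[str, str, str], ...]
    replicates_per_point: int = 2

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        object.__setattr__(self, "times", times)
        if len(times) < 2:
            raise ValueError("design needs at least 2 time points")
        if any(a >= b for a, b in zip(times, times[1:])):
            raise ValueError("time points must be strictly increasing")
        keys = [a[0] for a in self.accessions]
        if len(set(keys)) != len(keys):
            raise ValueError("accession keys must be unique")
        for key, typ, _name in self.accessions:
            if typ not in ACC_TYPES:
                raise ValueError(f"accession type {typ!r} not in {ACC_TYPES}")
        if self.replicates_per_point < 2:
            raise ValueError("at least two biological replicates per time are required")

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def n_intervals(self) -> int:
        return len(self.times) - 1

    @property
    def acc_keys(self) -> tuple[str, ...]:
        return tuple(a[0] for a in self.accessions)

    def acc_type(self, acc_key: str) -> str:
        for key, typ, _ in self.accessions:
            if key == acc_key:
                return typ
        raise KeyError(f"unknown accession key {acc_key!r}")


@dataclass(frozen=True)
class LibraryInfo:
    """One sequencing library: which accession, time and replicate it is."""

    library_id: str
    acc_key: str
    time: float
    replicate: int
    mapped_reads: float | None = None

    def __post_init__(self) -> None:
        if self.mapped_reads is not None and self.mapped_reads <= 0:
            raise ValueError(f"library {self.library_id}: mapped_reads must be positive")


@dataclass
class CountMatrix:
    """Genes x libraries read counts bound to the experimental design.

    ``counts`` is a DataFrame indexed by gene id with one column per
    library id, in the canonical (acc_key, time, replicate) order.
    """

    design: Design
    libraries: list[LibraryInfo]
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        lib_ids = [lib.library_id for lib in self.libraries]
        if len(set(lib_ids)) != len(lib_ids):
            raise ValueError("duplicated library ids")
        seen = set()
        for lib in self.libraries:
            key = (lib.acc_key, lib.time, lib.replicate)
            if key in seen:
                raise ValueError(f"duplicated (acc_key, time, replicate): {key}")
            seen.add(key)
        if list(self.counts.columns) != lib_ids:
            self.counts = self.counts[lib_ids]
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicated gene id: {dup!r}")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("negative read counts")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    def lib_sizes(self) -> pd.Series:
        """Mapped reads per library; column sums where not supplied."""
        sizes = {}
        for lib in self.libraries:
            if lib.mapped_reads is not None:
                sizes[lib.library_id] = float(lib.mapped_reads)
            else:
                sizes[lib.library_id] = float(self.counts[lib.library_id].sum())
        return pd.Series(sizes)[self.counts.columns]

    def libraries_for(self, acc_key: str, time: float | None = None) -> list[LibraryInfo]:
        if acc_key not in self.design.acc_keys:
            raise KeyError(f"unknown accession key {acc_key!r}")
        out = [lib for lib in self.libraries if lib.acc_key == acc_key]
        if time is not None:
            out = [lib for lib in out if lib.time == float(time)]
            if not out:
                raise KeyError(f"no libraries for accession {acc_key!r} at time {time}")
        return out

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.design, self.libraries, self.counts.loc[list(gene_ids)])


@dataclass
class GeneAnnotation:
    """Per-gene annotation: description, gene-model length (bp), TF flag."""

    table: pd.DataFrame  # index: gene id; columns: descr, length_bp, is_tf

    def __post_init__(self) -> None:
        required = {"descr", "length_bp", "is_tf"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise ValueError("duplicated gene id in annotation")
        if (self.table["length_bp"] <= 0).any():
            bad = self.table.index[self.table["length_bp"] <= 0][0]
            raise ValueError(f"non-positive gene length for {bad!r}")

    def lengths_for(self, gene_ids: Sequence[str]) -> pd.Series:
        missing = [g for g in gene_ids if g not in self.table.index]
        if missing:
            raise KeyError(f"genes without annotated length: {missing[:10]}")
        return self.table.loc[list(gene_ids), "length_bp"].astype(float)


@dataclass
class GOMap:
    """Gene -> GO term mapping with aspect (BP/CC/MF) and description."""

    table: pd.DataFrame  # columns: gene_id, go_id, aspect, descr

    def __post_init__(self) -> None:
        required = {"gene_id", "go_id", "aspect", "descr"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"GO map missing columns: {sorted(missing)}")
        bad_ids = ~self.table["go_id"].map(lambda s: bool(_GO_ID_RE.match(str(s))))
        if bad_ids.any():
            raise ValueError(
                f"malformed GO ids: {sorted(self.table.loc[bad_ids, 'go_id'].unique())[:5]}"
            )
        bad_asp = ~self.table["aspect"].isin(GO_ASPECTS)
        if bad_asp.any():
            raise ValueError(
                f"GO aspect must be one of {GO_ASPECTS}; got "
                f"{sorted(self.table.loc[bad_asp, 'aspect'].unique())}"
            )
        self.table = self.table.drop_duplicates(subset=["gene_id", "go_id"]).reset_index(drop=True)

    def genes_for(self, term: str) -> set[str]:
        return set(self.table.loc[self.table["go_id"] == term, "gene_id"])

    def terms(self, aspect: str | None = None) -> pd.DataFrame:
        t = self.table
        if aspect is not None:
            t = t[t["aspect"] == aspect]
        return t.drop_duplicates(subset="go_id")[["go_id", "aspect", "descr"]]


@dataclass(frozen=True)
class FilterReport:
    """Outcome of the cross-accession consistency filter."""

    kept: int
    total: int

    @property
    def percentage(self) -> float:
        """Percentage kept, rounded to two decimals (e.g. 83.45)."""
        if self.total == 0:
            return 0.0
        return round(100.0 * self.kept / self.total, 2)

    def __str__(self) -> str:
        return f"{self.kept} of {self.total} genes kept ({self.percentage:.2f}%)"


# ---------------------------------------------------------------------------
# readers / writers


def read_design(path: str | Path) -> tuple[Design, list[LibraryInfo]]:
    """Read the library-design TSV.

    Columns: library_id, acc_key, acc_type, time, replicate and optionally
    mapped_reads and acc_name.
    """
    df = pd.read_csv(path, sep="\t", dtype={"library_id": str, "acc_key": str})
    required = {"library_id", "acc_key", "acc_type", "time", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design file missing columns: {sorted(missing)}")
    times = tuple(sorted(df["time"].astype(float).unique()))
    accs = []
    for key, sub in df.groupby("acc_key", sort=True):
        typ = sub["acc_type"].iloc[0]
        name = str(sub["acc_name"].iloc[0]) if "acc_name" in sub.columns else str(key)
        accs.append((str(key), str(typ), name))
    reps = int(df.groupby(["acc_key", "time"]).size().min())
    design = Design(times=times, accessions=tuple(accs), replicates_per_point=max(2, reps))
    libs = []
    for _, row in df.iterrows():
        mapped = float(row["mapped_reads"]) if "mapped_reads" in df.columns and pd.notna(row.get("mapped_reads")) else None
        libs.append(
            LibraryInfo(
                library_id=str(row["library_id"]),
                acc_key=str(row["acc_key"]),
                time=float(row["time"]),
                replicate=int(row["replicate"]),
                mapped_reads=mapped,
            )
        )
    libs.sort(key=lambda l: (l.acc_key, l.time, l.replicate))
    return design, libs


def _check_integer_counts(df: pd.DataFrame) -> pd.DataFrame:
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("non-numeric count cell")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite count cell")
    if np.any(arr != np.floor(arr)):
        i, j = np.argwhere(arr != np.floor(arr))[0]
        raise ValueError(
            f"non-integer count {arr[i, j]!r} for gene {df.index[i]!r}, "
            f"library {df.columns[j]!r}"
        )
    return df.astype(np.int64)


def read_count_table(path: str | Path, design_path: str | Path) -> CountMatrix:
    """Read a delimited genes x libraries count table plus its design.

    The count file header names the libraries; the first column holds gene
    ids (kept verbatim as strings, even if numeric-looking).  Every count
    column must appear in the design file.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicated gene id: {dup!r}")
    df = _check_integer_counts(df)
    design, libs = read_design(design_path)
    known = {l.library_id for l in libs}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise ValueError(f"libraries missing from design file: {unknown}")
    libs = [l for l in libs if l.library_id in set(df.columns)]
    return CountMatrix(design=design, libraries=libs, counts=df)


def write_count_table(cm: CountMatrix, path: str | Path, design_path: str | Path | None = None) -> None:
    """Write counts as TSV/CSV; optionally also the design table."""
    sep = "," if str(path).endswith(".csv") else "\t"
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep=sep)
    if design_path is not None:
        write_design(cm, design_path)


def write_design(cm: CountMatrix, path: str | Path) -> None:
    rows = []
    for lib in cm.libraries:
        rows.append(
            {
                "library_id": lib.library_id,
                "acc_key": lib.acc_key,
                "acc_type": cm.design.acc_type(lib.acc_key),
                "time": lib.time,
                "replicate": lib.replicate,
                "mapped_reads": lib.mapped_reads if lib.mapped_reads is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_count_mtx(mtx_path: str | Path, genes_path: str | Path, libs_path: str | Path, design_path: str | Path) -> CountMatrix:
    """Read MatrixMarket counts with sidecar gene-id and library-id files."""
    raw = mmread(str(mtx_path))
    mat = raw.toarray() if hasattr(raw, "toarray") else np.asarray(raw)
    genes = [line.strip() for line in Path(genes_path).read_text().splitlines() if line.strip()]
    lib_ids = [line.strip() for line in Path(libs_path).read_text().splitlines() if line.strip()]
    df = pd.DataFrame(mat, index=genes, columns=lib_ids)
    df.index.name = "gene_id"
    df = _check_integer_counts(df)
    design, libs = read_design(design_path)
    known = {l.library_id for l in libs}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise ValueError(f"libraries missing from design file: {unknown}")
    libs = [l for l in libs if l.library_id in set(df.columns)]
    return CountMatrix(design=design, libraries=libs, counts=df)


def write_count_mtx(cm: CountMatrix, mtx_path: str | Path, genes_path: str | Path, libs_path: str | Path) -> None:
    mmwrite(str(mtx_path), csr_matrix(cm.counts.to_numpy()))
    Path(genes_path).write_text("\n".join(cm.gene_ids) + "\n")
    Path(libs_path).write_text("\n".join(cm.counts.columns) + "\n")


def read_annotation(path: str | Path) -> GeneAnnotation:
    """Read a gene-annotation TSV with columns id, descr, length_bp, is_tf."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    required = {"id", "descr", "length_bp", "is_tf"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation file missing columns: {sorted(missing)}")
    df["is_tf"] = df["is_tf"].map(
        lambda v: str(v).strip().lower() in {"true", "1", "t", "yes"}
    )
    df["descr"] = df["descr"].fillna("").astype(str)
    return GeneAnnotation(df.set_index("id")[["descr", "length_bp", "is_tf"]])


_GAF_ASPECT = {"P": "BP", "C": "CC", "F": "MF"}


def read_go_map(path: str | Path) -> GOMap:
    """Read gene->GO annotations from GAF 2.x or a four-column TSV.

    GAF rows use column 2 (gene id), 5 (GO id) and 9 (aspect P/F/C).  The
    TSV alternative has columns gene_id, go_id, aspect, descr.
    """
    text = Path(path).read_text()
    lines = [l for l in text.splitlines() if l and not l.startswith("!")]
    if text.startswith("!gaf-version") or (lines and len(lines[0].split("\t")) >= 15):
        rows = []
        for line in lines:
            cols = line.split("\t")
            aspect = _GAF_ASPECT.get(cols[8])
            if aspect is None:
                raise ValueError(f"bad GAF aspect {cols[8]!r}")
            rows.append({"gene_id": cols[1], "go_id": cols[4], "aspect": aspect, "descr": ""})
        return GOMap(pd.DataFrame(rows))
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
    if "descr" not in df.columns:
        df["descr"] = ""
    df["descr"] = df["descr"].fillna("")
    return GOMap(df[["gene_id", "go_id", "aspect", "descr"]])


# ---------------------------------------------------------------------------
# consistency filter


def filter_consistent_genes(cm: CountMatrix, min_total: int = 1) -> tuple[CountMatrix, FilterReport]:
    """Keep genes expressed consistently across *every* accession.

    A gene passes if its summed raw counts over the libraries of each
    accession reach ``min_total`` (default 1) in all accessions.  Filtering
    twice with the same threshold is a no-op.
    """
    if min_total < 1:
        raise ValueError("min_total must be ≥ 1")
    keep = np.ones(cm.n_genes, dtype=bool)
    for acc in cm.design.acc_keys:
        cols = [l.library_id for l in cm.libraries if l.acc_key == acc]
        if not cols:
            continue
        keep &= cm.counts[cols].sum(axis=1).to_numpy() >= min_total
    report = FilterReport(kept=int(keep.sum()), total=cm.n_genes)
    if report.kept == 0:
        import warnings

        warnings.warn("consistency filter removed every gene", stacklevel=2)
    filtered = CountMatrix(cm.design, cm.libraries, cm.counts.loc[keep])
    return filtered, report
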