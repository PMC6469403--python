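"""Readers and writers for the tabular formats the pipeline touches.

All internal coordinates are 0-based half-open; GFF3 (1-based closed) is
converted at the boundary.  The canonical on-disk dialect is TSV with a
header line, ``#`` comments and no quoting.  Genotypes are unphased string
codes ``{AA, AB, BB, NA}``.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneTable",
    "HitTable",
    "GenotypeMatrix",
    "CountsMatrix",
    "ProgenyTable",
    "read_gene_table",
    "write_gene_table",
    "read_hits",
    "write_hits",
    "read_genotypes",
    "write_genotypes",
    "read_counts",
    "write_counts",
    "read_progeny",
    "write_progeny",
    "write_bed",
    "write_tsv",
]

GENOTYPE_CODES = ("AA", "AB", "BB", "NA")

HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "pct_identity",
    "aln_length",
    "mismatches",
    "gap_opens",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


@dataclass(frozen=True)
class GeneTable:
    """Per-species table of gene coordinates (0-based half-open)."""

    species_id: str
    records: pd.DataFrame  # columns: gene_id, chromosome, start, end, strand

    def __post_init__(self) -> None:
        df = self.records
        required = ["gene_id", "chromosome", "start", "end", "strand"]
        if list(df.columns) != required:
            raise ValueError(f"GeneTable columns must be {required}")
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id {dup!r} in {self.species_id}")
        if len(df) and not (df["start"] < df["end"]).all():
            bad = df.index[~(df["start"] < df["end"])][0]
            raise ValueError(f"start >= end at row {bad}")
        if len(df) and (df["chromosome"].astype(str) == "").any():
            raise ValueError("empty chromosome name")

    def __len__(self) -> int:
        return len(self.records)

    def chromosomes(self) -> list[str]:
        return sorted(self.records["chromosome"].unique())

    def gene_chromosome(self) -> dict[str, str]:
        return dict(zip(self.records["gene_id"], self.records["chromosome"]))


@dataclass(frozen=True)
class HitTable:
    """Pairwise similarity hits, 12-column BLAST outfmt-6 dialect."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.rows.columns) != HIT_COLUMNS:
            raise ValueError(f"HitTable columns must be {HIT_COLUMNS}")
        if len(self.rows):
            if (self.rows["evalue"] < 0).any():
                raise ValueError("negative evalue")
            if not np.isfinite(self.rows["bitscore"]).all():
                raise ValueError("non-finite bitscore")
            ids = self.rows[["query_id", "subject_id"]].astype(str)
            if (ids == "").any().any():
                raise ValueError("empty query/subject id")

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class GenotypeMatrix:
    """Lines x markers genotype codes with a marker -> locus map."""

    line_ids: tuple[str, ...]
    marker_ids: tuple[str, ...]
    codes: np.ndarray  # dtype <U2, shape (n_lines, n_markers)
    marker_map: dict[str, tuple[str, float]]  # marker -> (chromosome, position)

    def __post_init__(self) -> None:
        if self.codes.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError("codes shape does not match id lists")
        bad = set(np.unique(self.codes)) - set(GENOTYPE_CODES)
        if bad:
            raise ValueError(f"unknown genotype codes {sorted(bad)}")
        missing = [m for m in self.marker_ids if m not in self.marker_map]
        if missing:
            raise ValueError(f"markers absent from marker_map: {missing[:5]}")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def marker_chromosomes(self) -> np.ndarray:
        return np.array([self.marker_map[m][0] for m in self.marker_ids])

    def select_markers(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        ids = tuple(self.marker_ids[i] for i in keep)
        return GenotypeMatrix(
            self.line_ids,
            ids,
            self.codes[:, keep],
            {m: self.marker_map[m] for m in ids},
        )


@dataclass(frozen=True)
class CountsMatrix:
    """Gene x sample nonnegative integer counts plus gene -> chromosome map."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray  # int, shape (n_genes, n_samples)
    gene_chrom: dict[str, str]

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match id lists")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    def chromosomes(self) -> np.ndarray:
        return np.array([self.gene_chrom[g] for g in self.gene_ids])


@dataclass(frozen=True)
class ProgenyTable:
    """Per-mother progeny counts by sex under two experimental conditions."""

    rows: pd.DataFrame  # mother_id, condition, males, females, hermaphrodites

    def __post_init__(self) -> None:
        required = ["mother_id", "condition", "males", "females", "hermaphrodites"]
        if list(self.rows.columns) != required:
            raise ValueError(f"ProgenyTable columns must be {required}")
        counts = self.rows[["males", "females", "hermaphrodites"]]
        if len(self.rows) and (counts < 0).any().any():
            raise ValueError("negative progeny counts")
        bad = set(self.rows["condition"].unique()) - {"RNAi", "Control"}
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.rows)


# ---------------------------------------------------------------------------
# gene tables


def read_gene_table(
    path: str | Path, dialect: Literal["gff3_genes", "tsv"] = "tsv",
    species_id: str | None = None,
) -> GeneTable:
    """Read a gene coordinate table from GFF3 (``type=gene`` rows only) or TSV.

    GFF3 1-based closed intervals are converted to 0-based half-open.  Rows
    are returned sorted by (chromosome, start).
    """
    path = Path(path)
    sid = species_id if species_id is not None else path.stem
    if dialect == "tsv":
        df = _read_tsv(path)
        if df.empty:
            df = pd.DataFrame(
                columns=["gene_id", "chromosome", "start", "end", "strand"]
            )
        df = df.astype({"start": int, "end": int})
    elif dialect == "gff3_genes":
        records = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 9:
                    raise ValueError(
                        f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}"
                    )
                if fields[2] != "gene":
                    continue
                try:
                    start1, end1 = int(fields[3]), int(fields[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
                if end1 < start1:
                    raise ValueError(f"{path}:{lineno}: end < start")
                attrs = dict(
                    kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                )
                gene_id = attrs.get("ID")
                if not gene_id:
                    raise ValueError(f"{path}:{lineno}: gene row without ID")
                strand = fields[6] if fields[6] in ("+", "-", ".") else "."
                records.append((gene_id, fields[0], start1 - 1, end1, strand))
        df = pd.DataFrame(
            records, columns=["gene_id", "chromosome", "start", "end", "strand"]
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = df.sort_values(["chromosome", "start"], kind="stable").reset_index(drop=True)
    return GeneTable(sid, df[["gene_id", "chromosome", "start", "end", "strand"]])


def write_gene_table(gt: GeneTable, path: str | Path) -> None:
    write_tsv(gt.records, path)


# ---------------------------------------------------------------------------
# hit tables


def read_hits(path: str | Path) -> HitTable:
    """Read a 12-column tabular hit file (BLAST outfmt-6 dialect)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 columns, got {len(fields)}"
                )
            rows.append(fields)
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    if len(df):
        df = df.astype(
            {
                "pct_identity": float,
                "aln_length": int,
                "mismatches": int,
                "gap_opens": int,
                "qstart": int,
                "qend": int,
                "sstart": int,
                "send": int,
                "evalue": float,
                "bitscore": float,
            }
        )
    else:
        df = _empty_hits()
    return HitTable(df)


def _empty_hits() -> pd.DataFrame:
    df = pd.DataFrame(columns=HIT_COLUMNS)
    return df.astype(
        {c: float for c in ("pct_identity", "evalue", "bitscore")}
        | {c: int for c in ("aln_length", "mismatches", "gap_opens",
                            "qstart", "qend", "sstart", "send")}
        | {"query_id": str, "subject_id": str}
    )


def write_hits(ht: HitTable, path: str | Path) -> None:
    ht.rows.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# genotype matrices

_VCF_GT = {"0/0": "AA", "0/1": "AB", "1/0": "AB", "1/1": "BB", "./.": "NA"}


def read_genotypes(
    path: str | Path, dialect: Literal["csv", "vcf_gt"] = "csv"
) -> GenotypeMatrix:
    """Read a genotype matrix.

    ``csv``: first column ``line_id``, remaining columns one marker each;
    a companion marker map is embedded as ``#map marker chrom pos`` header
    comments.  ``vcf_gt``: minimal VCF with GT-only FORMAT; samples are
    lines, records are markers (``0/0``→AA, ``0/1``/``1/0``→AB, ``1/1``→BB,
    ``./.``→NA).
    """
    path = Path(path)
    if dialect == "csv":
        marker_map: dict[str, tuple[str, float]] = {}
        data_lines = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#map\t"):
                    _, marker, chrom, pos = line.split("\t")
                    marker_map[marker] = (chrom, float(pos))
                elif line.startswith("#") or not line:
                    continue
                else:
                    data_lines.append(line)
        header = data_lines[0].split(",")
        if header[0] != "line_id":
            raise ValueError(f"{path}: first column must be line_id")
        marker_ids = tuple(header[1:])
        line_ids = []
        rows = []
        for lineno, line in enumerate(data_lines[1:], 2):
            fields = line.split(",")
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}: ragged row at data line {lineno}: "
                    f"{len(fields)} fields, expected {len(header)}"
                )
            line_ids.append(fields[0])
            rows.append(fields[1:])
        codes = np.array(rows, dtype="<U2") if rows else np.empty(
            (0, len(marker_ids)), dtype="<U2"
        )
        bad = set(np.unique(codes)) - set(GENOTYPE_CODES) if codes.size else set()
        if bad:
            raise ValueError(f"{path}: unknown genotype token(s) {sorted(bad)}")
        if not marker_map:
            marker_map = {m: ("unknown", float(i)) for i, m in enumerate(marker_ids)}
        return GenotypeMatrix(tuple(line_ids), marker_ids, codes, marker_map)

    if dialect == "vcf_gt":
        marker_ids_l: list[str] = []
        marker_map = {}
        geno_rows = []
        samples: tuple[str, ...] = ()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if line.startswith("##") or not line:
                    continue
                if line.startswith("#CHROM"):
                    samples = tuple(line.split("\t")[9:])
                    continue
                fields = line.split("\t")
                if len(fields) != 9 + len(samples):
                    raise ValueError(f"{path}:{lineno}: ragged VCF row")
                chrom, pos, vid = fields[0], fields[1], fields[2]
                gts = []
                for tok in fields[9:]:
                    gt = tok.split(":")[0]
                    if gt not in _VCF_GT:
                        raise ValueError(
                            f"{path}:{lineno}: unknown genotype token {gt!r}"
                        )
                    gts.append(_VCF_GT[gt])
                marker_ids_l.append(vid)
                marker_map[vid] = (chrom, float(pos))
                geno_rows.append(gts)
        codes = (
            np.array(geno_rows, dtype="<U2").T
            if geno_rows
            else np.empty((len(samples), 0), dtype="<U2")
        )
        return GenotypeMatrix(samples, tuple(marker_ids_l), codes, marker_map)

    raise ValueError(f"unknown dialect {dialect!r}")


def write_genotypes(
    gm: GenotypeMatrix, path: str | Path, dialect: Literal["csv", "vcf_gt"] = "csv"
) -> None:
    path = Path(path)
    if dialect == "csv":
        with open(path, "w") as fh:
            for m in gm.marker_ids:
                chrom, pos = gm.marker_map[m]
                fh.write(f"#map\t{m}\t{chrom}\t{pos:g}\n")
            fh.write("line_id," + ",".join(gm.marker_ids) + "\n")
            for i, lid in enumerate(gm.line_ids):
                fh.write(lid + "," + ",".join(gm.codes[i]) + "\n")
    elif dialect == "vcf_gt":
        inv = {"AA": "0/0", "AB": "0/1", "BB": "1/1", "NA": "./."}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(gm.line_ids)
                + "\n"
            )
            for j, m in enumerate(gm.marker_ids):
                chrom, pos = gm.marker_map[m]
                gts = "\t".join(inv[g] for g in gm.codes[:, j])
                fh.write(f"{chrom}\t{pos:g}\t{m}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# counts, progeny, generic TSV/BED


def read_counts(path: str | Path) -> CountsMatrix:
    """Read a gene x sample counts TSV with a ``chromosome`` column."""
    df = _read_tsv(path)
    if "gene_id" not in df.columns or "chromosome" not in df.columns:
        raise ValueError(f"{path}: counts TSV needs gene_id and chromosome columns")
    sample_ids = tuple(c for c in df.columns if c not in ("gene_id", "chromosome"))
    counts = df[list(sample_ids)].to_numpy()
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.all(counts == np.round(counts)):
            raise ValueError(f"{path}: non-integer counts")
        counts = counts.astype(np.int64)
    return CountsMatrix(
        tuple(df["gene_id"].astype(str)),
        sample_ids,
        counts,
        dict(zip(df["gene_id"].astype(str), df["chromosome"].astype(str))),
    )


def write_counts(cm: CountsMatrix, path: str | Path) -> None:
    df = pd.DataFrame(cm.counts, columns=list(cm.sample_ids))
    df.insert(0, "chromosome", [cm.gene_chrom[g] for g in cm.gene_ids])
    df.insert(0, "gene_id", list(cm.gene_ids))
    write_tsv(df, path)


def read_progeny(path: str | Path) -> ProgenyTable:
    df = _read_tsv(path)
    df = df.astype({"males": int, "females": int, "hermaphrodites": int})
    df["mother_id"] = df["mother_id"].astype(str)
    return ProgenyTable(
        df[["mother_id", "condition", "males", "females", "hermaphrodites"]]
    )


def write_progeny(pt: ProgenyTable, path: str | Path) -> None:
    write_tsv(pt.rows, path)


def write_bed(
    blocks: Iterable[tuple[str, int, int, str]] | pd.DataFrame,
    path: str | Path,
) -> None:
    """Write (chrom, start, end, name) blocks as sorted BED6.

    Coordinates are 0-based half-open.  Overlapping blocks within one
    (chromosome, name) track are rejected.
    """
    if isinstance(blocks, pd.DataFrame):
        rows = [tuple(r) for r in blocks.itertuples(index=False)]
    else:
        rows = [tuple(b) for b in blocks]
    rows.sort(key=lambda r: (r[0], int(r[1]), int(r[2])))
    last_end: dict[tuple[str, str], int] = {}
    for chrom, start, end, name in rows:
        key = (chrom, name)
        if int(start) < last_end.get(key, -1):
            raise ValueError(f"overlapping BED blocks on {chrom} track {name}")
        last_end[key] = int(end)
    with open(path, "w") as fh:
        for chrom, start, end, name in rows:
            fh.write(f"{chrom}\t{int(start)}\t{int(end)}\t{name}\t0\t.\n")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Canonical TSV: header line, no index, no quoting."""
    df.to_csv(path, sep="\t", index=False)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        text = "".join(line for line in fh if not line.startswith("#"))
    if not text.strip():
        return pd.DataFrame()
    return pd.read_csv(_io.StringIO(text), sep="\t")
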