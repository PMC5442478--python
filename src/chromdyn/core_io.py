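"""Coordinate conventions, containers and standard-format I/O.

All genomic intervals in this package are 0-based half-open ``[start, end)``,
in BED files as well as in memory.  Strand-aware quantities ("distance
downstream of the TSS") are oriented so that positive distances always point
downstream of transcription, on both strands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STRANDS = ("+", "-")

#: Promoter half-width in bp: the promoter is TSS +- this value.  The same
#: window is used for chromatin-state classification, nucleosome assignment
#: and CRR compartment analysis so the definitions cannot drift apart.
DEFAULT_PROMOTER_HALFWIDTH = 500


class BedParseError(ValueError):
    """Raised for a malformed BED line; message names the line number."""


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names and lengths of the (synthetic or real) genome."""

    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("genome must have at least one chromosome")
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths


@dataclass
class ReadTable:
    """Uniquely-mapped single-end read intervals with strand.

    ``reads`` has columns ``chrom, start, end, strand`` sorted by
    (chrom, start); ``total_mapped`` always equals the number of records and
    is the depth-normalisation denominator throughout the package.
    """

    reads: pd.DataFrame
    n_rejected: int = 0

    COLUMNS = ("chrom", "start", "end", "strand")

    def __post_init__(self) -> None:
        df = self.reads
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"ReadTable missing columns: {sorted(missing)}")
        df = df.loc[:, list(self.COLUMNS)]
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        self.reads = df

    @property
    def total_mapped(self) -> int:
        return int(len(self.reads))

    def __len__(self) -> int:
        return len(self.reads)

    def by_chrom(self) -> dict[str, pd.DataFrame]:
        return {str(c): g for c, g in self.reads.groupby("chrom", sort=True)}

    @classmethod
    def from_arrays(cls, chrom, start, end, strand) -> "ReadTable":
        return cls(
            pd.DataFrame(
                {
                    "chrom": np.asarray(chrom, dtype=object),
                    "start": np.asarray(start, dtype=np.int64),
                    "end": np.asarray(end, dtype=np.int64),
                    "strand": np.asarray(strand, dtype=object),
                }
            )
        )

    @classmethod
    def empty(cls) -> "ReadTable":
        return cls.from_arrays([], [], [], [])

    def concat(self, other: "ReadTable") -> "ReadTable":
        return ReadTable(pd.concat([self.reads, other.reads], ignore_index=True))


@dataclass
class GeneAnnotation:
    """Gene models: per gene id, chrom, strand, tss and tes coordinates.

    The TSS is strand-aware: for ``-`` strand genes it is the larger
    coordinate and downstream runs toward smaller coordinates.  ``genes``
    columns: ``gene_id, chrom, strand, tss, tes``.
    """

    genes: pd.DataFrame
    promoter_halfwidth: int = DEFAULT_PROMOTER_HALFWIDTH

    COLUMNS = ("gene_id", "chrom", "strand", "tss", "tes")

    def __post_init__(self) -> None:
        df = self.genes
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"GeneAnnotation missing columns: {sorted(missing)}")
        if df["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids in annotation")
        bad = ~df["strand"].isin(STRANDS)
        if bad.any():
            raise ValueError(f"invalid strand values: {df.loc[bad, 'strand'].unique()}")
        self.genes = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.genes)

    def promoters(self) -> pd.DataFrame:
        """Promoter intervals TSS +- halfwidth, clipped at 0, half-open."""
        g = self.genes
        start = np.maximum(g["tss"].to_numpy() - self.promoter_halfwidth, 0)
        end = g["tss"].to_numpy() + self.promoter_halfwidth + 1
        return pd.DataFrame(
            {
                "gene_id": g["gene_id"],
                "chrom": g["chrom"],
                "start": start,
                "end": end,
                "strand": g["strand"],
            }
        )

    def gene_bodies(self) -> pd.DataFrame:
        g = self.genes
        start = np.minimum(g["tss"], g["tes"])
        end = np.maximum(g["tss"], g["tes"]) + 1
        return pd.DataFrame(
            {"gene_id": g["gene_id"], "chrom": g["chrom"], "start": start, "end": end}
        )

    def tss_relative(self, chrom: str, positions: np.ndarray, gene_row) -> np.ndarray:
        """Strand-oriented distance of positions to one gene's TSS."""
        d = np.asarray(positions) - int(gene_row.tss)
        return d if gene_row.strand == "+" else -d


@dataclass
class ExpressionTable:
    """Per-gene expression in two conditions with DEG labels.

    Columns: ``gene_id, expr_a, expr_b, log2_fc, deg_label`` with
    ``deg_label`` in {"up", "down", "none"}.  Labels come from an upstream
    differential-expression analysis and are taken as given.
    """

    table: pd.DataFrame

    COLUMNS = ("gene_id", "expr_a", "expr_b", "log2_fc", "deg_label")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"ExpressionTable missing columns: {sorted(missing)}")
        bad = ~self.table["deg_label"].isin(("up", "down", "none"))
        if bad.any():
            raise ValueError("deg_label must be 'up', 'down' or 'none'")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


def read_bed(path) -> ReadTable:
    """Parse a BED3+ file into a :class:`ReadTable`.

    Strand is taken from column 6 when present, else defaults to ``+``.
    Records with ``start >= end`` are rejected and counted in
    ``n_rejected``; structurally malformed lines raise
    :class:`BedParseError` naming the line number.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    strands: list[str] = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: expected >=3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in STRANDS else "+"
            if start < 0 or start >= end:
                n_rejected += 1
                continue
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
            strands.append(strand)
    rt = ReadTable.from_arrays(chroms, starts, ends, strands)
    rt.n_rejected = n_rejected
    return rt


def write_bed(table: ReadTable | pd.DataFrame, path, score=None) -> None:
    """Write intervals as BED6 (name ".", score 0 unless given)."""
    df = table.reads if isinstance(table, ReadTable) else table
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": ".",
            "score": df[score] if score is not None and score in df else 0,
            "strand": df["strand"] if "strand" in df else "+",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(track: dict[str, np.ndarray] | pd.DataFrame, path, bin_size: int = 1) -> None:
    """Write per-bin values as bedGraph, merging adjacent equal-valued bins.

    ``track`` maps chrom -> value per bin of width ``bin_size`` (bin i covers
    ``[i*bin_size, (i+1)*bin_size)``), or is a DataFrame with columns
    chrom/start/end/value already in interval form.
    """
    lines: list[str] = []
    if isinstance(track, pd.DataFrame):
        it = (
            (r.chrom, int(r.start), int(r.end), float(r.value))
            for r in track.itertuples()
        )
        for chrom, start, end, value in _merge_equal(it):
            lines.append(f"{chrom}\t{start}\t{end}\t{value:g}")
    else:
        for chrom in track:
            values = np.asarray(track[chrom], dtype=float)
            if not np.all(np.isfinite(values)):
                raise ValueError("bedGraph values must be finite")
            it = (
                (chrom, i * bin_size, (i + 1) * bin_size, float(v))
                for i, v in enumerate(values)
            )
            for c, start, end, value in _merge_equal(it):
                lines.append(f"{c}\t{start}\t{end}\t{value:g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def _merge_equal(intervals):
    cur = None
    for chrom, start, end, value in intervals:
        if cur is not None and cur[0] == chrom and cur[2] == start and cur[3] == value:
            cur = (chrom, cur[1], end, value)
        else:
            if cur is not None:
                yield cur
            cur = (chrom, start, end, value)
    if cur is not None:
        yield cur


def rpkm(count: float, region_len: int, total_mapped: int) -> float:
    """Reads per kilobase of region per million mapped reads."""
    if region_len <= 0:
        raise ValueError("region length must be positive")
    if total_mapped <= 0:
        raise ValueError("total mapped reads must be positive")
    return count * 1e9 / (region_len * total_mapped)


def read_genes_tsv(path, promoter_halfwidth: int = DEFAULT_PROMOTER_HALFWIDTH) -> GeneAnnotation:
    return GeneAnnotation(pd.read_csv(path, sep="\t"), promoter_halfwidth)


def write_genes_tsv(annotation: GeneAnnotation, path) -> None:
    annotation.genes.to_csv(path, sep="\t", index=False)


def read_expression_tsv(path) -> ExpressionTable:
    return ExpressionTable(pd.read_csv(path, sep="\t"))


def write_expression_tsv(expression: ExpressionTable, path) -> None:
    expression.table.to_csv(path, sep="\t", index=False)
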