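"""Genomic containers and flat-file readers/writers shared by every stage.

All coordinates are 0-based, half-open, both in memory and on disk
(BED / bedGraph convention).  Conversion to any other convention happens
nowhere in this package.

Formats handled here:

* BED3/BED6 interval files (peaks, ATAC),
* bedGraph coverage tracks, resampled onto a fixed bin grid,
* a minimal gene table TSV (``chrom  start  end  strand  gene_id``),
* chrom.sizes two-column TSV,
* counts TSV (first column ``gene_id``, one column per sample).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Interval",
    "GeneModel",
    "GenomeAnnotation",
    "BinnedTrack",
    "CountMatrix",
    "MalformedRecordError",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_gene_table",
    "write_gene_table",
    "read_counts",
    "write_counts",
]


class MalformedRecordError(ValueError):
    """A record in a flat genomic file violates the format contract."""


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise MalformedRecordError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware TSS/TES.

    On the plus strand the TSS is ``start`` and the TES is ``end - 1``;
    on the minus strand the TSS is ``end - 1`` and the TES is ``start``.
    "Upstream" of a minus-strand TSS therefore moves toward larger
    coordinates.
    """

    interval: Interval
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise MalformedRecordError(
                f"gene {self.gene_id}: unknown strand {self.strand!r}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    def locus_window(self, upstream: int, chrom_length: int | None = None) -> Interval:
        """Window from ``upstream`` bp before the TSS to the TES, strand-aware.

        The window always contains the full gene body.  It is clipped at
        chromosome boundaries when ``chrom_length`` is given.
        """
        if self.strand == "+":
            s, e = self.start - upstream, self.end
        else:
            s, e = self.start, self.end + upstream
        s = max(s, 0)
        if chrom_length is not None:
            e = min(e, chrom_length)
        return Interval(self.chrom, s, e, name=self.gene_id)

    def promoter_window(
        self, up: int, down: int, chrom_length: int | None = None
    ) -> Interval:
        """Strand-aware window ``[TSS - up, TSS + down)`` clipped to the chromosome."""
        if self.strand == "+":
            s, e = self.tss - up, self.tss + down
        else:
            s, e = self.tss - down + 1, self.tss + up + 1
        s = max(s, 0)
        if chrom_length is not None:
            e = min(e, chrom_length)
        return Interval(self.chrom, s, e, name=self.gene_id)


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus a list of gene models."""

    chrom_sizes: dict[str, int]
    genes: list[GeneModel]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise MalformedRecordError(f"duplicate gene id {g.gene_id}")
            seen.add(g.gene_id)
            if g.chrom not in self.chrom_sizes:
                raise MalformedRecordError(
                    f"gene {g.gene_id} on unknown chromosome {g.chrom}"
                )
            if g.end > self.chrom_sizes[g.chrom]:
                raise MalformedRecordError(
                    f"gene {g.gene_id} extends past end of {g.chrom}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def __len__(self) -> int:
        return len(self.genes)

    def get(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def n_bins(chrom_length: int, bin_size: int) -> int:
    return math.ceil(chrom_length / bin_size)


@dataclass
class BinnedTrack:
    """Fixed-width binned coverage, one float array per chromosome.

    The last bin of a chromosome is truncated (never dropped) when
    ``bin_size`` does not divide the chromosome length.
    """

    bin_size: int
    chrom_sizes: dict[str, int]
    values: dict[str, np.ndarray]
    sample_id: str = ""
    role: str = ""

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_sizes.items():
            expected = n_bins(length, self.bin_size)
            arr = np.asarray(self.values[chrom], dtype=float)
            if arr.shape != (expected,):
                raise ValueError(
                    f"{chrom}: expected {expected} bins, got {arr.shape}"
                )
            self.values[chrom] = arr

    def bin_widths(self, chrom: str) -> np.ndarray:
        length = self.chrom_sizes[chrom]
        nb = n_bins(length, self.bin_size)
        widths = np.full(nb, self.bin_size, dtype=float)
        rem = length - (nb - 1) * self.bin_size
        widths[-1] = rem
        return widths

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(
            bin_size=self.bin_size,
            chrom_sizes=dict(self.chrom_sizes),
            values={c: v.copy() for c, v in self.values.items()},
            sample_id=self.sample_id,
            role=self.role,
        )


@dataclass
class CountMatrix:
    """Integer counts, genes x samples, with a WT/MUT group label per sample."""

    counts: pd.DataFrame  # index gene_id, columns sample_id
    groups: dict[str, str]  # sample_id -> "WT" | "MUT"

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise MalformedRecordError("duplicate gene ids in count matrix")
        if self.counts.columns.duplicated().any():
            raise MalformedRecordError("duplicate sample ids in count matrix")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise MalformedRecordError(
                f"negative count at gene {self.counts.index[r]!r}, "
                f"sample {self.counts.columns[c]!r}"
            )
        if not np.allclose(vals, np.round(vals)):
            raise MalformedRecordError("counts must be integral")
        for s in self.counts.columns:
            if s not in self.groups:
                raise MalformedRecordError(f"sample {s!r} has no group label")
            if self.groups[s] not in ("WT", "MUT"):
                raise MalformedRecordError(
                    f"sample {s!r}: group must be WT or MUT, got {self.groups[s]!r}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == group]


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path, chrom_sizes: Mapping[str, int] | None = None) -> list[Interval]:
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise MalformedRecordError(f"{path}, line {lineno}: fewer than 3 fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise MalformedRecordError(f"{path}, line {lineno}: {exc}") from exc
            if start >= end or start < 0:
                raise MalformedRecordError(
                    f"{path}, line {lineno}: invalid interval {chrom}:{start}-{end}"
                )
            if chrom_sizes is not None:
                if chrom not in chrom_sizes:
                    raise MalformedRecordError(
                        f"{path}, line {lineno}: unknown chromosome {chrom!r}"
                    )
                if end > chrom_sizes[chrom]:
                    raise MalformedRecordError(
                        f"{path}, line {lineno}: interval past end of {chrom}"
                    )
            name = fields[3] if len(fields) > 3 else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            out.append(Interval(chrom, start, end, name=name, score=score))
    return out


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    with open(path, "w") as fh:
        for iv in ivs:
            if iv.name is None and iv.score is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = iv.name if iv.name is not None else "."
                score = f"{iv.score:g}" if iv.score is not None else "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\n")


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(
    path: str | Path,
    chrom_sizes: Mapping[str, int],
    bin_size: int,
    sample_id: str = "",
    role: str = "",
) -> BinnedTrack:
    """Read a sorted, non-overlapping bedGraph onto a fixed bin grid.

    Each bin's value is the coverage-weighted mean of the records covering
    it, with uncovered stretches counting as zero — i.e. the accumulated
    record mass divided by the bin width.  This preserves total signal mass
    up to grid truncation at chromosome ends.
    """
    sums = {
        c: np.zeros(n_bins(length, bin_size)) for c, length in chrom_sizes.items()
    }
    last_end: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise MalformedRecordError(f"{path}, line {lineno}: need 4 fields")
            chrom, start, end, value = (
                fields[0],
                int(fields[1]),
                int(fields[2]),
                float(fields[3]),
            )
            if chrom not in chrom_sizes:
                raise MalformedRecordError(
                    f"{path}, line {lineno}: unknown chromosome {chrom!r}"
                )
            if start >= end:
                raise MalformedRecordError(
                    f"{path}, line {lineno}: invalid interval {chrom}:{start}-{end}"
                )
            if end > chrom_sizes[chrom]:
                raise MalformedRecordError(
                    f"{path}, line {lineno}: record past end of {chrom}"
                )
            if start < last_end.get(chrom, 0):
                raise MalformedRecordError(
                    f"{path}, line {lineno}: records overlap or are unsorted on {chrom}"
                )
            last_end[chrom] = end
            first = start // bin_size
            last = (end - 1) // bin_size
            if first == last:
                sums[chrom][first] += value * (end - start)
            else:
                idx = np.arange(first, last + 1)
                lo = np.maximum(idx * bin_size, start)
                hi = np.minimum((idx + 1) * bin_size, end)
                sums[chrom][first : last + 1] += value * (hi - lo)
    values: dict[str, np.ndarray] = {}
    for chrom, length in chrom_sizes.items():
        nb = n_bins(length, bin_size)
        widths = np.full(nb, bin_size, dtype=float)
        widths[-1] = length - (nb - 1) * bin_size
        values[chrom] = sums[chrom] / widths
    return BinnedTrack(
        bin_size=bin_size,
        chrom_sizes=dict(chrom_sizes),
        values=values,
        sample_id=sample_id,
        role=role,
    )


def write_bedgraph(track: BinnedTrack, path: str | Path) -> None:
    """Write a binned track as a sorted, run-length-merged bedGraph."""
    with open(path, "w") as fh:
        for chrom in sorted(track.chrom_sizes):
            vals = track.values[chrom]
            length = track.chrom_sizes[chrom]
            if len(vals) == 0:
                continue
            run_start = 0
            run_val = vals[0]
            for i in range(1, len(vals)):
                if vals[i] != run_val:
                    fh.write(
                        f"{chrom}\t{run_start * track.bin_size}\t"
                        f"{min(i * track.bin_size, length)}\t{run_val:g}\n"
                    )
                    run_start, run_val = i, vals[i]
            fh.write(
                f"{chrom}\t{run_start * track.bin_size}\t{length}\t{run_val:g}\n"
            )


# ---------------------------------------------------------------------------
# chrom sizes / gene table / counts


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise MalformedRecordError(f"{path}, line {lineno}: need 2 fields")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def read_gene_table(path: str | Path, chrom_sizes: Mapping[str, int]) -> GenomeAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    required = {"chrom", "start", "end", "strand", "gene_id"}
    missing = required - set(df.columns)
    if missing:
        raise MalformedRecordError(f"{path}: missing columns {sorted(missing)}")
    genes = [
        GeneModel(
            interval=Interval(row.chrom, int(row.start), int(row.end)),
            strand=row.strand,
            gene_id=row.gene_id,
        )
        for row in df.itertuples()
    ]
    return GenomeAnnotation(chrom_sizes=dict(chrom_sizes), genes=genes)


def write_gene_table(annotation: GenomeAnnotation, path: str | Path) -> None:
    rows = [
        (g.chrom, g.start, g.end, g.strand, g.gene_id)
        for g in sorted(annotation.genes, key=lambda g: (g.chrom, g.start, g.gene_id))
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_counts(path: str | Path, groups: Mapping[str, str]) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return CountMatrix(counts=df, groups=dict(groups))


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    out = matrix.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
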