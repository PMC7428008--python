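"""Binned read-density tracks.

Each aligned read is extended to a fixed length from its 5′ end (default
200 bp) and tallied over fixed-width bins tiling every chromosome from
coordinate 0 (default 25 bp): a bin receives +1 for every extended read
overlapping it by at least one base. Tracks are depth-normalized by scaling
to a fixed number of reads (default one million), which makes libraries of
different sequencing depth comparable.

Reads live in pandas DataFrames with columns ``chrom, start, end, strand``
(BED6 order on disk); tracks store one numpy count vector per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Mapping, NamedTuple, Tuple

import numpy as np
import pandas as pd

READ_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class AlignedRead(NamedTuple):
    """A mapped read as a stranded 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'


@dataclass
class BinnedTrack:
    """Genome-tiled fixed-width bin counts for one library."""

    data: Dict[str, np.ndarray]
    chrom_sizes: Dict[str, int]
    bin_size: int = 25
    extension: int = 200
    depth: int = 0
    normalized: bool = False
    scale_per: float = 1_000_000.0

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.bin_size)  # ceil division

    @property
    def total_bins(self) -> int:
        return sum(arr.size for arr in self.data.values())

    @property
    def total_events(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    def same_grid(self, other: "BinnedTrack") -> bool:
        return (self.bin_size == other.bin_size
                and self.chrom_sizes == other.chrom_sizes)


def extend_read(read: AlignedRead, extension: int,
                chrom_length: int | None = None) -> Tuple[int, int]:
    """Extend a read to ``extension`` bases from its 5′ end.

    Plus strand: [start, start+extension); minus strand: [end−extension, end);
    clipped to [0, chrom_length) when a chromosome length is given.
    """
    if extension <= 0:
        raise ValueError("extension must be > 0")
    if read.strand == "-":
        s, e = read.end - extension, read.end
    else:
        s, e = read.start, read.start + extension
    s = max(s, 0)
    if chrom_length is not None:
        e = min(e, chrom_length)
    return s, e


def read_bed_reads(path: Path | str) -> pd.DataFrame:
    """Read a BED6 read file (one record per read)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=READ_COLUMNS, dtype={"chrom": str})
    return df[["chrom", "start", "end", "strand"]].copy()


def read_sam_reads(path: Path | str) -> pd.DataFrame:
    """Adapter for SAM/BAM input.

    Properly-paired fragments are reduced to one stranded interval, keeping
    the plus-most (forward) mate; unpaired mapped reads are kept as-is.
    Secondary/supplementary alignments and unmapped reads are dropped.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path)) as af:
        for aln in af:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.is_paired and aln.is_proper_pair and aln.is_reverse:
                continue  # keep only the forward mate of a proper pair
            rows.append((aln.reference_name, aln.reference_start,
                         aln.reference_end, "-" if aln.is_reverse else "+"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])


def bin_counts(reads: pd.DataFrame, chrom_sizes: Mapping[str, int],
               bin_size: int = 25, extension: int = 200) -> BinnedTrack:
    """Tally extended-read overlap events over the fixed bin grid.

    Bin b = [b·bin_size, (b+1)·bin_size) receives +1 for every extended read
    whose interval overlaps it by ≥1 base. Depth = number of input reads.
    """
    unknown = set(reads["chrom"].unique()) - set(chrom_sizes)
    if unknown:
        raise ValueError(f"reads on unknown chromosomes: {sorted(unknown)}")

    data: Dict[str, np.ndarray] = {
        chrom: np.zeros(-(-length // bin_size), dtype=np.int64)
        for chrom, length in chrom_sizes.items()
    }
    for chrom, grp in reads.groupby("chrom", sort=False):
        length = chrom_sizes[chrom]
        start = grp["start"].to_numpy(np.int64)
        end = grp["end"].to_numpy(np.int64)
        minus = grp["strand"].to_numpy() == "-"
        s = np.where(minus, end - extension, start)
        e = np.where(minus, end, start + extension)
        np.clip(s, 0, length, out=s)
        np.clip(e, 0, length, out=e)
        keep = e > s
        s, e = s[keep], e[keep]
        b0 = s // bin_size
        b1 = (e - 1) // bin_size  # inclusive last bin
        diff = np.zeros(data[chrom].size + 1, dtype=np.int64)
        np.add.at(diff, b0, 1)
        np.add.at(diff, b1 + 1, -1)
        data[chrom] += np.cumsum(diff)[:-1]
    return BinnedTrack(data=data, chrom_sizes=dict(chrom_sizes),
                       bin_size=bin_size, extension=extension,
                       depth=len(reads), normalized=False)


def normalize_depth(track: BinnedTrack, scale_per: float = 1_000_000.0) -> BinnedTrack:
    """Scale every bin by scale_per / depth. Errors on double normalization."""
    if track.normalized:
        raise ValueError("track is already depth-normalized")
    if track.depth <= 0:
        raise ValueError("cannot normalize a track with zero depth")
    factor = scale_per / track.depth
    data = {c: arr.astype(np.float64) * factor for c, arr in track.data.items()}
    return replace(track, data=data, normalized=True, scale_per=scale_per)


def write_track(track: BinnedTrack, path: Path | str, fmt: str = "bedgraph",
                omit_zero: bool = True, header: str | None = None) -> None:
    """Write a track as bedGraph or fixedStep wiggle at bin resolution."""
    B = track.bin_size
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        if fmt == "bedgraph":
            fh.write('track type=bedGraph\n')
            for chrom in sorted(track.data):
                arr = track.data[chrom]
                length = track.chrom_sizes[chrom]
                idx = np.nonzero(arr)[0] if omit_zero else np.arange(arr.size)
                for b in idx:
                    fh.write(f"{chrom}\t{b * B}\t{min((b + 1) * B, length)}\t"
                             f"{arr[b]:.10g}\n")
        elif fmt == "wig":
            for chrom in sorted(track.data):
                fh.write(f"fixedStep chrom={chrom} start=1 step={B} span={B}\n")
                fh.write("\n".join(f"{v:.10g}" for v in track.data[chrom]))
                fh.write("\n")
        else:
            raise ValueError(f"unknown track format {fmt!r}")


def read_bedgraph(path: Path | str, chrom_sizes: Mapping[str, int],
                  bin_size: int = 25, **track_kwargs) -> BinnedTrack:
    """Read a bin-resolution bedGraph back into a track (round-trip aid)."""
    data = {chrom: np.zeros(-(-length // bin_size), dtype=np.float64)
            for chrom, length in chrom_sizes.items()}
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            chrom, s, _e, v = line.split("\t")
            data[chrom][int(s) // bin_size] = float(v)
    # restore integer dtype when the file held only integral values
    if all(np.all(arr == np.floor(arr)) for arr in data.values()):
        data = {c: arr.astype(np.int64) for c, arr in data.items()}
    return BinnedTrack(data=data, chrom_sizes=dict(chrom_sizes),
                       bin_size=bin_size, **track_kwargs)
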