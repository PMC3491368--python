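"""Read-level ChIP-seq signal model.

Single-end sequencing tags are reduced to strand-specific 5' positions,
deduplicated to at most one tag per genomic position per strand (a guard
against PCR artifacts), shifted 75 bp toward the fragment midpoint (half
the nucleosomal DNA length), counted in windows, depth-normalized to a
common library size of 5 million non-redundant reads, and background-
subtracted against a control library with negative values clipped to zero.

Coordinates are 0-based half-open (BED convention) throughout; SAM input
is converted on read.  "Uniquely aligned" is enforced with a MAPQ cutoff
since alignment happens upstream of this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TagSet",
    "WindowTrack",
    "read_chrom_sizes",
    "read_tags_bed",
    "read_tags_sam",
    "deduplicate",
    "shift_tags",
    "count_windows",
    "normalize_depth",
    "subtract_control",
    "bedgraph_tracks",
    "write_bedgraph",
]

DEFAULT_SHIFT = 75
DEPTH_TARGET = 5_000_000


@dataclass
class TagSet:
    """Per-(chromosome, strand) sorted, unique tag 5' positions."""

    positions: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    @property
    def library_size(self) -> int:
        return int(sum(a.size for a in self.positions.values()))

    def chromosomes(self) -> list[str]:
        return sorted({c for c, _ in self.positions})

    def all_positions(self, chrom: str) -> np.ndarray:
        """Both-strand sorted positions for one chromosome."""
        arrs = [
            self.positions[(chrom, s)]
            for s in "+-"
            if (chrom, s) in self.positions
        ]
        if not arrs:
            return np.array([], dtype=np.int64)
        return np.sort(np.concatenate(arrs))


@dataclass
class WindowTrack:
    """Fixed-grid window values per chromosome (starts at 0, step apart)."""

    window: int
    step: int
    values: dict[str, np.ndarray]
    normalization_target: int | None = None

    def starts(self, chrom: str) -> np.ndarray:
        return np.arange(self.values[chrom].size, dtype=np.int64) * self.step


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))


def read_tags_bed(path) -> pd.DataFrame:
    """BED6 reads -> tag table (chrom, pos = strand-specific 5' end, strand)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 5],
        names=["chrom", "start", "end", "strand"],
        comment="#",
    )
    pos = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    return pd.DataFrame(
        {"chrom": df["chrom"], "pos": pos.astype(np.int64), "strand": df["strand"]}
    )


def read_tags_sam(path, min_mapq: int = 20) -> pd.DataFrame:
    """SAM/BAM -> tag table, keeping uniquely-aligned reads (MAPQ filter)."""
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.mapping_quality < min_mapq:
                continue
            if rec.is_reverse:
                rows.append((rec.reference_name, rec.reference_end - 1, "-"))
            else:
                rows.append((rec.reference_name, rec.reference_start, "+"))
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand"])


def deduplicate(tags: pd.DataFrame) -> TagSet:
    """At most one tag per genomic position per strand; idempotent."""
    positions: dict[tuple[str, str], np.ndarray] = {}
    for (chrom, strand), grp in tags.groupby(["chrom", "strand"], sort=True):
        positions[(str(chrom), str(strand))] = np.unique(
            grp["pos"].to_numpy(dtype=np.int64)
        )
    return TagSet(positions)


def shift_tags(
    tagset: TagSet, shift: int = DEFAULT_SHIFT, chrom_sizes: dict[str, int] | None = None
) -> TagSet:
    """Shift tags toward the fragment midpoint: + strand +shift, - strand -shift.

    Positions are clamped to [0, chromosome length) at the edges; the tag
    count is unaffected (clamped duplicates are kept by re-unique only if
    they collide, which can only happen at the extreme edge).
    """
    if shift < 0:
        raise ValueError("shift must be non-negative")
    out = {}
    for (chrom, strand), pos in tagset.positions.items():
        moved = pos + shift if strand == "+" else pos - shift
        moved = np.maximum(moved, 0)
        if chrom_sizes and chrom in chrom_sizes:
            moved = np.minimum(moved, chrom_sizes[chrom] - 1)
        out[(chrom, strand)] = np.sort(moved)
    return TagSet(out)


def count_windows(
    tagset: TagSet,
    window_bp: int,
    step_bp: int,
    chrom_sizes: dict[str, int],
) -> WindowTrack:
    """Tag counts in sliding windows [k*step, k*step + window) per chromosome."""
    if not (window_bp >= step_bp > 0):
        raise ValueError("require window >= step > 0")
    values = {}
    for chrom, size in chrom_sizes.items():
        n_win = max(1, -(-size // step_bp))
        starts = np.arange(n_win, dtype=np.int64) * step_bp
        pos = tagset.all_positions(chrom)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window_bp, side="left")
        values[chrom] = (hi - lo).astype(float)
    return WindowTrack(window_bp, step_bp, values)


def normalize_depth(
    track: WindowTrack, library_size: int, target: int = DEPTH_TARGET
) -> WindowTrack:
    """Scale window values to a common depth of ``target`` reads."""
    if library_size <= 0:
        raise ValueError("library size must be positive")
    factor = target / library_size
    return WindowTrack(
        track.window,
        track.step,
        {c: v * factor for c, v in track.values.items()},
        normalization_target=target,
    )


def subtract_control(sample: WindowTrack, control: WindowTrack) -> WindowTrack:
    """max(0, N_sample - N_control) per window; grids must match."""
    if (sample.window, sample.step) != (control.window, control.step) or set(
        sample.values
    ) != set(control.values):
        raise ValueError("sample and control tracks are on different grids")
    values = {}
    for chrom in sample.values:
        a, b = sample.values[chrom], control.values[chrom]
        if a.size != b.size:
            raise ValueError(f"window grids differ on {chrom}")
        values[chrom] = np.maximum(0.0, a - b)
    return replace(sample, values=values)


def bedgraph_tracks(
    data,
    mode: str,
    chrom_sizes: dict[str, int],
    library_size: int | None = None,
) -> pd.DataFrame:
    """Genome-browser tiles: ChIP tags in 200-bp tiles or RNA read centers in 20-bp.

    ``chip-200bp-shifted`` expects a TagSet of 75-bp-shifted tags and
    normalizes counts to 5 M reads; ``rna-20bp-centers`` expects a reads
    DataFrame (chrom, start, end) and counts read centers unnormalized.
    Zero tiles are omitted; records are sorted, half-open, non-overlapping.
    """
    rows = []
    if mode == "chip-200bp-shifted":
        tile = 200
        if library_size is None:
            library_size = data.library_size
        factor = DEPTH_TARGET / library_size
        for chrom in data.chromosomes():
            pos = data.all_positions(chrom)
            idx, counts = np.unique(pos // tile, return_counts=True)
            for i, c in zip(idx, counts):
                rows.append((chrom, int(i) * tile, int(i) * tile + tile, c * factor))
    elif mode == "rna-20bp-centers":
        tile = 20
        centers = ((data["start"] + data["end"]) // 2).to_numpy(dtype=np.int64)
        for chrom in sorted(data["chrom"].unique()):
            sel = centers[(data["chrom"] == chrom).to_numpy()]
            idx, counts = np.unique(sel // tile, return_counts=True)
            for i, c in zip(idx, counts):
                rows.append((chrom, int(i) * tile, int(i) * tile + tile, float(c)))
    else:
        raise ValueError(f"unknown bedGraph mode {mode!r}")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    for chrom, size in chrom_sizes.items():
        df.loc[df["chrom"] == chrom, "end"] = df.loc[
            df["chrom"] == chrom, "end"
        ].clip(upper=size)
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def write_bedgraph(df: pd.DataFrame, path, track_name: str | None = None) -> None:
    with open(path, "w") as fh:
        if track_name:
            fh.write(f'track type=bedGraph name="{track_name}"\n')
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value:g}\n")
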