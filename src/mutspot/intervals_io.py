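"""Genome tiling, interval arithmetic, and text-format I/O.

Everything downstream speaks 0-based half-open coordinates (the BED
convention).  This module provides the interval and genome containers, the
fixed-width window tiling used for hotspot scoring, flanking-region
construction with chromosome-end truncation and mappability masking, and
readers/writers for BED, bedGraph, chrom.sizes and FASTA.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "GenomeIndex",
    "ScoreTrack",
    "Flank",
    "FlankStats",
    "make_windows",
    "build_flank",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bedgraph",
    "write_bedgraph",
    "read_fasta",
    "write_fasta",
]

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome span in 0-based half-open coordinates [start, end)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class GenomeIndex:
    """Chromosome lengths plus (optionally) the sequences themselves.

    A chrom.sizes file yields a skeleton index (lengths only); a FASTA
    yields a full index whose ``sequence`` accessor returns uppercase
    bases over the alphabet {A, C, G, T, N}.
    """

    chrom_lengths: dict[str, int]
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"non-positive length {length} for {chrom}")

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def check_interval(self, interval: GenomicInterval) -> None:
        """Raise if ``interval`` is not fully inside the genome."""
        length = self.chrom_lengths.get(interval.chrom)
        if length is None:
            raise KeyError(f"unknown chromosome {interval.chrom!r}")
        if interval.end > length:
            raise ValueError(
                f"interval {interval} extends past chromosome end ({length})"
            )

    def sequence(self, chrom: str, start: int, end: int) -> str:
        if self.sequences is None:
            raise ValueError("genome index carries lengths only, no sequence")
        self.check_interval(GenomicInterval(chrom, start, end))
        return self.sequences[chrom][start:end]


def _normalize_sequence(seq: str) -> str:
    seq = seq.upper()
    return "".join(b if b in _VALID_BASES else "N" for b in seq)


class ScoreTrack:
    """Per-base real-valued track (conservation, mappability).

    Values are stored as one float array per chromosome with NaN marking
    missing positions; a point query returns either a value or NaN, never
    a silent default, and queries outside the covered bounds raise.
    """

    def __init__(self, values: dict[str, np.ndarray]):
        self._values = {c: np.asarray(v, dtype=float) for c, v in values.items()}

    @classmethod
    def constant(cls, genome: GenomeIndex, value: float) -> "ScoreTrack":
        return cls(
            {c: np.full(n, float(value)) for c, n in genome.chrom_lengths.items()}
        )

    @property
    def chroms(self) -> list[str]:
        return list(self._values)

    def _array(self, chrom: str) -> np.ndarray:
        try:
            return self._values[chrom]
        except KeyError:
            raise KeyError(f"track has no chromosome {chrom!r}") from None

    def at(self, chrom: str, pos: int) -> float:
        arr = self._array(chrom)
        if not 0 <= pos < arr.size:
            raise IndexError(f"position {chrom}:{pos} outside track bounds")
        return float(arr[pos])

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        arr = self._array(chrom)
        if start < 0 or end > arr.size or start >= end:
            raise IndexError(f"range {chrom}:{start}-{end} outside track bounds")
        return arr[start:end]

    def values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized point query; any out-of-bounds position raises."""
        arr = self._array(chrom)
        positions = np.asarray(positions)
        if positions.size and (positions.min() < 0 or positions.max() >= arr.size):
            raise IndexError(f"position outside track bounds on {chrom}")
        return arr[positions]

    def runs(self, chrom: str) -> Iterator[tuple[int, int, float]]:
        """Yield maximal (start, end, value) runs of defined values."""
        arr = self._array(chrom)
        defined = ~np.isnan(arr)
        if not defined.any():
            return
        # run boundaries: value change or defined-ness change
        change = np.empty(arr.size, dtype=bool)
        change[0] = True
        same = (arr[1:] == arr[:-1]) | (np.isnan(arr[1:]) & np.isnan(arr[:-1]))
        change[1:] = ~same
        starts = np.flatnonzero(change)
        ends = np.append(starts[1:], arr.size)
        for s, e in zip(starts, ends):
            if defined[s]:
                yield int(s), int(e), float(arr[s])


@dataclass
class Flank:
    """Flanking regions of a target window with a validity mask.

    ``left``/``right`` are the flank intervals truncated at chromosome
    ends (None when the window abuts an end); the masks mark flank bases
    whose mappability passes the threshold and therefore count toward the
    valid-base lengths L0 and R0.
    """

    left: GenomicInterval | None
    right: GenomicInterval | None
    left_valid: np.ndarray = field(repr=False)
    right_valid: np.ndarray = field(repr=False)

    @property
    def n_valid_left(self) -> int:
        return int(self.left_valid.sum())

    @property
    def n_valid_right(self) -> int:
        return int(self.right_valid.sum())


@dataclass
class FlankStats:
    """Mutation counts and valid-base lengths of a window's flanks.

    ``left_mutations`` (L) and ``right_mutations`` (R) count mutations at
    valid flank bases; ``left_valid_bases`` (L0) and ``right_valid_bases``
    (R0) count the bases themselves.  The flanking mutation rate is
    (L + R) / (L0 + R0), defined only when L0 + R0 > 0.
    """

    left_mutations: int
    right_mutations: int
    left_valid_bases: int
    right_valid_bases: int

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")


def make_windows(genome: GenomeIndex, width: int) -> list[GenomicInterval]:
    """Tile every chromosome with non-overlapping windows of ``width`` bp.

    The final window on each chromosome may be shorter than ``width``;
    such trailing windows are kept (they are scored with their true
    length).  Output is sorted by (chrom, start).
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    if not genome.chrom_lengths:
        raise ValueError("no chromosomes")
    windows: list[GenomicInterval] = []
    for chrom in sorted(genome.chrom_lengths):
        length = genome.chrom_lengths[chrom]
        for start in range(0, length, width):
            windows.append(GenomicInterval(chrom, start, min(start + width, length)))
    return windows


def build_flank(
    window: GenomicInterval,
    genome: GenomeIndex,
    flank_size: int,
    mappability: ScoreTrack | None = None,
    min_mappability: float = 0.5,
) -> Flank:
    """Construct the flanking regions of ``window``, truncated at chromosome
    ends, with per-base mappability masking.

    The target window itself is excluded: the left flank is
    [max(0, start - flank_size), start) and the right flank is
    [end, min(chrom_length, end + flank_size)).  Flank bases with
    mappability below ``min_mappability`` (or with a missing mappability
    value) are marked invalid; with no track supplied every base is valid.
    """
    if flank_size < 1:
        raise ValueError("flank_size must be >= 1")
    genome.check_interval(window)
    chrom_len = genome.chrom_lengths[window.chrom]

    left_start = max(0, window.start - flank_size)
    right_end = min(chrom_len, window.end + flank_size)
    left = (
        GenomicInterval(window.chrom, left_start, window.start)
        if left_start < window.start
        else None
    )
    right = (
        GenomicInterval(window.chrom, window.end, right_end)
        if window.end < right_end
        else None
    )

    def valid_mask(iv: GenomicInterval | None) -> np.ndarray:
        if iv is None:
            return np.zeros(0, dtype=bool)
        if mappability is None:
            return np.ones(iv.length, dtype=bool)
        vals = mappability.values(iv.chrom, iv.start, iv.end)
        return ~np.isnan(vals) & (vals >= min_mappability)

    return Flank(left, right, valid_mask(left), valid_mask(right))


# ---------------------------------------------------------------------------
# text-format readers / writers


def _parse_error(path, lineno: int, msg: str) -> ValueError:
    return ValueError(f"{path}, line {lineno}: {msg}")


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3+ (tab-separated, no header; extra columns ignored)."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise _parse_error(path, lineno, "fewer than 3 BED columns")
            try:
                iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            except ValueError as exc:
                raise _parse_error(path, lineno, str(exc)) from None
            intervals.append(iv)
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path, names=None) -> None:
    with open(path, "w") as fh:
        if names is None:
            for iv in intervals:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
        else:
            for iv, name in zip(intervals, names):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def read_chrom_sizes(path) -> GenomeIndex:
    """Read a two-column "name<TAB>length" file into a lengths-only index."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise _parse_error(path, lineno, "expected name<TAB>length")
            try:
                lengths[parts[0]] = int(parts[1])
            except ValueError:
                raise _parse_error(path, lineno, f"bad length {parts[1]!r}") from None
    return GenomeIndex(lengths)


def write_chrom_sizes(genome: GenomeIndex, path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")


def read_bedgraph(path, genome: GenomeIndex | None = None) -> ScoreTrack:
    """Read a text bedGraph into a per-base ScoreTrack.

    Each interval expands to per-base values.  Overlapping intervals are
    an error ("ambiguous track value").  When a genome is supplied, arrays
    are sized to chromosome lengths and out-of-genome intervals raise;
    otherwise each chromosome array is sized to the maximum end seen.
    """
    records: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise _parse_error(path, lineno, "expected chrom start end value")
            try:
                chrom, start, end, value = (
                    parts[0],
                    int(parts[1]),
                    int(parts[2]),
                    float(parts[3]),
                )
            except ValueError:
                raise _parse_error(path, lineno, "unparsable coordinates/value") from None
            if start < 0 or start >= end:
                raise _parse_error(path, lineno, f"bad interval {start}-{end}")
            records.setdefault(chrom, []).append((start, end, value))

    arrays: dict[str, np.ndarray] = {}
    for chrom, recs in records.items():
        if genome is not None:
            if chrom not in genome.chrom_lengths:
                raise ValueError(f"bedGraph chromosome {chrom!r} not in genome")
            size = genome.chrom_lengths[chrom]
        else:
            size = max(e for _, e, _ in recs)
        arr = np.full(size, np.nan)
        covered = np.zeros(size, dtype=bool)
        for start, end, value in recs:
            if end > size:
                raise ValueError(
                    f"bedGraph interval {chrom}:{start}-{end} exceeds "
                    f"chromosome length {size}"
                )
            if covered[start:end].any():
                raise ValueError(
                    f"ambiguous track value: overlapping bedGraph intervals "
                    f"at {chrom}:{start}-{end}"
                )
            covered[start:end] = True
            arr[start:end] = value
        arrays[chrom] = arr
    if genome is not None:
        for chrom, length in genome.chrom_lengths.items():
            arrays.setdefault(chrom, np.full(length, np.nan))
    return ScoreTrack(arrays)


def write_bedgraph(track: ScoreTrack, path) -> None:
    """Write defined runs of a ScoreTrack as text bedGraph."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            for start, end, value in track.runs(chrom):
                fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def read_fasta(path) -> GenomeIndex:
    """Read a FASTA into a full genome index.

    Lowercase bases are uppercased; anything outside {A,C,G,T} becomes N.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        sequences[record.id] = _normalize_sequence(str(record.seq))
    if not sequences:
        raise ValueError(f"no sequences in {path}")
    return GenomeIndex({c: len(s) for c, s in sequences.items()}, sequences)


def write_fasta(genome: GenomeIndex, path, line_width: int = 70) -> None:
    if genome.sequences is None:
        raise ValueError("genome index has no sequences to write")
    with open(path, "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")
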