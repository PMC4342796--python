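"""Genomic intervals, BED I/O, and overlap queries.

Coordinates are BED-style throughout: 0-based, half-open ``[start, end)``.
No 1-based conversion exists anywhere in the package. Strand is ignored:
histone-mark peaks and enhancer assays are strand-agnostic. Duplicate
identical regions are retained; peak callers may legitimately emit them.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

from .errors import BedParseError, BoundsError

_SKIP_PREFIXES = ("track", "browser", "#")


@dataclass(frozen=True)
class GenomicRegion:
    """A half-open genomic interval ``[start, end)`` on a named chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name (e.g. ``"chr1"``).
    start, end : int
        0-based half-open coordinates; ``0 <= start < end`` is enforced.
    name : str, optional
        Identifier carried through BED round trips (column 4).
    label : str, optional
        Free-text activity annotation, e.g. the tissue in which an
        enhancer drives expression.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def overlap_bp(self, other: "GenomicRegion") -> int:
        """Shared bases with ``other`` (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Genome:
    """Chromosome-size table bounding simulation and background sampling."""

    chrom_sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {size}")

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_sizes.values())

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    def contains(self, region: GenomicRegion) -> bool:
        size = self.chrom_sizes.get(region.chrom)
        return size is not None and region.end <= size

    @classmethod
    def from_file(cls, path) -> "Genome":
        """Read a two-column ``chrom.sizes`` TSV."""
        sizes: dict[str, int] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            chrom, size = line.split("\t")[:2]
            sizes[chrom] = int(size)
        return cls(sizes)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, size in self.chrom_sizes.items():
                fh.write(f"{chrom}\t{size}\n")


class RegionSet:
    """An ordered, normalized collection of :class:`GenomicRegion`.

    Regions are sorted by ``(chrom, start, end)`` on construction and a
    per-chromosome numpy index is built lazily for overlap queries.
    """

    def __init__(self, regions: Iterable[GenomicRegion], source_id: str = ""):
        self.regions: tuple[GenomicRegion, ...] = tuple(
            sorted(regions, key=GenomicRegion.sort_key)
        )
        self.source_id = source_id
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[GenomicRegion]:
        return iter(self.regions)

    def __getitem__(self, i: int) -> GenomicRegion:
        return self.regions[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.regions == other.regions

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"RegionSet({len(self)} regions, source_id={self.source_id!r})"

    def check_bounds(self, genome: Genome) -> None:
        for r in self.regions:
            if r.chrom not in genome.chrom_sizes:
                raise BoundsError(f"region {r} on unknown chromosome {r.chrom!r}")
            if r.end > genome.chrom_sizes[r.chrom]:
                raise BoundsError(
                    f"region {r} exceeds {r.chrom} length "
                    f"{genome.chrom_sizes[r.chrom]}"
                )

    def _chrom_index(self, chrom: str) -> tuple[np.ndarray, np.ndarray] | None:
        if self._index is None:
            idx: dict[str, list[list[int]]] = {}
            for r in self.regions:
                idx.setdefault(r.chrom, [[], []])
                idx[r.chrom][0].append(r.start)
                idx[r.chrom][1].append(r.end)
            self._index = {
                c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
                for c, (s, e) in idx.items()
            }
        return self._index.get(chrom)


def overlaps(query: GenomicRegion, peaks: RegionSet, min_bp: int = 1) -> bool:
    """True iff some peak shares at least ``min_bp`` bases with ``query``.

    Uses binary search on the sorted start coordinates to bound the
    candidate window, then a vectorized overlap computation; half-open
    semantics mean adjacent intervals ``[a,b)``/``[b,c)`` never overlap.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    idx = peaks._chrom_index(query.chrom)
    if idx is None:
        return False
    starts, ends = idx
    # peaks with start > end - min_bp cannot share min_bp bases
    hi = int(np.searchsorted(starts, query.end - min_bp, side="right"))
    if hi == 0:
        return False
    ov = np.minimum(ends[:hi], query.end) - np.maximum(starts[:hi], query.start)
    return bool((ov >= min_bp).any())


def overlap_flags(
    queries: Iterable[GenomicRegion], peaks: RegionSet, min_bp: int = 1
) -> np.ndarray:
    """Vector of overlap booleans, one per query, against one peak set."""
    return np.array([overlaps(q, peaks, min_bp=min_bp) for q in queries], dtype=bool)


def parse_bed(path_or_stream, genome: Genome | None = None) -> RegionSet:
    """Parse BED3+ text into a normalized :class:`RegionSet`.

    Columns beyond the name (col 4) are ignored; ``track``/``browser``/``#``
    lines and blank lines are skipped. Coordinates are interpreted as
    0-based half-open. Raises :class:`BedParseError` with the line number
    on malformed input and :class:`BoundsError` when a ``genome`` is given
    and a region falls outside it.
    """
    if isinstance(path_or_stream, (str, Path)):
        stream = open(path_or_stream)
        source_id = Path(path_or_stream).stem
        close = True
    else:
        stream = path_or_stream
        source_id = getattr(path_or_stream, "name", "<stream>")
        close = False

    regions: list[GenomicRegion] = []
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated input
                fields = line.split()
            if len(fields) < 3:
                raise BedParseError(f"expected >=3 columns, got {len(fields)}", lineno)
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"non-integer coordinates {fields[1]!r}, {fields[2]!r}", lineno
                ) from None
            if start < 0 or start >= end:
                raise BedParseError(
                    f"invalid interval [{start}, {end}) (require 0 <= start < end)",
                    lineno,
                )
            name = fields[3] if len(fields) >= 4 and fields[3] != "." else None
            regions.append(GenomicRegion(chrom, start, end, name=name))
    finally:
        if close:
            stream.close()

    out = RegionSet(regions, source_id=source_id)
    if genome is not None:
        out.check_bounds(genome)
    return out


def parse_bed_string(text: str, genome: Genome | None = None) -> RegionSet:
    """Convenience wrapper: parse BED from an in-memory string."""
    return parse_bed(io.StringIO(text), genome=genome)


def write_bed(regions: RegionSet, path) -> int:
    """Write BED3 (or BED4 when any region has a name); returns record count.

    Round-trips through :func:`parse_bed` to an equal :class:`RegionSet`.
    """
    with_names = any(r.name is not None for r in regions)
    n = 0
    with open(path, "w") as fh:
        for r in regions:
            if with_names:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name or '.'}\n")
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
            n += 1
    return n
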