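"""Core genomic data containers.

All coordinates in this package are 0-based, half-open ([start, end)),
BED-style. Formats with other conventions (GFF3) are converted at the
I/O boundary and never leak 1-based coordinates inward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomeModel",
    "GenomicInterval",
    "GeneModel",
    "AnnotationSet",
    "FragmentSet",
    "WindowedSignal",
    "BlockedTrack",
    "Segment",
    "SegmentSet",
]


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosome names and lengths (bp)."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    @property
    def total_bp(self) -> int:
        return sum(l for _, l in self.chromosomes)


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval with optional strand, name and score."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"degenerate interval {self.chrom}:{self.start}-{self.end} (start >= end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its single primary transcript.

    ``tss``/``tts`` are strand-aware base positions: for a '+' gene the TSS
    is ``interval.start``, for a '-' gene it is ``interval.end - 1``.
    """

    id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    five_utr: tuple[GenomicInterval, ...] = ()
    three_utr: tuple[GenomicInterval, ...] = ()

    def __post_init__(self):
        prev_end = -1
        for ex in sorted(self.exons, key=lambda e: e.start):
            if ex.start < prev_end:
                raise ValueError(f"gene {self.id}: overlapping exons")
            prev_end = ex.end
        span_s, span_e = self.interval.start, self.interval.end
        for ex in self.exons + self.five_utr + self.three_utr:
            if ex.start < span_s or ex.end > span_e:
                raise ValueError(f"gene {self.id}: child feature outside gene span")
        object.__setattr__(self, "exons", tuple(sorted(self.exons, key=lambda e: e.start)))

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand != "-" else self.interval.end - 1

    @property
    def tts(self) -> int:
        return self.interval.end - 1 if self.strand != "-" else self.interval.start

    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.interval.chrom, a.end, b.start, self.strand))
        return out


@dataclass
class AnnotationSet:
    """Gene models plus transposable-element intervals."""

    genes: list[GeneModel] = field(default_factory=list)
    tes: list[GenomicInterval] = field(default_factory=list)

    def gene_by_id(self, gid: str) -> GeneModel:
        for g in self.genes:
            if g.id == gid:
                return g
        raise KeyError(gid)


@dataclass
class FragmentSet:
    """Sequenced MNase fragments from one digest condition.

    ``digest`` is 'light' or 'heavy'; ``replicate`` is a free-form id.
    """

    intervals: list[GenomicInterval]
    digest: str = "light"
    replicate: str = "rep1"

    def __post_init__(self):
        if self.digest not in ("light", "heavy"):
            raise ValueError(f"digest must be 'light' or 'heavy', got {self.digest!r}")

    def __len__(self) -> int:
        return len(self.intervals)

    def lengths(self) -> np.ndarray:
        return np.array([len(iv) for iv in self.intervals], dtype=int)

    @staticmethod
    def pool(*sets: "FragmentSet") -> "FragmentSet":
        """Replicate pooling: concatenation of fragment lists."""
        if not sets:
            raise ValueError("nothing to pool")
        digest = sets[0].digest
        if any(s.digest != digest for s in sets):
            raise ValueError("cannot pool different digests")
        ivs: list[GenomicInterval] = []
        for s in sets:
            ivs.extend(s.intervals)
        return FragmentSet(ivs, digest=digest, replicate="pooled")


class WindowedSignal:
    """Fixed-width windowed signal over a genome.

    One value per window ``[i*width, (i+1)*width)``; the final window of each
    chromosome may be partial. Values are stored per chromosome as float
    arrays of length ``ceil(chrom_length / width)``.
    """

    def __init__(self, genome: GenomeModel, width: int, values: dict[str, np.ndarray]):
        if width <= 0:
            raise ValueError("window width must be positive")
        self.genome = genome
        self.width = int(width)
        self.values: dict[str, np.ndarray] = {}
        for name, length in genome.chromosomes:
            n = -(-length // width)
            v = np.asarray(values[name], dtype=float)
            if v.shape != (n,):
                raise ValueError(
                    f"{name}: expected {n} windows of width {width}, got shape {v.shape}"
                )
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name}: non-finite signal values")
            self.values[name] = v

    @classmethod
    def zeros(cls, genome: GenomeModel, width: int) -> "WindowedSignal":
        return cls(
            genome, width,
            {n: np.zeros(-(-l // width)) for n, l in genome.chromosomes},
        )

    def n_windows(self, chrom: str) -> int:
        return len(self.values[chrom])

    def concat(self) -> np.ndarray:
        """All window values, chromosomes in genome order."""
        return np.concatenate([self.values[n] for n in self.genome.names])

    def copy_with(self, values: dict[str, np.ndarray]) -> "WindowedSignal":
        return WindowedSignal(self.genome, self.width, values)

    def compatible(self, other: "WindowedSignal") -> bool:
        return (
            self.width == other.width
            and self.genome.chromosomes == other.genome.chromosomes
        )

    def base_value(self, chrom: str, pos: int) -> float:
        """Value at single-base resolution (each base takes its window's value)."""
        return float(self.values[chrom][pos // self.width])

    def __eq__(self, other) -> bool:
        if not isinstance(other, WindowedSignal):
            return NotImplemented
        return self.compatible(other) and all(
            np.array_equal(self.values[n], other.values[n]) for n in self.genome.names
        )


class BlockedTrack:
    """Blocked fragment-center hotspot counts.

    Block ``j`` of a chromosome covers bases ``[block*j, block*(j+1))`` and
    holds the number of fragment centers within ``window`` bp centred on the
    block's central base. Defaults: 5-bp blocks scored from 21-bp windows.
    """

    def __init__(self, genome: GenomeModel, values: dict[str, np.ndarray],
                 block: int = 5, window: int = 21):
        if block % 2 == 0 or window % 2 == 0:
            raise ValueError("block and window sizes must be odd")
        if window < block:
            raise ValueError("window must be at least the block size")
        self.genome = genome
        self.block = int(block)
        self.window = int(window)
        self.values: dict[str, np.ndarray] = {}
        for name, length in genome.chromosomes:
            n = -(-length // block)
            v = np.asarray(values[name], dtype=float)
            if v.shape != (n,):
                raise ValueError(f"{name}: expected {n} blocks, got shape {v.shape}")
            if np.any(v < 0):
                raise ValueError(f"{name}: negative block counts")
            self.values[name] = v

    def concat(self) -> np.ndarray:
        return np.concatenate([self.values[n] for n in self.genome.names])


@dataclass(frozen=True)
class Segment:
    """A called region (HS, resistant, footprint, peak) with signed score."""

    interval: GenomicInterval
    sign: str
    score: float

    def __post_init__(self):
        if self.sign not in ("+", "-"):
            raise ValueError(f"sign must be '+' or '-', got {self.sign!r}")
        # note: sign usually matches the score's sign, but gap-merged
        # segments score the mean over member AND gap windows, which can
        # cross zero at lenient cutoffs, so no consistency check here

    @property
    def midpoint(self) -> int:
        return self.interval.midpoint


@dataclass
class SegmentSet:
    """A collection of called segments with provenance label."""

    segments: list[Segment]
    source: str = ""

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def positive(self) -> "SegmentSet":
        return SegmentSet([s for s in self.segments if s.sign == "+"], self.source)

    def negative(self) -> "SegmentSet":
        return SegmentSet([s for s in self.segments if s.sign == "-"], self.source)

    def intervals(self) -> list[GenomicInterval]:
        return [s.interval for s in self.segments]

    def total_bp(self) -> int:
        return sum(len(s.interval) for s in self.segments)
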