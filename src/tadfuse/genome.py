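"""Genome partitioning into uniform bins.

All coordinates are 0-based, half-open.  A :class:`GenomeSpec` describes
chromosome names/lengths and a bin size; a :class:`GenomicBinTable` is the
concrete bin axis shared by all matrices and tracks in a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input file or configuration violates a contract."""


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names, lengths (bp) and a uniform bin size (bp).

    Chromosome lengths must be positive multiples of ``bin_size``: ragged
    terminal bins are rejected at construction so that every bin in a run
    has identical width.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_size: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom_names", tuple(self.chrom_names))
        object.__setattr__(self, "chrom_lengths", tuple(int(x) for x in self.chrom_lengths))
        if self.bin_size <= 0:
            raise ValidationError(f"bin_size must be positive, got {self.bin_size}")
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValidationError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValidationError("duplicate chromosome names")
        for name, length in zip(self.chrom_names, self.chrom_lengths):
            if length <= 0 or length % self.bin_size != 0:
                raise ValidationError(
                    f"chromosome {name!r}: length {length} is not a positive "
                    f"multiple of bin_size {self.bin_size}"
                )

    @property
    def n_bins_per_chrom(self) -> dict[str, int]:
        return {c: l // self.bin_size for c, l in zip(self.chrom_names, self.chrom_lengths)}

    @property
    def n_bins(self) -> int:
        return sum(self.n_bins_per_chrom.values())

    def bins(self) -> "GenomicBinTable":
        return GenomicBinTable.from_spec(self)


@dataclass
class GenomicBinTable:
    """Ordered genomic bins with consecutive global ids 0..n-1.

    ``chroms``/``starts``/``ends`` are parallel arrays sorted by
    (chromosome, start).  Bins are uniform-width except, optionally, a
    wider final bin per chromosome produced by coarsening (``ragged_end``).
    """

    chroms: np.ndarray           # object array of chromosome labels
    starts: np.ndarray           # int64 bp
    ends: np.ndarray             # int64 bp
    bin_size: int
    ragged_end: bool = False
    _offsets: dict[str, tuple[int, int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise ValidationError("bin table columns differ in length")
        self._offsets = {}
        i = 0
        n = len(self.chroms)
        while i < n:
            chrom = self.chroms[i]
            j = i
            while j < n and self.chroms[j] == chrom:
                j += 1
            if chrom in self._offsets:
                raise ValidationError(f"bins for chromosome {chrom!r} are not contiguous")
            self._offsets[chrom] = (i, j - i)
            block_starts = self.starts[i:j]
            block_ends = self.ends[i:j]
            if block_starts[0] != 0:
                raise ValidationError(f"{chrom!r}: first bin does not start at 0")
            if not np.all(block_starts[1:] == block_ends[:-1]):
                raise ValidationError(f"{chrom!r}: bins are not sorted/contiguous")
            widths = block_ends - block_starts
            uniform = widths == self.bin_size
            if self.ragged_end:
                ok = np.all(uniform[:-1]) and widths[-1] >= self.bin_size
            else:
                ok = np.all(uniform)
            if not ok:
                raise ValidationError(
                    f"{chrom!r}: non-uniform bin widths (expected {self.bin_size})"
                )
            i = j

    @classmethod
    def from_spec(cls, spec: GenomeSpec) -> "GenomicBinTable":
        chroms, starts, ends = [], [], []
        for name, length in zip(spec.chrom_names, spec.chrom_lengths):
            nb = length // spec.bin_size
            chroms.extend([name] * nb)
            s = np.arange(nb, dtype=np.int64) * spec.bin_size
            starts.extend(s)
            ends.extend(s + spec.bin_size)
        return cls(np.array(chroms, dtype=object), np.array(starts), np.array(ends), spec.bin_size)

    @property
    def n_bins(self) -> int:
        return len(self.chroms)

    @property
    def chrom_names(self) -> list[str]:
        return list(self._offsets)

    def chrom_span(self, chrom: str) -> tuple[int, int]:
        """(global offset, number of bins) for a chromosome."""
        if chrom not in self._offsets:
            raise KeyError(chrom)
        return self._offsets[chrom]

    def chrom_slice(self, chrom: str) -> slice:
        off, nb = self.chrom_span(chrom)
        return slice(off, off + nb)

    def bin_id(self, chrom: str, pos: int) -> int:
        """Global id of the bin whose half-open interval contains ``pos``."""
        off, nb = self.chrom_span(chrom)
        local = pos // self.bin_size
        if self.ragged_end:
            local = min(local, nb - 1)
        if not 0 <= local < nb or pos < 0:
            raise ValidationError(f"position {chrom}:{pos} outside chromosome")
        return off + int(local)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chroms, "start": self.starts, "end": self.ends})

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, ragged_end: bool = False) -> "GenomicBinTable":
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValidationError(f"bins table needs columns {sorted(required)}")
        widths = (df["end"] - df["start"]).to_numpy()
        if len(widths) == 0:
            raise ValidationError("empty bins table")
        bin_size = int(np.min(widths))
        return cls(
            df["chrom"].to_numpy(dtype=object),
            df["start"].to_numpy(dtype=np.int64),
            df["end"].to_numpy(dtype=np.int64),
            bin_size,
            ragged_end=ragged_end,
        )

    def same_axis(self, other: "GenomicBinTable") -> bool:
        return (
            self.n_bins == other.n_bins
            and np.array_equal(self.chroms, other.chroms)
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
        )
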