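"""Genome layout: chromosome sizes tiled into fixed-size bins with GC content.

All internal coordinates are 0-based half-open; the last bin of a chromosome
may be shorter than ``bin_size``. Sex chromosomes are carried in the layout
but flagged so downstream copy-number code can mask them before
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_BIN_SIZE = 1_000_000
SEX_CHROMOSOME_NAMES = frozenset({"X", "Y", "chrX", "chrY"})


def strip_chr(name: str) -> str:
    """Normalize a chromosome name by removing a leading ``chr`` prefix."""
    return name[3:] if name.lower().startswith("chr") else name


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes tiled into contiguous fixed-size windows.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    bin_size
        Window size in bp (default 1 Mb).
    gc
        Per-bin GC fraction in [0, 1], concatenated over chromosomes in
        order. If omitted, a flat 0.41 genome-average is assumed.
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int = DEFAULT_BIN_SIZE
    gc: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("layout needs at least one chromosome")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.gc is not None:
            gc = np.asarray(self.gc, dtype=float)
            if gc.shape != (self.n_bins,):
                raise ValueError(
                    f"gc has {gc.shape[0] if gc.ndim == 1 else 'bad'} entries, "
                    f"layout has {self.n_bins} bins"
                )
            if np.any((gc < 0) | (gc > 1)):
                raise ValueError("gc fractions must lie in [0, 1]")
            object.__setattr__(self, "gc", gc)

    # -- bin bookkeeping -------------------------------------------------
    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    def n_bins_of(self, chrom: str) -> int:
        length = dict(self.chromosomes)[chrom]
        return -(-length // self.bin_size)  # ceil division

    @property
    def n_bins(self) -> int:
        return sum(self.n_bins_of(name) for name, _ in self.chromosomes)

    def chrom_offsets(self) -> dict[str, int]:
        """Global index of the first bin of each chromosome."""
        offsets: dict[str, int] = {}
        pos = 0
        for name, _ in self.chromosomes:
            offsets[name] = pos
            pos += self.n_bins_of(name)
        return offsets

    def chrom_slice(self, chrom: str) -> slice:
        start = self.chrom_offsets()[chrom]
        return slice(start, start + self.n_bins_of(chrom))

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global bin index of a 0-based position, chr-prefix tolerant."""
        chrom = self._resolve(chrom)
        length = dict(self.chromosomes)[chrom]
        if not 0 <= pos < length:
            raise ValueError(f"position {pos} outside {chrom} (len {length})")
        return self.chrom_offsets()[chrom] + pos // self.bin_size

    def _resolve(self, chrom: str) -> str:
        if chrom in dict(self.chromosomes):
            return chrom
        bare = strip_chr(chrom)
        for name, _ in self.chromosomes:
            if strip_chr(name) == bare:
                return name
        raise KeyError(f"chromosome {chrom!r} not in layout")

    def is_sex(self, chrom: str) -> bool:
        return strip_chr(chrom) in {"X", "Y"}

    @property
    def sex_mask(self) -> np.ndarray:
        """Boolean per-bin array, True on sex-chromosome bins."""
        out = np.zeros(self.n_bins, dtype=bool)
        for name, _ in self.chromosomes:
            if self.is_sex(name):
                out[self.chrom_slice(name)] = True
        return out

    @property
    def gc_filled(self) -> np.ndarray:
        if self.gc is not None:
            return self.gc
        return np.full(self.n_bins, 0.41)

    def bins(self) -> pd.DataFrame:
        """Per-bin table: chrom, start, end (0-based half-open), gc."""
        rows = []
        for name, length in self.chromosomes:
            starts = np.arange(0, length, self.bin_size)
            ends = np.minimum(starts + self.bin_size, length)
            rows.append(pd.DataFrame({"chrom": name, "start": starts, "end": ends}))
        table = pd.concat(rows, ignore_index=True)
        table["gc"] = self.gc_filled
        return table

    # -- I/O --------------------------------------------------------------
    def to_tsv(self, path) -> None:
        self.bins().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, bin_size: int | None = None) -> "GenomeLayout":
        """Rebuild a layout from a per-bin table (chrom, start, end, gc)."""
        table = pd.read_csv(path, sep="\t")
        for col in ("chrom", "start", "end"):
            if col not in table.columns:
                raise ValueError(f"layout table missing column {col!r}")
        chroms: list[tuple[str, int]] = []
        for name, sub in table.groupby("chrom", sort=False):
            chroms.append((str(name), int(sub["end"].max())))
        if bin_size is None:
            widths = table["end"] - table["start"]
            bin_size = int(widths.max())
        gc = table["gc"].to_numpy(dtype=float) if "gc" in table.columns else None
        return cls(tuple(chroms), bin_size=bin_size, gc=gc)

    @classmethod
    def synthetic(
        cls,
        n_autosomes: int = 4,
        chrom_length: int = 120_000_000,
        bin_size: int = DEFAULT_BIN_SIZE,
        gc_mean: float = 0.41,
        gc_sd: float = 0.05,
        include_sex: bool = False,
        seed: int | None = 0,
    ) -> "GenomeLayout":
        """Small synthetic genome for simulation and testing.

        GC content varies smoothly bin-to-bin (AR(1)-like walk clipped to
        [0.25, 0.65]) so that GC-bias correction has structure to remove.
        """
        chroms = [(f"chr{i + 1}", chrom_length) for i in range(n_autosomes)]
        if include_sex:
            chroms.append(("chrX", chrom_length))
        layout = cls(tuple(chroms), bin_size=bin_size)
        rng = np.random.default_rng(seed)
        gc = np.empty(layout.n_bins)
        value = gc_mean
        for i in range(layout.n_bins):
            value = gc_mean + 0.8 * (value - gc_mean) + rng.normal(0, gc_sd * 0.6)
            gc[i] = np.clip(value, 0.25, 0.65)
        return cls(tuple(chroms), bin_size=bin_size, gc=gc)
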