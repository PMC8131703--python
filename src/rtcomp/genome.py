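"""Genome binning primitives.

A genome is a fixed, ordered set of chromosomes partitioned into equal-size
bins; every 1-D quantity in this package (RT score, RIF1 score, eigenvector,
read counts) lives on those bins as a :class:`BinnedTrack`. Missing data is an
explicit boolean mask, never a silent zero, so bin coordinates stay aligned
across tracks and samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["GenomeSpec", "BinnedTrack"]


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosomes with a common bin size.

    Parameters
    ----------
    chromosomes
        Sequence of ``(name, length_in_bins)`` pairs; order is the canonical
        bin order of every track on this genome.
    bin_size
        Bin width in base pairs.
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int

    def __post_init__(self) -> None:
        chroms = tuple((str(n), int(l)) for n, l in self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        if not chroms:
            raise ValueError("genome must contain at least one chromosome")
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(l < 10 for _, l in chroms):
            raise ValueError("each chromosome must span at least 10 bins")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def n_bins(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def chrom_length(self, name: str) -> int:
        for n, l in self.chromosomes:
            if n == name:
                return l
        raise KeyError(name)

    def chrom_slices(self) -> dict[str, slice]:
        """Map chromosome name -> slice into the genome-wide bin order."""
        out: dict[str, slice] = {}
        off = 0
        for n, l in self.chromosomes:
            out[n] = slice(off, off + l)
            off += l
        return out

    def refine(self, factor: int) -> "GenomeSpec":
        """Split every bin into `factor` bins (e.g. 250 kb -> 50 kb)."""
        if factor < 1 or self.bin_size % factor != 0:
            raise ValueError("factor must divide bin_size")
        return GenomeSpec(
            tuple((n, l * factor) for n, l in self.chromosomes),
            self.bin_size // factor,
        )

    def coarsen(self, factor: int) -> "GenomeSpec":
        """Merge `factor` consecutive bins (lengths must be divisible)."""
        if any(l % factor for _, l in self.chromosomes):
            raise ValueError("factor must divide every chromosome length")
        return GenomeSpec(
            tuple((n, l // factor) for n, l in self.chromosomes),
            self.bin_size * factor,
        )


@dataclass
class BinnedTrack:
    """One scalar per genomic bin, with an explicit missing-data mask.

    ``mask[i] is True`` means bin *i* carries no value; masked entries are
    excluded from every statistic and propagate through derived tracks.
    """

    genome: GenomeSpec
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.genome.n_bins,):
            raise ValueError(
                f"track length {self.values.shape} does not match genome "
                f"({self.genome.n_bins} bins)"
            )
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool).copy()
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape mismatch")
            self.mask |= ~np.isfinite(self.values)

    @property
    def bin_size(self) -> int:
        return self.genome.bin_size

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[~self.mask]

    def n_valid(self) -> int:
        return int((~self.mask).sum())

    def chrom_view(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        sl = self.genome.chrom_slices()[name]
        return self.values[sl], self.mask[sl]

    def with_values(self, values: np.ndarray, name: str | None = None) -> "BinnedTrack":
        return BinnedTrack(
            self.genome, values, self.mask.copy(), self.name if name is None else name
        )

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(self.genome, self.values.copy(), self.mask.copy(), self.name)

    def coarsen(self, factor: int, how: str = "mean") -> "BinnedTrack":
        """Aggregate `factor` consecutive bins per chromosome.

        ``how`` is ``"mean"`` (masked-aware) or ``"sum"``. A coarse bin is
        masked only if all constituent fine bins are masked.
        """
        coarse = self.genome.coarsen(factor)
        out_vals: list[np.ndarray] = []
        out_mask: list[np.ndarray] = []
        for name, _ in self.genome.chromosomes:
            v, m = self.chrom_view(name)
            v = np.where(m, np.nan, v).reshape(-1, factor)
            import warnings as _warnings

            with np.errstate(invalid="ignore"), _warnings.catch_warnings():
                _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
                agg = np.nanmean(v, axis=1) if how == "mean" else np.nansum(v, axis=1)
            allm = m.reshape(-1, factor).all(axis=1)
            out_vals.append(np.where(allm, np.nan, agg))
            out_mask.append(allm)
        return BinnedTrack(
            coarse, np.concatenate(out_vals), np.concatenate(out_mask), self.name
        )

    def require_same_genome(self, other: "BinnedTrack") -> None:
        if self.genome != other.genome:
            raise ValueError("tracks are defined on different genomes/binnings")
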