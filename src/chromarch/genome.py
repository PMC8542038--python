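"""Genome binning specification.

A :class:`GenomeSpec` fixes the bin grid every stage works on: an ordered set
of chromosomes, each a number of bins at a single base (finest) bin size.
Coarser analysis grids (TAD and compartment resolution) are integer multiples
of the base grid obtained with :meth:`GenomeSpec.coarsened`.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ValidationError

MIN_BINS = 20


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosomes with a common bin size.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, n_bins)`` pairs. Bin indices are 0-based and
        intervals are 0-based half-open throughout the package.
    bin_size
        Base pairs per bin (> 0).
    seed
        Default seed attached to genomes created by the synthetic generator.
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "chromosomes", tuple((str(c), int(n)) for c, n in self.chromosomes))
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValidationError("chromosome names must be unique")
        if self.bin_size <= 0:
            raise ValidationError("bin_size must be positive")
        for name, n in self.chromosomes:
            if n < MIN_BINS:
                raise ValidationError(f"chromosome {name!r} has {n} bins; need >= {MIN_BINS}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    def n_bins(self, chrom: str) -> int:
        for name, n in self.chromosomes:
            if name == chrom:
                return n
        raise ValidationError(f"unknown chromosome {chrom!r}")

    @property
    def total_bins(self) -> int:
        return sum(n for _, n in self.chromosomes)

    def offsets(self) -> dict[str, int]:
        """Global fine-bin offset of each chromosome's first bin."""
        out, acc = {}, 0
        for name, n in self.chromosomes:
            out[name] = acc
            acc += n
        return out

    def locate(self, global_bin: int) -> tuple[str, int]:
        """Map a global bin index to (chromosome, local bin)."""
        if global_bin < 0:
            raise ValidationError(f"negative bin index {global_bin}")
        acc = 0
        for name, n in self.chromosomes:
            if global_bin < acc + n:
                return name, global_bin - acc
            acc += n
        raise ValidationError(f"bin index {global_bin} beyond genome ({acc} bins)")

    def coarsened(self, factor: int) -> "GenomeSpec":
        """Spec at ``factor`` times coarser bins; bin counts must divide evenly."""
        if factor < 1:
            raise ValidationError("coarsening factor must be >= 1")
        if factor == 1:
            return self
        chroms = []
        for name, n in self.chromosomes:
            if n % factor:
                raise ValidationError(f"chromosome {name!r}: {n} bins not divisible by {factor}")
            chroms.append((name, n // factor))
        return GenomeSpec(tuple(chroms), self.bin_size * factor, self.seed)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"chromosomes": list(self.chromosomes), "bin_size": self.bin_size, "seed": self.seed},
            indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GenomeSpec":
        d = json.loads(Path(path).read_text())
        return cls(tuple((c, n) for c, n in d["chromosomes"]), d["bin_size"], d.get("seed", 0))
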