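"""Genome layout: chromosome sizes and centromere positions.

All coordinates are 0-based half-open. The p-arm of a chromosome is
``[0, centromere)`` and the q-arm is ``[centromere, length)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths and centromere positions (bp)."""

    chromosomes: tuple[tuple[str, int], ...]
    centromeres: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        cen = dict(self.centromeres)
        if set(cen) != set(names):
            raise ValueError("centromeres must be given for exactly the chromosomes")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
            if not 0 < cen[name] < length:
                raise ValueError(f"centromere of {name} outside (0, length)")

    # -- lookups ---------------------------------------------------------
    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    def length(self, chrom: str) -> int:
        for name, ln in self.chromosomes:
            if name == chrom:
                return ln
        raise KeyError(chrom)

    def centromere(self, chrom: str) -> int:
        for name, pos in self.centromeres:
            if name == chrom:
                return pos
        raise KeyError(chrom)

    def arm(self, chrom: str, which: str) -> tuple[int, int]:
        """Half-open bp bounds of arm ``"p"`` or ``"q"``."""
        cen = self.centromere(chrom)
        if which == "p":
            return 0, cen
        if which == "q":
            return cen, self.length(chrom)
        raise ValueError(f"unknown arm {which!r}")

    def chrom_index(self, chrom: str) -> int:
        return self.names.index(chrom)

    def total_length(self) -> int:
        return sum(ln for _, ln in self.chromosomes)

    # -- construction / IO ----------------------------------------------
    @classmethod
    def from_lengths(
        cls, lengths: Mapping[str, int] | Iterable[tuple[str, int]],
        centromeres: Mapping[str, int],
    ) -> "GenomeLayout":
        items = tuple(lengths.items()) if isinstance(lengths, Mapping) else tuple(lengths)
        return cls(items, tuple((n, centromeres[n]) for n, _ in items))

    @classmethod
    def default_toy(cls, n_chroms: int = 5, length: int = 100_000_000,
                    centromere: int = 40_000_000) -> "GenomeLayout":
        """Desk-scale genome: ``n_chroms`` chromosomes of ``length`` bp each."""
        names = [f"chr{i + 1}" for i in range(n_chroms)]
        return cls(tuple((n, length) for n in names),
                   tuple((n, centromere) for n in names))

    def to_frame(self) -> pd.DataFrame:
        cen = dict(self.centromeres)
        return pd.DataFrame(
            {"chrom": self.names,
             "length": [ln for _, ln in self.chromosomes],
             "centromere": [cen[n] for n in self.names]}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenomeLayout":
        return cls(tuple(zip(df["chrom"], df["length"].astype(int))),
                   tuple(zip(df["chrom"], df["centromere"].astype(int))))

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "GenomeLayout":
        return cls.from_frame(pd.read_csv(path, sep="\t"))
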