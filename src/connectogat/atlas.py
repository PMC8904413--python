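"""Brain parcellation metadata.

Graph nodes are regions of a fixed anatomical parcellation. The bundled
default is the 86-region Desikan-Killiany table (68 cortical + 18
subcortical regions), the standard FreeSurfer whole-brain node set used
in connectome studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

_HEMISPHERES = {"left", "right", "none"}
_CLASSES = {"cortical", "subcortical"}


@dataclass(frozen=True)
class Region:
    index: int
    name: str
    hemisphere: str
    region_class: str


@dataclass(frozen=True)
class AtlasParcellation:
    """Ordered node table: one row per brain region.

    Region indices must be contiguous 0..n-1; the index order fixes the
    row/column order of every connectivity matrix and feature matrix.
    """

    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        idx = [r.index for r in self.regions]
        if idx != list(range(len(idx))):
            raise ValueError("region indices must be contiguous 0..n-1")
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        for r in self.regions:
            if r.hemisphere not in _HEMISPHERES:
                raise ValueError(f"bad hemisphere {r.hemisphere!r} for {r.name}")
            if r.region_class not in _CLASSES:
                raise ValueError(f"bad class {r.region_class!r} for {r.name}")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def cortical_mask(self) -> list[bool]:
        return [r.region_class == "cortical" for r in self.regions]

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "AtlasParcellation":
        required = {"index", "name", "hemisphere", "class"}
        if not required.issubset(df.columns):
            raise ValueError(f"atlas table needs columns {sorted(required)}")
        df = df.sort_values("index")
        regions = tuple(
            Region(int(r["index"]), str(r["name"]), str(r["hemisphere"]), str(r["class"]))
            for _, r in df.iterrows()
        )
        return cls(regions)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AtlasParcellation":
        return cls.from_table(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "index": [r.index for r in self.regions],
                "name": [r.name for r in self.regions],
                "hemisphere": [r.hemisphere for r in self.regions],
                "class": [r.region_class for r in self.regions],
            }
        ).to_csv(path, sep="\t", index=False)


def default_atlas() -> AtlasParcellation:
    """The bundled 86-region Desikan-Killiany parcellation."""
    with resources.files("connectogat.data").joinpath("dk86.tsv").open() as f:
        atlas = AtlasParcellation.from_table(pd.read_csv(f, sep="\t"))
    return atlas


def make_toy_atlas(n: int) -> AtlasParcellation:
    """A generic n-region parcellation for simulations at reduced scale."""
    regions = tuple(
        Region(i, f"region{i:03d}", "left" if i % 2 == 0 else "right", "cortical")
        for i in range(n)
    )
    return AtlasParcellation(regions)
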