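"""The 90-region AAL cortical/subcortical parcellation used as network nodes.

The atlas ships as a plain TSV resource: 45 base regions, each split into
left/right hemispheres, indexed 1-90. Region abbreviations (SFGdor_l, THA_r,
...) label rows/columns of every connectivity matrix downstream.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import pandas as pd

N_REGIONS = 90


@dataclass(frozen=True)
class ROIAtlas:
    """Ordered region table: index (1-based), full name, abbreviation, hemisphere."""

    table: pd.DataFrame

    def __post_init__(self):
        required = {"index", "name", "abbrev", "hemisphere"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"atlas table missing columns {required - set(self.table.columns)}")
        if len(self.table) != N_REGIONS:
            raise ValueError(f"expected {N_REGIONS} regions, got {len(self.table)}")
        if self.table["abbrev"].duplicated().any():
            dupes = self.table["abbrev"][self.table["abbrev"].duplicated()].tolist()
            raise ValueError(f"duplicate region abbreviations: {dupes}")

    @property
    def abbrevs(self) -> list[str]:
        return self.table["abbrev"].tolist()

    @property
    def names(self) -> list[str]:
        return self.table["name"].tolist()

    def __len__(self) -> int:
        return len(self.table)


def load_atlas() -> ROIAtlas:
    """Load the packaged 90-region AAL label table."""
    ref = importlib.resources.files("cortexnets.data").joinpath("aal90.tsv")
    with importlib.resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t")
    return ROIAtlas(table=table)
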