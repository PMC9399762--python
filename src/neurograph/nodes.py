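"""AAL-90 node table: 90 brain regions (78 cortical + 12 subcortical).

Node order is fixed to the 90-region automated anatomical labeling (AAL)
parcellation, 1-based indices in all user-facing files (e.g. Frontal_Mid_L
is index 7, Insula_R is 30, Temporal_Sup_R is 82).  Internal arrays are
0-based; conversion happens at the I/O boundary.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

N_REGIONS = 90
N_CORTICAL = 78
N_SUBCORTICAL = 12

REQUIRED_COLUMNS = ("aal_index", "name", "hemisphere", "tissue", "lobe")


@dataclass(frozen=True)
class NodeTable:
    """Validated 90-row region table (AAL index, name, hemisphere, tissue, lobe)."""

    frame: pd.DataFrame

    @property
    def names(self) -> list[str]:
        return self.frame["name"].tolist()

    def name_of(self, aal_index: int) -> str:
        """Region name for a 1-based AAL index."""
        return self.frame.set_index("aal_index").loc[aal_index, "name"]

    def index_of(self, name: str) -> int:
        """1-based AAL index for a region name."""
        row = self.frame[self.frame["name"] == name]
        if row.empty:
            raise KeyError(f"unknown region name: {name!r}")
        return int(row["aal_index"].iloc[0])


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"node table missing columns: {missing}")
    if len(df) != N_REGIONS:
        raise ValueError(f"node table must have exactly {N_REGIONS} rows, got {len(df)}")
    idx = df["aal_index"].to_numpy()
    if sorted(idx.tolist()) != list(range(1, N_REGIONS + 1)):
        raise ValueError("aal_index must be the unique consecutive integers 1..90")
    if df["name"].duplicated().any():
        dups = df.loc[df["name"].duplicated(), "name"].tolist()
        raise ValueError(f"duplicate region names: {dups}")
    n_cort = int((df["tissue"] == "cortical").sum())
    n_sub = int((df["tissue"] == "subcortical").sum())
    if (n_cort, n_sub) != (N_CORTICAL, N_SUBCORTICAL):
        raise ValueError(
            f"expected {N_CORTICAL} cortical + {N_SUBCORTICAL} subcortical regions, "
            f"got {n_cort} + {n_sub}"
        )
    return df.sort_values("aal_index").reset_index(drop=True)


def load_node_table(path: str | Path | None = None) -> NodeTable:
    """Load and validate a node table; the bundled AAL-90 table by default."""
    if path is None:
        ref = importlib.resources.files("neurograph") / "data" / "aal90_nodes.csv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    return NodeTable(_validate(df))
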