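"""Hierarchical HDF5 results store.

All pipeline outputs are aggregated into one HDF5 file holding named
tables (pandas/pytables fixed format so tables round-trip identically):

    /abund/depth       specimen x gene sequencing depth
    /abund/rel         specimen x gene relative abundance
    /cags/partition    gene_id -> cag_id table
    /cags/abund        specimen x CAG proportional abundance
    /stats/cag_fits    per-CAG beta-binomial coefficients, p and q
    /stats/aggregates  taxon/function-level errors-in-response results
    /islands/records   detected island coordinates (only when genomes given)
    /meta/params       every parameter and seed used for the run
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

TABLE_KEYS = [
    "/abund/depth",
    "/abund/rel",
    "/cags/partition",
    "/cags/abund",
    "/stats/cag_fits",
    "/stats/aggregates",
    "/islands/records",
    "/meta/params",
]


class ResultsStore:
    """Thin wrapper over pandas.HDFStore with a fixed key layout."""

    def __init__(self, path: str | Path, mode: str = "a"):
        self.path = Path(path)
        self.mode = mode

    def write_table(self, key: str, table: pd.DataFrame) -> None:
        with pd.HDFStore(self.path, mode="a") as store:
            store.put(key, table, format="fixed")

    def read_table(self, key: str) -> pd.DataFrame:
        with pd.HDFStore(self.path, mode="r") as store:
            return store.get(key)

    def keys(self) -> list[str]:
        with pd.HDFStore(self.path, mode="r") as store:
            return sorted(store.keys())

    def __contains__(self, key: str) -> bool:
        return key in self.keys()

    def write_params(self, params: dict) -> None:
        """Record run parameters/seeds as a one-column table of JSON-encoded values."""
        tab = pd.DataFrame(
            {"value": [json.dumps(v, sort_keys=True) for v in params.values()]},
            index=pd.Index(list(params), name="param"),
        )
        self.write_table("/meta/params", tab)

    def read_params(self) -> dict:
        tab = self.read_table("/meta/params")
        return {k: json.loads(v) for k, v in tab["value"].items()}
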