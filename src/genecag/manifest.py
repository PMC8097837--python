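"""Specimen manifest parsing.

The manifest is a CSV with columns "specimen", "R1", "R2" plus arbitrary
covariate columns used by the statistical formula. A specimen may span
multiple rows (multiple FASTQ file pairs); its covariates must agree
across those rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

REQUIRED_COLUMNS = ["specimen", "R1", "R2"]


@dataclass
class Manifest:
    rows: pd.DataFrame  # one row per file pair
    covariates: pd.DataFrame  # one row per specimen, indexed by specimen

    @property
    def specimens(self) -> list[str]:
        return list(self.covariates.index)

    def file_pairs(self, specimen: str) -> list[tuple[str, str]]:
        sub = self.rows[self.rows["specimen"] == specimen]
        return list(zip(sub["R1"], sub["R2"]))


def parse_manifest(path: str | Path) -> Manifest:
    rows = pd.read_csv(path, dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"manifest missing required column(s): {missing}")
    if rows["specimen"].isna().any() or (rows["specimen"].str.len() == 0).any():
        raise ValueError("manifest contains an empty specimen name")
    if rows.duplicated(subset=["specimen", "R1"]).any():
        dup = rows[rows.duplicated(subset=["specimen", "R1"])]
        raise ValueError(
            f"duplicate (specimen, R1) pair(s) in manifest: {dup[['specimen', 'R1']].values.tolist()[:3]}"
        )
    cov_cols = [c for c in rows.columns if c not in ("R1", "R2")]
    cov = rows[cov_cols].drop_duplicates()
    if cov["specimen"].duplicated().any():
        bad = cov.loc[cov["specimen"].duplicated(), "specimen"].tolist()
        raise ValueError(f"inconsistent covariates across rows of specimen(s): {bad[:5]}")
    covariates = cov.set_index("specimen")
    return Manifest(rows=rows, covariates=covariates)
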