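"""Tabular IO and run configuration.

All feature tables are tab-separated text with a header row and row labels,
decimal point ".", and "NA" as the missing-value token — the dominant
convention for microbiome feature tables. Orientation is always declared
explicitly (silent transposition is the classic feature-table bug); tables
are normalized to samples-as-rows in memory.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml


def read_matrix(path, orientation: str = "samples_as_rows") -> pd.DataFrame:
    """Read a TSV feature table, strictly numeric, normalized to
    samples-as-rows. Duplicate sample ids or non-numeric cells are errors
    (the offending row/column is named)."""
    if orientation not in ("samples_as_rows", "samples_as_cols"):
        raise ValueError(f"unknown orientation: {orientation}")
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False,
        dtype=str,
    )
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row labels in {path}: {dups}")
    if pd.Index(df.columns).duplicated().any():
        raise ValueError(f"duplicate column labels in {path}")
    out = {}
    for col in df.columns:
        try:
            out[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad[0] if len(bad) else "?"
            raise ValueError(
                f"non-numeric value in {path} at row {row!r}, column {col!r}"
            ) from None
    df = pd.DataFrame(out, index=df.index)
    if orientation == "samples_as_cols":
        df = df.T
    if df.index.duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")
    df.index.name = "sample_id"
    return df


def write_matrix(table: pd.DataFrame, path) -> None:
    """Write a samples-as-rows table as TSV at full float precision
    (12 significant digits), NaN as "NA"."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", na_rep="NA", float_format="%.12g",
                 index_label=table.index.name or "sample_id")


@dataclass
class RunConfig:
    """Flat, typed configuration of one pipeline run.

    Input paths are optional; any missing input is generated by the
    synthetic cohort generator under the run seed.
    """

    # inputs (None -> simulate)
    gene_matrix: str | None = None
    genus_counts: str | None = None
    species_counts: str | None = None
    hmo_peaks: str | None = None
    hmo_sample_info: str | None = None
    metadata: str | None = None
    marker_panel: str | None = None
    # thresholds
    theta_full: float = 0.9
    theta_partial: float = 0.25
    coverage_presence_threshold: float = 0.0
    corr_threshold: float = 0.2
    prevalence_min: float = 0.25
    top_n_taxa: int = 20
    # DMM
    K_min: int = 1
    K_max: int = 4
    n_restarts: int = 2
    dmm_max_iter: int = 300
    # misc
    pseudo_total: int = 10000
    seed: int = 0
    n_infants: int = 105
    n_milk: int = 90
    n_perm: int = 999
    out_dir: str = "results"

    def __post_init__(self):
        if not (0 < self.theta_partial < self.theta_full <= 1):
            raise ValueError("need 0 < theta_partial < theta_full <= 1")
        if self.K_min < 1 or self.K_max < self.K_min:
            raise ValueError("K range must be non-empty with K_min >= 1")
        if self.pseudo_total < 100:
            raise ValueError("pseudo_total must be >= 100")
        if self.coverage_presence_threshold < 0:
            raise ValueError("coverage_presence_threshold must be >= 0")
        if not 0 <= self.corr_threshold <= 1:
            raise ValueError("corr_threshold must lie in [0, 1]")

    @property
    def K_range(self) -> range:
        return range(self.K_min, self.K_max + 1)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
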