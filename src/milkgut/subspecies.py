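"""B. longum subspecies typing from pangenome marker-gene presence.

B. longum subsp. infantis carries a conserved cluster of HMO import and
metabolism genes (Blon_2331-Blon_2361) that subsp. longum lacks; subsp.
longum instead carries the arabinose-utilization genes araA and araD, absent
from infantis genomes. A metagenome's B. longum population is therefore
stratified by the detected fraction of HMO-cluster genes (f_hmo) and by
ara-gene detection:

    EXCLUSIVE_INFANTIS   f_hmo >= theta_full,               no ara
    PUTATIVE_INFANTIS    theta_partial <= f_hmo < theta_full, no ara
    COEXISTENCE          f_hmo >= theta_partial,            ara present
    EXCLUSIVE_LONGUM     f_hmo < theta_partial,             ara present
    UNCLASSIFIED         f_hmo < theta_partial,             no ara

The thresholds are configurable (the source analyses describe "almost all"
and "partial" cluster detection rather than numbers; defaults 0.9 / 0.25).
An accessory quorum statistic reports, among HMO-cluster-positive samples,
the fraction carrying at least two of the three LNT transporter genes
(Blon_2175-2177).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
import yaml
from scipy.cluster import hierarchy


class SubspeciesClass(str, Enum):
    EXCLUSIVE_INFANTIS = "EXCLUSIVE_INFANTIS"
    PUTATIVE_INFANTIS = "PUTATIVE_INFANTIS"
    COEXISTENCE = "COEXISTENCE"
    EXCLUSIVE_LONGUM = "EXCLUSIVE_LONGUM"
    UNCLASSIFIED = "UNCLASSIFIED"


INFANTIS_POSITIVE = frozenset(
    {
        SubspeciesClass.EXCLUSIVE_INFANTIS,
        SubspeciesClass.PUTATIVE_INFANTIS,
        SubspeciesClass.COEXISTENCE,
    }
)


@dataclass(frozen=True)
class MarkerPanel:
    """Marker gene families for subspecies typing.

    Gene ids are free strings so that locus tags or pangenome family ids can
    be supplied interchangeably via the panel file.
    """

    hmo_cluster: tuple
    ara_genes: tuple = ("araA", "araD")
    lnt_genes: tuple = ("Blon_2175", "Blon_2176", "Blon_2177")

    def __post_init__(self):
        if len(self.hmo_cluster) == 0:
            raise ValueError("hmo_cluster must be non-empty")
        hmo = set(self.hmo_cluster)
        if hmo & set(self.ara_genes) or hmo & set(self.lnt_genes):
            raise ValueError("hmo_cluster must be disjoint from ara and lnt genes")
        if len(self.ara_genes) != 2:
            raise ValueError("ara_genes must be exactly two genes (araA, araD)")
        if len(self.lnt_genes) != 3:
            raise ValueError("lnt_genes must be exactly three genes")

    @classmethod
    def default(cls) -> "MarkerPanel":
        """Blon_2331..Blon_2361 HMO cluster, araA/araD, Blon_2175-2177."""
        return cls(hmo_cluster=tuple(f"Blon_{i}" for i in range(2331, 2362)))

    @classmethod
    def from_file(cls, path) -> "MarkerPanel":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            hmo_cluster=tuple(d["hmo_cluster"]),
            ara_genes=tuple(d.get("ara_genes", ("araA", "araD"))),
            lnt_genes=tuple(d.get("lnt_genes", ("Blon_2175", "Blon_2176", "Blon_2177"))),
        )

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "hmo_cluster": list(self.hmo_cluster),
                    "ara_genes": list(self.ara_genes),
                    "lnt_genes": list(self.lnt_genes),
                },
                fh,
            )

    @property
    def all_genes(self) -> tuple:
        return tuple(self.hmo_cluster) + tuple(self.ara_genes) + tuple(self.lnt_genes)


@dataclass
class SubspeciesCall:
    sample_id: str
    f_hmo: float
    ara_present: bool
    lnt_count: int
    subspecies_class: SubspeciesClass


def binarize(matrix: pd.DataFrame, presence_threshold: float = 0.0) -> pd.DataFrame:
    """Gene coverage -> presence. Entry 1 iff coverage >= threshold for a
    positive threshold; with threshold 0 presence means coverage > 0, so a
    0/1 matrix passes through unchanged."""
    if presence_threshold < 0:
        raise ValueError("presence_threshold must be >= 0")
    X = np.asarray(matrix, dtype=float)
    if np.any(X < 0):
        raise ValueError("negative coverage value")
    if presence_threshold == 0:
        B = (X > 0).astype(int)
    else:
        B = (X >= presence_threshold).astype(int)
    return pd.DataFrame(B, index=matrix.index, columns=matrix.columns)


def _panel_presence(presence_row: pd.Series, genes) -> np.ndarray:
    """Presence bits for the requested genes; a gene missing from the matrix
    counts as absent (coverage 0)."""
    return np.array([int(presence_row.get(g, 0) > 0) for g in genes])


def classify_sample(
    presence: pd.Series,
    panel: MarkerPanel,
    theta_full: float = 0.9,
    theta_partial: float = 0.25,
    ara_rule: str = "both",
) -> SubspeciesCall:
    """Classify one sample from its marker presence bits (rule table in the
    module docstring). ``ara_rule`` 'both' (conservative default: araA and
    araD are jointly diagnostic of subsp. longum) or 'any'."""
    if not (0 < theta_partial < theta_full <= 1):
        raise ValueError("need 0 < theta_partial < theta_full <= 1")
    if ara_rule not in ("both", "any"):
        raise ValueError("ara_rule must be 'both' or 'any'")
    if not any(g in presence.index for g in panel.all_genes):
        raise ValueError("presence vector has none of the panel genes")
    hmo_bits = _panel_presence(presence, panel.hmo_cluster)
    ara_bits = _panel_presence(presence, panel.ara_genes)
    lnt_bits = _panel_presence(presence, panel.lnt_genes)
    f_hmo = float(hmo_bits.mean())
    ara_present = bool(ara_bits.all()) if ara_rule == "both" else bool(ara_bits.any())
    if ara_present:
        cls = (
            SubspeciesClass.COEXISTENCE
            if f_hmo >= theta_partial
            else SubspeciesClass.EXCLUSIVE_LONGUM
        )
    elif f_hmo >= theta_full:
        cls = SubspeciesClass.EXCLUSIVE_INFANTIS
    elif f_hmo >= theta_partial:
        cls = SubspeciesClass.PUTATIVE_INFANTIS
    else:
        cls = SubspeciesClass.UNCLASSIFIED
    name = presence.name if presence.name is not None else ""
    return SubspeciesCall(str(name), f_hmo, ara_present, int(lnt_bits.sum()), cls)


def classify_all(
    presence: pd.DataFrame,
    panel: MarkerPanel,
    theta_full: float = 0.9,
    theta_partial: float = 0.25,
    ara_rule: str = "both",
) -> pd.DataFrame:
    """Classify every sample; returns a tidy calls table."""
    calls = [
        classify_sample(presence.loc[s], panel, theta_full, theta_partial, ara_rule)
        for s in presence.index
    ]
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "f_hmo": [c.f_hmo for c in calls],
            "ara_present": [c.ara_present for c in calls],
            "lnt_count": [c.lnt_count for c in calls],
            "subspecies_class": [c.subspecies_class.value for c in calls],
        }
    )


def lnt_transporter_stat(
    presence: pd.DataFrame,
    panel: MarkerPanel,
    min_genes: int = 2,
    theta_full: float = 0.9,
    theta_partial: float = 0.25,
    ara_rule: str = "both",
) -> float:
    """Among HMO-cluster-positive samples (exclusive/putative infantis or
    coexistence), the fraction carrying >= ``min_genes`` of the three LNT
    transporter genes."""
    calls = classify_all(presence, panel, theta_full, theta_partial, ara_rule)
    eligible = calls[calls.subspecies_class.isin(c.value for c in INFANTIS_POSITIVE)]
    if eligible.empty:
        raise ValueError("no HMO-cluster-positive samples; statistic undefined")
    return float((eligible.lnt_count >= min_genes).mean())


def cluster_samples(presence: pd.DataFrame, panel: MarkerPanel | None = None):
    """Complete-linkage hierarchical clustering (Euclidean distance) of the
    samples' 0/1 marker profiles, as used for marker-heatmap sample ordering.

    Samples are pre-sorted lexicographically by id so the merge order (and
    hence the leaf order) is reproducible under input reordering. Returns
    ``(linkage_matrix, leaf_order)`` with leaf_order a list of sample ids;
    a single sample yields ``(None, [that id])``.
    """
    if panel is not None:
        cols = [g for g in panel.all_genes if g in presence.columns]
        if not cols:
            raise ValueError("no panel genes found in the matrix")
        presence = presence[cols]
    presence = presence.sort_index()
    if presence.shape[0] < 2:
        return None, list(presence.index)
    Z = hierarchy.linkage(presence.to_numpy(dtype=float), method="complete",
                          metric="euclidean")
    order = [presence.index[i] for i in hierarchy.leaves_list(Z)]
    return Z, order


def crosstab_subspecies(calls: pd.DataFrame, grouping) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Contingency table of subspecies class by an external grouping (GMC
    type, cohort, ...) plus row-normalized percentages."""
    grouping = pd.Series(grouping)
    if len(grouping) != len(calls):
        raise ValueError("grouping length does not match the number of calls")
    counts = pd.crosstab(grouping.to_numpy(), calls["subspecies_class"].to_numpy())
    counts.index.name = "group"
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return counts, pct
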