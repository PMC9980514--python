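"""Human-milk oligosaccharide (HMO) quantification and Se/Le milk typing.

Capillary-electrophoresis peak areas are quantified against a per-sample
noise level and internal standard (IS): SNR = raw_area / noise. Peaks with
SNR >= 10 (LOQ) get an IS-normalized peak area nPA = 100 * raw_area /
is_area; peaks between LOD (SNR 3) and LOQ are replaced by the LOQ-equivalent
nPA divided by sqrt(2) (triangular-distribution assumption); peaks below LOD
are absent (nPA 0).

Maternal secretor status is read off the alpha1-2-fucosylated markers
(2'-FL, DFL, LNFP I) and Lewis status off the alpha1-4-fucosylated markers
(LNFP II, LNDFH II); their 2x2 combination defines HM groups I (Se+Le+),
II (Se-Le+), III (Se+Le-), IV (Se-Le-).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as _stats

ABOVE_LOQ = "ABOVE_LOQ"
IMPUTED_LOD_LOQ = "IMPUTED_LOD_LOQ"
ABSENT = "ABSENT"

SE_MARKERS = ("2'-FL", "DFL", "LNFP I")
LE_MARKERS = ("LNFP II", "LNDFH II")

_GROUP_TABLE = {
    (True, True): "I",
    (False, True): "II",
    (True, False): "III",
    (False, False): "IV",
}


@dataclass
class QuantifiedHMOTable:
    """Per (sample, peak) nPA values and quantification status.

    ``long``: columns sample_id, peak_label, raw_area, snr, npa, status.
    """

    long: pd.DataFrame

    def npa_wide(self) -> pd.DataFrame:
        return self.long.pivot_table(
            index="sample_id", columns="peak_label", values="npa", fill_value=0.0,
            aggfunc="first",
        )

    def status_wide(self) -> pd.DataFrame:
        w = self.long.pivot(index="sample_id", columns="peak_label", values="status")
        return w.fillna(ABSENT)


def quantify_peaks(
    peaks: pd.DataFrame,
    sample_info: pd.DataFrame,
    snr_loq: float = 10.0,
    snr_lod: float = 3.0,
) -> QuantifiedHMOTable:
    """SNR-gated quantification of raw peak areas.

    peaks: long table (sample_id, peak_label, raw_area);
    sample_info: per-sample noise_level and is_area (indexed by sample_id or
    with a sample_id column).
    """
    if not snr_lod < snr_loq:
        raise ValueError("need snr_lod < snr_loq")
    info = sample_info.set_index("sample_id") if "sample_id" in sample_info.columns else sample_info
    if (info["noise_level"] <= 0).any():
        raise ValueError("noise_level must be positive for every sample")
    if (info["is_area"] <= 0).any():
        raise ValueError("is_area must be positive for every sample")
    df = peaks.copy()
    if (df["raw_area"] < 0).any():
        raise ValueError("raw peak areas must be non-negative")
    if df.duplicated(["sample_id", "peak_label"]).any():
        raise ValueError("duplicate peak label within a sample")
    missing = set(df["sample_id"]) - set(info.index)
    if missing:
        raise ValueError(f"samples without noise/IS information: {sorted(missing)}")
    noise = info["noise_level"].reindex(df["sample_id"]).to_numpy(dtype=float)
    is_area = info["is_area"].reindex(df["sample_id"]).to_numpy(dtype=float)
    area = df["raw_area"].to_numpy(dtype=float)
    snr = area / noise
    npa = np.zeros(len(df))
    status = np.full(len(df), ABSENT, dtype=object)
    above = snr >= snr_loq
    npa[above] = 100.0 * area[above] / is_area[above]
    status[above] = ABOVE_LOQ
    between = (snr >= snr_lod) & ~above
    # LOQ-equivalent area is snr_loq * noise; imputed at LOQ / sqrt(2)
    npa[between] = 100.0 * (snr_loq * noise[between]) / is_area[between] / np.sqrt(2.0)
    status[between] = IMPUTED_LOD_LOQ
    out = df.loc[:, ["sample_id", "peak_label", "raw_area"]].copy()
    out["snr"] = snr
    out["npa"] = npa
    out["status"] = status
    return QuantifiedHMOTable(long=out)


def assign_hm_group(
    quant: QuantifiedHMOTable | pd.DataFrame,
    se_markers=SE_MARKERS,
    le_markers=LE_MARKERS,
    se_quorum: int = 2,
    le_quorum: int = 1,
    presence_status=(ABOVE_LOQ,),
) -> pd.DataFrame:
    """Secretor/Lewis phenotype and HM group per sample.

    A sample is secretor-positive when at least ``se_quorum`` of the Se
    marker HMOs have a status in ``presence_status`` (default: confidently
    quantified, i.e. above LOQ), and Lewis-positive analogously with
    ``le_quorum``. A marker absent from the table counts as ABSENT.
    """
    if se_quorum > len(se_markers):
        raise ValueError("se_quorum exceeds the number of Se markers")
    if le_quorum > len(le_markers):
        raise ValueError("le_quorum exceeds the number of Le markers")
    status = quant.status_wide() if isinstance(quant, QuantifiedHMOTable) else quant
    for m in tuple(se_markers) + tuple(le_markers):
        if m not in status.columns:
            status = status.copy()
            status[m] = ABSENT
    present = status.isin(set(presence_status))
    se = present[list(se_markers)].sum(axis=1) >= se_quorum
    le = present[list(le_markers)].sum(axis=1) >= le_quorum
    group = [_GROUP_TABLE[(bool(s), bool(l))] for s, l in zip(se, le)]
    return pd.DataFrame(
        {
            "sample_id": status.index,
            "secretor": se.to_numpy(),
            "lewis": le.to_numpy(),
            "group": group,
        }
    ).reset_index(drop=True)


def summarize_hm_groups(calls: pd.DataFrame) -> pd.DataFrame:
    """Cohort prevalence rollup of HM group calls.

    Returns one row per group I-IV (count, percent at 0.1% resolution) plus
    rollup rows for secretor-positive (I+III) and Lewis-positive (I+II)
    at 1% resolution, mirroring how such cohorts are usually reported.
    """
    if len(calls) == 0:
        raise ValueError("no HM group calls")
    n = len(calls)
    counts = calls["group"].value_counts()
    rows = []
    for g in ("I", "II", "III", "IV"):
        c = int(counts.get(g, 0))
        rows.append({"category": f"group_{g}", "count": c,
                     "percent": round(100.0 * c / n, 1)})
    se_count = int(calls["secretor"].sum())
    le_count = int(calls["lewis"].sum())
    rows.append({"category": "secretor_positive", "count": se_count,
                 "percent": float(round(100.0 * se_count / n))})
    rows.append({"category": "lewis_positive", "count": le_count,
                 "percent": float(round(100.0 * le_count / n))})
    return pd.DataFrame(rows)


def compare_hmo_groups(npa: pd.DataFrame, grouping) -> pd.DataFrame:
    """Differential HMO abundance across a sample grouping.

    Two levels -> Mann-Whitney per HMO; three or more -> Kruskal-Wallis.
    BH-FDR across the HMO family; per-group medians reported. ``grouping``
    is aligned positionally with the rows of the nPA matrix.
    """
    g = pd.Series(list(grouping), index=npa.index)
    levels = pd.unique(g)
    if len(levels) < 2:
        raise ValueError("grouping must have >= 2 levels")
    if any((g == lv).sum() == 0 for lv in levels):
        raise ValueError("empty group level")
    rows = []
    for hmo in npa.columns:
        vals = npa[hmo].to_numpy(dtype=float)
        if len(levels) == 2:
            stat, p = _stats.mann_whitney(vals[(g == levels[0]).to_numpy()],
                                          vals[(g == levels[1]).to_numpy()])
            test = "mann_whitney"
        else:
            stat, p = _stats.kruskal_wallis(vals, g.to_numpy())
            test = "kruskal_wallis"
        row = {"feature": hmo, "test": test, "statistic": stat, "p": p}
        for lv in levels:
            row[f"median_{lv}"] = float(np.median(vals[(g == lv).to_numpy()]))
        rows.append(row)
    out = pd.DataFrame(rows)
    out["q"] = _stats.bh_fdr(out["p"].to_numpy())
    return out
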