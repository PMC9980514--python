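"""End-to-end orchestration: from an input bundle (read from disk or
simulated with planted truth) to the full set of report tables.

Artifacts written to ``config.out_dir``:

1. ``subspecies_calls.tsv``      per-metagenome B. longum subspecies calls
2. ``gmc_assignments.tsv``       DMM community-type assignments (+ Laplace curve)
3. ``hm_group_calls.tsv``        milk Se/Le phenotypes (+ prevalence rollup)
4. ``diversity.tsv``             rarefied alpha diversity per sample
5. ``association_tables.tsv``    pH/age/calprotectin by GMC; HMOs by secretor
6. ``network_edges.tsv``         thresholded SparCC species network
7. ``crosstab_subspecies_gmc.tsv`` subspecies class x GMC type (+ pH by GMC)

Deterministic for a fixed config + seed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import community, hmo, simulate, stats, subspecies
from .io import RunConfig, read_matrix, write_matrix

log = logging.getLogger("milkgut")

ARTIFACTS = (
    "subspecies_calls.tsv",
    "gmc_assignments.tsv",
    "hm_group_calls.tsv",
    "diversity.tsv",
    "association_tables.tsv",
    "network_edges.tsv",
    "crosstab_subspecies_gmc.tsv",
)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def load_bundle(config: RunConfig) -> simulate.SimulatedBundle:
    """Read configured inputs; simulate any that are missing."""
    sim = simulate.simulate_all(
        n_infants=config.n_infants, n_milk=config.n_milk, seed=config.seed
    )
    if config.gene_matrix:
        sim.gene_coverage = read_matrix(config.gene_matrix)
    if config.genus_counts:
        sim.genus_counts = read_matrix(config.genus_counts)
    if config.species_counts:
        sim.species_counts = read_matrix(config.species_counts)
    if config.hmo_peaks:
        sim.hmo_peaks = pd.read_csv(config.hmo_peaks, sep="\t")
    if config.hmo_sample_info:
        sim.hmo_sample_info = pd.read_csv(config.hmo_sample_info, sep="\t")
    if config.metadata:
        sim.metadata = pd.read_csv(config.metadata, sep="\t")
    return sim


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the seven report artifacts.

    Returns a dict of the in-memory results keyed by artifact name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = load_bundle(config)
    panel = (
        subspecies.MarkerPanel.from_file(config.marker_panel)
        if config.marker_panel
        else subspecies.MarkerPanel.default()
    )
    results: dict = {}

    # --- 1. subspecies typing
    calls = _stage("subspecies")(_subspecies_stage)(bundle, panel, config)
    calls.to_csv(out / "subspecies_calls.tsv", sep="\t", index=False)
    results["subspecies_calls"] = calls

    # --- 2. community typing
    assignments, curve = _stage("gmc")(_gmc_stage)(bundle, config)
    assignments.to_csv(out / "gmc_assignments.tsv", sep="\t", index=False)
    curve.to_csv(out / "laplace_curve.tsv", sep="\t", index=False)
    results["gmc_assignments"] = assignments
    results["laplace_curve"] = curve

    # --- 3. HM typing
    hm_calls, prevalence, npa = _stage("hmo")(_hmo_stage)(bundle)
    hm_calls.to_csv(out / "hm_group_calls.tsv", sep="\t", index=False)
    prevalence.to_csv(out / "hm_group_prevalence.tsv", sep="\t", index=False)
    write_matrix(npa, out / "hmo_npa.tsv")
    results["hm_group_calls"] = hm_calls
    results["hm_group_prevalence"] = prevalence

    # --- 4. diversity
    diversity = _stage("diversity")(_diversity_stage)(bundle, config)
    write_matrix(diversity, out / "diversity.tsv")
    results["diversity"] = diversity

    # --- 5. associations
    assoc = _stage("associate")(_assoc_stage)(bundle, assignments, hm_calls, npa, config)
    assoc.to_csv(out / "association_tables.tsv", sep="\t", index=False)
    results["association_tables"] = assoc

    # --- 6. network
    net = _stage("network")(_network_stage)(bundle, config)
    net.edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
    net.nodes.to_csv(out / "network_nodes.tsv", sep="\t", index=False)
    results["network"] = net

    # --- 7. crosstabs
    crosstab = _stage("crosstab")(_crosstab_stage)(calls, assignments, bundle)
    crosstab.to_csv(out / "crosstab_subspecies_gmc.tsv", sep="\t")
    results["crosstab_subspecies_gmc"] = crosstab
    log.info("pipeline complete: %d artifacts in %s", len(ARTIFACTS), out)
    return results


def _subspecies_stage(bundle, panel, config):
    presence = subspecies.binarize(
        bundle.gene_coverage, config.coverage_presence_threshold
    )
    return subspecies.classify_all(
        presence, panel, config.theta_full, config.theta_partial
    )


def _gmc_stage(bundle, config):
    counts = bundle.genus_counts
    if not np.allclose(np.asarray(counts), np.round(np.asarray(counts))):
        counts = community.rescale_to_counts(counts, config.pseudo_total)
    best_K, models = community.dmm_select(
        counts,
        config.K_range,
        seed=config.seed,
        n_restarts=config.n_restarts,
        max_iter=config.dmm_max_iter,
    )
    assignments = community.assign_gmc(models[best_K])
    curve = pd.DataFrame(
        {
            "K": sorted(models),
            "laplace_score": [models[k].laplace_score for k in sorted(models)],
            "log_likelihood": [models[k].log_likelihood for k in sorted(models)],
            "selected": [k == best_K for k in sorted(models)],
        }
    )
    return assignments, curve


def _hmo_stage(bundle):
    quant = hmo.quantify_peaks(bundle.hmo_peaks, bundle.hmo_sample_info)
    calls = hmo.assign_hm_group(quant)
    prevalence = hmo.summarize_hm_groups(calls)
    return calls, prevalence, quant.npa_wide()


def _diversity_stage(bundle, config):
    rare = community.rarefy(bundle.species_counts, seed=config.seed)
    return community.alpha_diversity(rare)


def _assoc_stage(bundle, assignments, hm_calls, npa, config):
    meta = bundle.metadata.set_index("sample_id")
    gmc = assignments.set_index("sample_id")["gmc_type"]
    tables = []
    for var in ("fecal_ph", "age_months", "calprotectin"):
        vals = meta.loc[gmc.index, var].to_numpy()
        H, p = stats.kruskal_wallis(vals, gmc.to_numpy())
        row = {"analysis": f"{var}_by_gmc", "feature": var, "test": "kruskal_wallis",
               "statistic": H, "p": p, "q": np.nan}
        tables.append(pd.DataFrame([row]))
        if len(np.unique(gmc)) >= 3:
            dunn = stats.dunn_posthoc(vals, gmc.to_numpy())
            dunn.insert(0, "analysis", f"{var}_by_gmc_dunn")
            dunn["feature"] = var
            dunn = dunn.rename(columns={"z": "statistic"})
            tables.append(dunn[["analysis", "feature", "statistic", "p", "q",
                                "group_a", "group_b"]])
    # HMOs by maternal secretor status
    secretor = hm_calls.set_index("sample_id")["secretor"].reindex(npa.index)
    if secretor.nunique() == 2:
        cmp = hmo.compare_hmo_groups(npa, secretor.to_numpy())
        cmp.insert(0, "analysis", "hmo_by_secretor")
        tables.append(cmp[["analysis", "feature", "test", "statistic", "p", "q"]])
    # GMC type x secretor status (chi-squared), on the shared samples
    shared = gmc.index.intersection(secretor.index)
    if len(shared):
        tab = pd.crosstab(gmc.loc[shared], secretor.loc[shared])
        if tab.shape[0] >= 2 and tab.shape[1] >= 2:
            try:
                x2, p = stats.chi_squared(tab.to_numpy())
                tables.append(pd.DataFrame([{
                    "analysis": "gmc_by_secretor", "feature": "gmc_type",
                    "test": "chi_squared", "statistic": x2, "p": p, "q": np.nan,
                }]))
            except ValueError as exc:
                log.warning("chi-squared skipped: %s", exc)
    return pd.concat(tables, ignore_index=True)


def _network_stage(bundle, config):
    return stats.build_network(
        bundle.species_counts,
        top_n=config.top_n_taxa,
        prevalence_min=config.prevalence_min,
        corr_threshold=config.corr_threshold,
        seed=config.seed,
    )


def _crosstab_stage(calls, assignments, bundle):
    merged = calls.merge(assignments, on="sample_id")
    counts, pct = subspecies.crosstab_subspecies(
        merged, merged["gmc_type"].to_numpy()
    )
    ph = bundle.metadata.set_index("sample_id")["fecal_ph"]
    gmc = assignments.set_index("sample_id")["gmc_type"]
    summary = pd.DataFrame({
        "ph_mean": ph.groupby(gmc).mean(),
        "ph_sd": ph.groupby(gmc).std(),
    })
    out = counts.copy()
    out.columns = [f"n_{c}" for c in counts.columns]
    for c in pct.columns:
        out[f"pct_{c}"] = pct[c]
    for c in summary.columns:
        out[c] = summary[c]
    return out
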