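"""Synthetic cohort generator with planted ground truth.

Every pipeline input — pangenome marker coverage, genus counts from a
Dirichlet-multinomial mixture, a correlated species table for network
estimation, milk peak tables, and infant metadata — is generated from a
single integer seed (split into independent substreams), together with the
truth needed to score each downstream stage: true subspecies class, true
mixture component, true milk group, and the planted effect sizes.

Defaults encode the cohort this generator emulates: 105 partially breastfed
rural Kenyan infants aged 8.31 +/- 1.38 months with 90 maternal milk
samples; subspecies class frequencies 39/12/46/4 (%), GMC prevalences
50.5/40.0/9.5 (%) with fecal pH means 5.01/5.70/5.68, HM group frequencies
48.9/22.2/22.2/6.7 (%), and an 80% LNT-transporter quorum among
HMO-cluster-positive metagenomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .subspecies import MarkerPanel, SubspeciesClass

CLASS_ORDER = (
    SubspeciesClass.EXCLUSIVE_INFANTIS,
    SubspeciesClass.PUTATIVE_INFANTIS,
    SubspeciesClass.COEXISTENCE,
    SubspeciesClass.EXCLUSIVE_LONGUM,
    SubspeciesClass.UNCLASSIFIED,
)
#: cohort subspecies frequencies (percentages 39/12/46/4 renormalized)
DEFAULT_CLASS_PROBS = tuple(np.array([39.0, 12.0, 46.0, 4.0, 0.0]) / 101.0)
#: cohort HM group frequencies (groups I-IV)
DEFAULT_GROUP_PROBS = (0.489, 0.222, 0.222, 0.067)
#: cohort GMC prevalences
DEFAULT_GMC_PI = (0.505, 0.400, 0.095)
#: fecal pH means per GMC type
DEFAULT_PH_MEANS = (5.01, 5.70, 5.68)
#: fraction of HMO-cluster-positive metagenomes carrying >= 2 LNT transporter genes
DEFAULT_LNT_PREVALENCE = 0.8

BACKGROUND_HMOS = ("3-FL", "LNT", "LNFP III", "LNFP V", "LNnT", "LSTb", "6'-SL", "DSLNT")

GENERA = (
    "Bifidobacterium", "Escherichia", "Klebsiella", "Megasphaera",
    "Bacteroides", "Streptococcus", "Veillonella", "Enterococcus",
    "Prevotella", "Clostridium", "Lactobacillus", "Collinsella",
)

SPECIES = (
    "Bifidobacterium_longum", "Bifidobacterium_breve", "Bifidobacterium_bifidum",
    "Bifidobacterium_kashiwanohense", "Bifidobacterium_catenulatum",
    "Bifidobacterium_pseudocatenulatum", "Bifidobacterium_angulatum",
    "Limosilactobacillus_reuteri", "Escherichia_coli", "Klebsiella_pneumoniae",
    "Megasphaera_elsdenii", "Streptococcus_salivarius",
    "Bacteroides_thetaiotaomicron", "Bacteroides_fragilis",
    "Akkermansia_muciniphila", "Veillonella_parvula", "Enterococcus_faecalis",
    "Ruminococcus_gnavus", "Clostridium_saccharolyticum", "Prevotella_copri",
)


def default_gmc_alphas() -> list[np.ndarray]:
    """Planted Dirichlet parameters for the three GMC types over 12 genera:
    type 1 Bifidobacterium-dominant, type 2 with elevated Megasphaera, type 3
    the most diverse with Enterobacteriaceae enrichment."""
    m1 = np.array([0.72, 0.03, 0.02, 0.04, 0.05, 0.04, 0.03, 0.02, 0.02, 0.01, 0.01, 0.01])
    m2 = np.array([0.60, 0.05, 0.03, 0.12, 0.06, 0.04, 0.03, 0.02, 0.02, 0.01, 0.01, 0.01])
    m3 = np.array([0.30, 0.18, 0.14, 0.04, 0.08, 0.07, 0.05, 0.04, 0.04, 0.03, 0.02, 0.01])
    return [m1 * 60.0, m2 * 60.0, m3 * 35.0]


def default_species_corr() -> pd.DataFrame:
    """Planted basis correlation over the 20 species: two positive blocks
    (the B. kashiwanohense/catenulatum/pseudocatenulatum/angulatum subnetwork
    and the B. breve/B. longum/L. reuteri subnetwork, rho = 0.6)."""
    d = len(SPECIES)
    C = np.eye(d)
    blocks = [
        ("Bifidobacterium_kashiwanohense", "Bifidobacterium_catenulatum",
         "Bifidobacterium_pseudocatenulatum", "Bifidobacterium_angulatum"),
        ("Bifidobacterium_breve", "Bifidobacterium_longum", "Limosilactobacillus_reuteri"),
    ]
    idx = {s: i for i, s in enumerate(SPECIES)}
    for block in blocks:
        for a in block:
            for b in block:
                if a != b:
                    C[idx[a], idx[b]] = 0.6
    return pd.DataFrame(C, index=SPECIES, columns=SPECIES)


@dataclass
class SimTruth:
    """Planted ground truth, sufficient to score every downstream stage."""

    subspecies: pd.DataFrame | None = None  # sample_id, subspecies_class, lnt_planted
    gmc: pd.DataFrame | None = None  # sample_id, gmc_component
    hm_group: pd.DataFrame | None = None  # sample_id, group, secretor, lewis
    pi: np.ndarray | None = None
    alphas: list = field(default_factory=list)
    ph_means: tuple | None = None
    basis_corr: pd.DataFrame | None = None


def _ids(n: int, prefix: str = "S") -> list[str]:
    return [f"{prefix}{i+1:03d}" for i in range(n)]


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# pangenome marker profiles
# ---------------------------------------------------------------------------

def simulate_gene_profiles(
    n: int,
    class_probs=DEFAULT_CLASS_PROBS,
    panel: MarkerPanel | None = None,
    dropout: float = 0.0,
    noise_flip: float = 0.02,
    seed: int = 0,
    theta_full: float = 0.9,
    theta_partial: float = 0.25,
    lnt_prevalence: float = DEFAULT_LNT_PREVALENCE,
) -> tuple[pd.DataFrame, SimTruth]:
    """Sample x gene coverage matrix with planted subspecies classes.

    Class templates over the marker panel: exclusive infantis = full HMO
    cluster, no ara; putative infantis = a uniform fraction of cluster genes
    inside [theta_partial, theta_full), no ara; coexistence = full cluster
    plus both ara genes; exclusive longum = both ara only; unclassified =
    no markers. Cluster and ara bits are then flipped with probability
    ``noise_flip``; present genes are additionally missed with probability
    ``dropout``. LNT transporter genes are planted so that a fraction
    ``lnt_prevalence`` of HMO-cluster-positive samples carry >= 2 of them.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    probs = np.asarray(class_probs, dtype=float)
    if probs.size != 5 or np.any(probs < 0) or abs(probs.sum() - 1) > 1e-8:
        raise ValueError("class_probs must be a simplex over the 5 classes")
    if not (0 <= dropout < 0.5 and 0 <= noise_flip < 0.5):
        raise ValueError("dropout and noise_flip must lie in [0, 0.5)")
    panel = panel or MarkerPanel.default()
    rng = np.random.default_rng(seed)
    G = len(panel.hmo_cluster)
    # putative band: integer gene counts whose fraction stays inside the band
    m_lo = int(np.ceil(theta_partial * G))
    m_hi = int(np.ceil(theta_full * G)) - 1
    classes = rng.choice(len(CLASS_ORDER), size=n, p=probs)
    cols = list(panel.all_genes)
    presence = np.zeros((n, len(cols)), dtype=int)
    hmo_sl = slice(0, G)
    ara_sl = slice(G, G + 2)
    lnt_sl = slice(G + 2, G + 5)
    lnt_planted = np.zeros(n, dtype=int)
    for i, c in enumerate(classes):
        cls = CLASS_ORDER[c]
        if cls in (SubspeciesClass.EXCLUSIVE_INFANTIS, SubspeciesClass.COEXISTENCE):
            presence[i, hmo_sl] = 1
        elif cls is SubspeciesClass.PUTATIVE_INFANTIS:
            m = int(rng.integers(m_lo, m_hi + 1))
            on = rng.choice(G, size=m, replace=False)
            presence[i, on] = 1
        if cls in (SubspeciesClass.COEXISTENCE, SubspeciesClass.EXCLUSIVE_LONGUM):
            presence[i, ara_sl] = 1
        infantis_positive = cls in (
            SubspeciesClass.EXCLUSIVE_INFANTIS,
            SubspeciesClass.PUTATIVE_INFANTIS,
            SubspeciesClass.COEXISTENCE,
        )
        if infantis_positive:
            k = int(rng.integers(2, 4)) if rng.random() < lnt_prevalence else int(rng.integers(0, 2))
        else:
            k = 0
        lnt_planted[i] = k
        if k:
            on = rng.choice(3, size=k, replace=False)
            presence[i, np.arange(G + 2, G + 5)[on]] = 1
    # detection noise on the diagnostic cluster + ara bits
    flip = rng.random((n, G + 2)) < noise_flip
    presence[:, : G + 2] ^= flip.astype(int)
    if dropout > 0:
        drop = (rng.random(presence.shape) < dropout) & (presence == 1)
        presence[drop] = 0
    coverage = presence * rng.uniform(1.0, 10.0, size=presence.shape)
    ids = _ids(n)
    matrix = pd.DataFrame(coverage, index=ids, columns=cols)
    matrix.index.name = "sample_id"
    truth = SimTruth(
        subspecies=pd.DataFrame(
            {
                "sample_id": ids,
                "subspecies_class": [CLASS_ORDER[c].value for c in classes],
                "lnt_planted": lnt_planted,
            }
        )
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Dirichlet-multinomial mixture counts
# ---------------------------------------------------------------------------

def simulate_dmm_counts(
    n: int,
    pi=DEFAULT_GMC_PI,
    alphas=None,
    depth: int = 10000,
    seed: int = 0,
    taxa=None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Counts from a Dirichlet-multinomial mixture: component k ~ pi,
    composition ~ Dirichlet(alpha_k), counts ~ Multinomial(depth). Every row
    sums to ``depth`` exactly."""
    if n <= 0:
        raise ValueError("n must be positive")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    alphas = [np.asarray(a, dtype=float) for a in (alphas if alphas is not None else default_gmc_alphas())]
    J = alphas[0].size
    if any(a.size != J for a in alphas):
        raise ValueError("all alpha vectors must have the same length")
    if any(np.any(a <= 0) for a in alphas):
        raise ValueError("alpha vectors must be strictly positive")
    pi = np.asarray(pi, dtype=float)
    if pi.size != len(alphas) or abs(pi.sum() - 1) > 1e-8 or np.any(pi < 0):
        raise ValueError("pi must be a simplex matching the number of components")
    if taxa is None:
        taxa = list(GENERA[:J]) if J <= len(GENERA) else [f"taxon_{j+1}" for j in range(J)]
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(alphas), size=n, p=pi)
    counts = np.empty((n, J), dtype=np.int64)
    for i, k in enumerate(comp):
        p = rng.dirichlet(alphas[k])
        counts[i] = rng.multinomial(depth, p)
    ids = _ids(n)
    table = pd.DataFrame(counts, index=ids, columns=taxa)
    table.index.name = "sample_id"
    truth = SimTruth(
        gmc=pd.DataFrame({"sample_id": ids, "gmc_component": comp + 1}),
        pi=pi,
        alphas=alphas,
    )
    return table, truth


# ---------------------------------------------------------------------------
# milk peak tables
# ---------------------------------------------------------------------------

_GROUP_MARKERS = {
    "I": {"se": True, "le": True},
    "II": {"se": False, "le": True},
    "III": {"se": True, "le": False},
    "IV": {"se": False, "le": False},
}


def simulate_hmo_peaks(
    n: int,
    group_probs=DEFAULT_GROUP_PROBS,
    seed: int = 0,
    present_snr=(20.0, 200.0),
    absent_snr=(0.0, 2.0),
    ids=None,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Per-sample raw peak tables with planted HM groups.

    Marker peaks implied present by the group's Se/Le status get areas drawn
    uniformly at ``present_snr`` times the sample noise (far above LOQ);
    implied-absent markers sit below LOD at ``absent_snr`` times noise.
    Background HMOs and one unassigned peak are always present. Returns
    (peaks long table, per-sample noise/IS table, truth).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    probs = np.asarray(group_probs, dtype=float)
    if probs.size != 4 or np.any(probs < 0) or abs(probs.sum() - 1) > 1e-6:
        raise ValueError("group_probs must be a simplex over HM groups I-IV")
    probs = probs / probs.sum()
    from .hmo import LE_MARKERS, SE_MARKERS  # circular-safe import

    rng = np.random.default_rng(seed)
    ids = list(ids) if ids is not None else _ids(n, prefix="M")
    groups = rng.choice(["I", "II", "III", "IV"], size=n, p=probs)
    noise = rng.uniform(5.0, 15.0, size=n)
    is_area = rng.uniform(800.0, 1200.0, size=n)
    rows = []
    for i, sid in enumerate(ids):
        spec = _GROUP_MARKERS[groups[i]]
        for marker, implied in [(m, spec["se"]) for m in SE_MARKERS] + [
            (m, spec["le"]) for m in LE_MARKERS
        ]:
            lo, hi = present_snr if implied else absent_snr
            rows.append((sid, marker, noise[i] * rng.uniform(lo, hi)))
        for hmo in BACKGROUND_HMOS:
            rows.append((sid, hmo, noise[i] * rng.uniform(*present_snr)))
        rows.append((sid, "unassigned", noise[i] * rng.uniform(*present_snr)))
    peaks = pd.DataFrame(rows, columns=["sample_id", "peak_label", "raw_area"])
    info = pd.DataFrame({"sample_id": ids, "noise_level": noise, "is_area": is_area})
    truth = SimTruth(
        hm_group=pd.DataFrame(
            {
                "sample_id": ids,
                "group": groups,
                "secretor": [_GROUP_MARKERS[g]["se"] for g in groups],
                "lewis": [_GROUP_MARKERS[g]["le"] for g in groups],
            }
        )
    )
    return peaks, info, truth


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

def simulate_metadata(
    truth: SimTruth | pd.DataFrame,
    sd_ph: float = 0.8,
    seed: int = 0,
    ph_means=DEFAULT_PH_MEANS,
) -> pd.DataFrame:
    """Fecal pH (GMC-dependent), age, and calprotectin (null feature).

    pH ~ Normal(mean of the sample's GMC type, sd_ph) clipped to [4, 8];
    age ~ Normal(8.31, 1.38) months clipped to [6, 11]; calprotectin is
    log-normal and independent of GMC type (a planted null).
    """
    gmc = truth.gmc if isinstance(truth, SimTruth) else truth
    if gmc is None or "gmc_component" not in gmc.columns:
        raise ValueError("truth must carry GMC component labels")
    if sd_ph < 0:
        raise ValueError("sd_ph must be non-negative")
    rng = np.random.default_rng(seed)
    comp = gmc["gmc_component"].to_numpy(dtype=int)
    means = np.asarray(ph_means, dtype=float)
    mu = means[np.minimum(comp, len(means)) - 1]
    ph = np.clip(rng.normal(mu, sd_ph), 4.0, 8.0)
    age = np.clip(rng.normal(8.31, 1.38, size=len(comp)), 6.0, 11.0)
    calprotectin = np.exp(rng.normal(np.log(150.0), 0.6, size=len(comp)))
    return pd.DataFrame(
        {
            "sample_id": gmc["sample_id"],
            "age_months": age,
            "fecal_ph": ph,
            "calprotectin": calprotectin,
        }
    )


# ---------------------------------------------------------------------------
# correlated species counts (network testbed)
# ---------------------------------------------------------------------------

def simulate_correlated_counts(
    n: int,
    basis_corr: pd.DataFrame | None = None,
    depth: int = 50000,
    seed: int = 0,
    mu=None,
    sigma: float = 1.0,
) -> pd.DataFrame:
    """Log-normal basis abundances with the given correlation structure,
    closed to compositions and multinomially sampled at ``depth``."""
    if n < 2:
        raise ValueError("need n >= 2 samples")
    C = basis_corr if basis_corr is not None else default_species_corr()
    names = list(C.columns) if isinstance(C, pd.DataFrame) else None
    C = np.asarray(C, dtype=float)
    d = C.shape[0]
    if C.shape != (d, d) or not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("basis_corr must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-10):
        raise ValueError("basis_corr must have a unit diagonal")
    eig, V = np.linalg.eigh(C)
    if eig.min() < -1e-8:
        raise ValueError("basis_corr is not positive semi-definite")
    if names is None:
        names = [f"species_{j+1}" for j in range(d)]
    if mu is None:
        # spread of mean log abundances, dominant taxa first
        mu = np.linspace(3.0, -1.0, d)
        if names == list(SPECIES):
            mu = np.array([4.0, 3.0, 2.7, 2.0] + list(np.linspace(1.5, -1.0, d - 4)))
    mu = np.asarray(mu, dtype=float)
    rng = np.random.default_rng(seed)
    root = V @ np.diag(np.sqrt(np.clip(eig, 0, None)))
    z = rng.standard_normal((n, d)) @ root.T
    basis = np.exp(mu[None, :] + sigma * z)
    p = basis / basis.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, pi) for pi in p])
    table = pd.DataFrame(counts, index=_ids(n), columns=names)
    table.index.name = "sample_id"
    return table


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulatedBundle:
    gene_coverage: pd.DataFrame
    genus_counts: pd.DataFrame
    species_counts: pd.DataFrame
    hmo_peaks: pd.DataFrame
    hmo_sample_info: pd.DataFrame
    metadata: pd.DataFrame
    truth: SimTruth


def simulate_all(
    n_infants: int = 105,
    n_milk: int = 90,
    seed: int = 0,
    depth: int = 10000,
    **gene_kwargs,
) -> SimulatedBundle:
    """Generate the full input bundle for one cohort from a single seed.

    Milk samples are mothers of the first ``n_milk`` infants and share their
    sample ids; HM group is drawn independently of GMC type (the planted
    association between milk phenotype and community type is null).
    """
    if n_milk > n_infants:
        raise ValueError("n_milk cannot exceed n_infants")
    ss = np.random.SeedSequence(seed)
    s_gene, s_dmm, s_spec, s_hmo, s_meta = (_child_seed(c) for c in ss.spawn(5))
    gene_cov, truth_gene = simulate_gene_profiles(n_infants, seed=s_gene, **gene_kwargs)
    genus, truth_gmc = simulate_dmm_counts(n_infants, depth=depth, seed=s_dmm)
    species = simulate_correlated_counts(n_infants, depth=5 * depth, seed=s_spec)
    species.index = genus.index
    ids_milk = list(genus.index[:n_milk])
    peaks, info, truth_hmo = simulate_hmo_peaks(n_milk, seed=s_hmo, ids=ids_milk)
    metadata = simulate_metadata(truth_gmc, seed=s_meta)
    truth = SimTruth(
        subspecies=truth_gene.subspecies,
        gmc=truth_gmc.gmc,
        hm_group=truth_hmo.hm_group,
        pi=truth_gmc.pi,
        alphas=truth_gmc.alphas,
        ph_means=DEFAULT_PH_MEANS,
        basis_corr=default_species_corr(),
    )
    return SimulatedBundle(
        gene_coverage=gene_cov,
        genus_counts=genus,
        species_counts=species,
        hmo_peaks=peaks,
        hmo_sample_info=info,
        metadata=metadata,
        truth=truth,
    )
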