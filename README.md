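# milkgut

Analysis pipeline for infant gut microbiome cohorts with paired maternal
milk samples. It covers the computational core of a shotgun-metagenomics +
human-milk-oligosaccharide (HMO) cohort study in one tested package:

- **B. longum subspecies typing** from pangenome marker genes.
  *B. longum* subsp. *infantis* carries the HMO import/metabolism cluster
  (Blon_2331–Blon_2361) that subsp. *longum* lacks; *longum* carries the
  arabinose genes *araA*/*araD* instead. Each metagenome is stratified by
  the detected cluster fraction *f*<sub>HMO</sub> and ara detection into
  exclusive *infantis* / putative *infantis* / co-existence / exclusive
  *longum* / unclassified, with complete-linkage (Euclidean) sample
  clustering and the LNT-transporter (Blon_2175–2177) quorum statistic.
- **Community typing** by a Dirichlet-multinomial mixture (DMM) over
  genus counts, written from scratch: EM with numerical per-component
  Dirichlet updates, and the number of gut microbiome community (GMC)
  types chosen by a Laplace approximation to the negative log evidence.
  Plus rarefaction, alpha diversity (richness, Shannon *H*, inverse
  Simpson), Bray–Curtis, and PERMANOVA.
- **HMO quantification and milk typing**: peak areas gated by
  signal-to-noise (LOQ = SNR 10, LOD = SNR 3), internal-standard
  normalized areas (nPA, % of IS), peaks between LOD and LOQ imputed at
  LOQ/√2; maternal secretor status from 2'-FL/DFL/LNFP I, Lewis status
  from LNFP II/LNDFH II; HM groups I (Se+Le+) … IV (Se−Le−).
- **Association statistics and networks**: Kruskal–Wallis with Dunn
  post-hoc, Mann–Whitney, Pearson chi-squared, Benjamini–Hochberg FDR,
  CLR transform, and SparCC compositional correlations thresholded into a
  species co-occurrence network (top 20 species, prevalence ≥ 25%,
  |ρ| ≥ 0.2).
- **A synthetic cohort generator** that plants ground truth for every
  stage (subspecies classes, mixture components, milk groups, pH effects,
  correlation blocks), so the whole pipeline is testable without any
  sequencing data.

## Worked example

```python
import milkgut as mg

# milk typing on a simulated 90-mother cohort
peaks, info, truth = mg.simulate_hmo_peaks(90, seed=4)
quant = mg.quantify_peaks(peaks, info)          # SNR-gated nPA values
calls = mg.assign_hm_group(quant)               # Se/Le -> HM group I-IV
print(mg.summarize_hm_groups(calls).to_string(index=False))
```

```text
         category  count  percent
          group_I     37     41.1
         group_II     27     30.0
        group_III     16     17.8
         group_IV     10     11.1
secretor_positive     53     59.0
   lewis_positive     64     71.0
```

Counts and percentages per HM group, with secretor-positive = groups
I + III and Lewis-positive = groups I + II; for this seed the 90 planted
group labels are recovered exactly.

The numbered drivers under `analysis/` run the full story on the default
synthetic cohort (105 infants, 90 milk samples) and write their tables
under `results/`:

```bash
python analysis/01_simulate_cohort.py      # inputs + planted truth
python analysis/02_subspecies_typing.py    # calls, clustering, LNT statistic
python analysis/03_community_types.py      # DMM fit, K selection, pH by GMC
python analysis/04_hmo_typing.py           # milk typing, HMO-by-secretor tests
python analysis/05_associations_network.py # SparCC network, crosstabs
```

The same flow is available as a CLI (`milkgut run-all --seed 0 --out-dir
results/run`) or as a single call, `milkgut.run_pipeline(RunConfig(...))`.

## Acceptance script

`scripts/acceptance.py` rebuilds, from scratch, a 90-sample milk cohort
whose joint (Se, Le) marker patterns occur 44/20/20/6 times, pushes the
raw peak tables through quantification, group assignment and the
prevalence rollup, and writes the resulting cohort percentages as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
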