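# gcmet

Analysis pipeline for paired tumor / adjacent-tissue LC-MS metabolomics,
built around the question of how the metabolome — and, more tellingly, the
*correlation structure* of the metabolome — rewires during gastric-cancer
progression.  It is written for metabolomics analysts who have a normalized
(or raw) peak table with paired sample metadata and want a reproducible,
scriptable version of the full analysis arc:

1. **Normalization & QC** — internal-standard + tissue-weight normalization,
   pooled-QC relative standard deviations (fractions below 20 % / 30 %).
2. **Differential screen** — paired Wilcoxon signed-rank per metabolite with
   Benjamini–Hochberg FDR and median-pair-ratio log₂ fold changes; Mann–Whitney
   associations of differential metabolites with clinical indices; set-based
   hypergeometric pathway over-representation (GMT input).
3. **PLS-DA** — NIPALS PLS1 on the ±1 class response after auto-scaling,
   component count chosen by 5-fold cross-validated Q², validated by a
   2000-round label-permutation test (p ≥ 1/(B+1)).
4. **Differential correlation network** — per-group Spearman matrices and the
   Fisher-z contrast z = (atanh ρ_A − atanh ρ_B) / √(1/(n_A−3) + 1/(n_B−3)),
   FDR-filtered into a network with modules and degree-ranked hubs.
5. **Acylcarnitine ratio panel** — eight chain-length-specific ratios acting
   as β-oxidation enzyme-activity proxies (CPT1, VLCAD, SCAD, MCAD, ECHS1,
   C2/C0), paired-tested tumor vs adjacent.
6. **Biomarker evaluation** — patient-level 4:1 discovery/validation split,
   p-value marker ranking on discovery only, ROC/AUC by the pair-counting
   (Mann–Whitney) identity, and a two-marker logistic combination with a
   Youden threshold frozen on discovery.
7. **Stage-wise network topology** — per-TNM-stage significant-Spearman
   networks G_t (edge weight w_t = ρ when p < 0.01, else 0), extraction of the
   monotone subnetworks SG_t (trajectories w_I, w_II, w_III monotone within a
   ±0.02 equality band, with at least one adjacent-stage change > 0.05),
   top-15 degree hubs per stage, and per-hub informative star-subgraph
   triplets Tri(v) = (Info-SG_I(v), Info-SG_II(v), Info-SG_III(v)).

A first-class synthetic-cohort generator (`gcmet.synthetic_data`) emulates the
study design — 80 patients with paired samples, TNM stage counts 13/24/39/4,
~234 metabolites, log-normal intensities, internal standards, tissue weights,
pooled-QC injections — and plants known effects, stage-wise Spearman
trajectories (through the Gaussian-copula mapping r = 2·sin(πρ_s/6)) and hubs,
returning the ground truth so every stage of the pipeline can be scored.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from gcmet import synthetic_data as sd, core_data as cd, univariate as uv, nam, ratios

cfg = sd.SyntheticConfig(n_patients=40,
                         stage_counts={"I": 12, "II": 14, "III": 12, "IV": 2},
                         n_metabolites=80, seed=7)
pt, samples, mets, truth = sd.generate_cohort(cfg)
norm = cd.normalize_intensities(pt, samples, mets)
rsd, qc = cd.compute_qc_rsd(norm, samples)
print(f"QC: {qc['n_qc']} injections, {100*qc['frac_rsd_lt_20']:.1f}% of metabolites with RSD < 20%")

tissue = [s for s in samples if not s.is_qc]
tp = norm.subset_samples([s.sample_id for s in tissue])
diff = uv.differential_analysis(tp, tissue)
n_sig = sum(r.p_value < 0.05 for r in diff)
print(f"differential screen: {n_sig}/{len(diff)} metabolites at p < 0.05")

nets, subnets, hub_t, hubs, trips = nam.run_nam(tp, tissue)
print("stage subnetwork edges:", {t: len(sg.edges) for t, sg in subnets.items()})
```

which prints

```
QC: 8 injections, 95.0% of metabolites with RSD < 20%
differential screen: 30/80 metabolites at p < 0.05
stage subnetwork edges: {'I': 54, 'II': 1, 'III': 38}
```

Reading: the platform-stability check passes (95 % of metabolites reproducible
below 20 % RSD over the pooled-QC injections); 30 of 80 metabolites shift
between tumor and adjacent tissue at p < 0.05 (this 40-patient cohort plants
effects on 30 % of metabolites); and the stage-wise extraction finds edges
whose correlation strengthens or dissolves monotonically from TNM I to III —
here dominated by the planted decreasing fatty-acid pairs (visible in stage I,
gone by stage II) and the growing hub neighborhood (re-appearing in stage III).

The same pipeline runs from the shell:

```bash
gcmet run-all --config cfg.yaml --seed 7 --out results/
gcmet simulate --seed 3 --out cohort/           # synthetic cohort + ground truth
gcmet nam --config cfg.yaml --out results_nam/  # a single stage
```

Each run writes per-stage TSV/JSON artifacts, GraphML network exports and a
provenance manifest (config hash + seeds) sufficient to reproduce every number.

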