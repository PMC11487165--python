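# esckit

A multi-omic analysis toolkit for esophageal squamous cell carcinoma (ESCC)
cohorts — and, more generally, any bulk tumour cohort with expression,
somatic-mutation, copy-number, histology-tile and survival data.

ESCC is highly heterogeneous: tumours differ in differentiation state,
metabolic programmes, immune infiltration and stem-like character, and these
differences track prognosis. `esckit` packages the statistical machinery
needed to dissect that heterogeneity into a tested, reusable library with a
command-line interface:

- **Transcriptomic subtyping** — consensus non-negative matrix factorisation
  (NMF) over the top-MAD variable genes, with cophenetic-correlation rank
  selection and one-vs-rest marker-gene calling.
- **Immune profiling** — marker-mean immune cell estimation (Danaher-style
  signatures bundled), a four-part benchmarking protocol (tumour purity,
  copy number at marker loci, cross-method concordance, IHC counts), and
  resampled consensus clustering into immune subtypes.
- **Pathway functional-mutation enrichment** — a mutation-burden-adjusted
  per-sample pathway score with Kruskal–Wallis subtype comparisons.
- **Intratumour heterogeneity (ITH)** — Shannon diversity of the 10-bin
  variant-allele-frequency (VAF) distribution.
- **Histology meta-features** — tile QC, patient-level discovery/test
  splits, one-vs-rest Wilcoxon feature selection with joint BH FDR, and
  held-out validation of per-subtype meta-features.
- **Survival utilities** — Kaplan–Meier/log-rank, Cox proportional hazards,
  and the maximally selected log-rank cutpoint.
- **Synthetic cohorts** — a fully labelled generator that plants every kind
  of structure the analyses look for, so the whole pipeline is testable
  without any data download.

## The statistics at the core

**Consensus NMF.** The expression matrix (restricted to the top-*n* genes by
unscaled median absolute deviation) is shifted non-negative and factorised
as `V ≈ W H` by multiplicative updates from many random restarts. Each
restart labels samples by their dominant metagene (argmax of the columns of
`H`); the consensus matrix `C` is the across-restart co-clustering
frequency. Rank stability is the cophenetic correlation between the
dissimilarities `1 − C` and the cophenetic distances of their
average-linkage dendrogram; final labels cut that dendrogram at *k*.

**Burden-adjusted functional-mutation enrichment.** For sample *s* and gene
set *g* with *N_g* genes, `score(s, g) = (F_sg / N_g) / max(T_s, 1)` where
*F_sg* counts the sample's non-silent mutations in the set's genes and
*T_s* its total non-silent burden. The score is invariant to uniform burden
scaling and zero when the set is unmutated.

**Shannon ITH.** Each tumour's VAFs (alt / (ref + alt)) are binned into ten
equal bins over [0, 1]; with bin proportions *p_i*,
`H′ = −Σ p_i ln p_i ∈ [0, ln 10]`. Flat VAF spectra (many coexisting
clones) maximise H′; a single tight clonal peak gives 0.

**Meta-features.** For every (subtype, image feature) pair a two-sided
Wilcoxon rank-sum compares the subtype's tiles against the rest; BH runs
once across all pairs. The top five features per subtype that are
significant (FDR < 0.01), higher in the subtype, and unique to it are
summed into one histological marker per subtype, then re-tested on the
held-out patients.

## Worked example

```python
from esckit.simulate import CohortSimConfig, simulate_cohort
from esckit.subtype import select_variable_genes, nmf_consensus
from esckit.mutations import functional_enrichment, enrichment_subtype_test
from esckit.ith import ith_index
from esckit.survival import km_logrank
from sklearn.metrics import adjusted_rand_score

cfg = CohortSimConfig(seed=7, marker_effect=4.0,
                      enrichment_factors={"stemness": {"PATHWAY_01": 5.0}})
cohort = simulate_cohort(cfg)           # 120 samples, 4 planted subtypes
expr, truth = cohort["expression"], cohort["truth"]

genes = select_variable_genes(expr, 1500)
res = nmf_consensus(expr.subset_genes(genes), k=4, restarts=20, seed=7)
ari = adjusted_rand_score(truth["labels"].to_numpy(), res.labels.to_numpy())
print(f"cophenetic(k=4) = {res.cophenetic:.3f}, ARI vs truth = {ari:.2f}")

fem = functional_enrichment(cohort["mutations"], cohort["gene_sets"])
tests = enrichment_subtype_test(fem.scores, truth["labels"])
top = tests.sort_values("p").iloc[0]
print(f"top pathway: {tests['p'].idxmin()} (KW p = {top['p']:.2e}, "
      f"highest in {top['top_subtype']})")

ith = ith_index(cohort["mutations"])
print(f"median ITH (Shannon H', nats) = {ith.median():.3f}")

km = km_logrank(res.labels, cohort["sample_sheet"].frame)
print(f"log-rank across NMF clusters: chi2 = {km['statistic']:.2f}, p = {km['p']:.4f}")
```

prints

```
cophenetic(k=4) = 1.000, ARI vs truth = 1.00
top pathway: PATHWAY_01 (KW p = 1.02e-14, highest in stemness)
median ITH (Shannon H', nats) = 1.838
log-rank across NMF clusters: chi2 = 8.62, p = 0.0349
```

The subtyping recovers the four planted expression blocks exactly
(ARI = 1 at a perfectly stable rank, cophenetic 1.0); the pathway carrying
a 5× planted mutation-rate factor in the stemness subtype tops the
Kruskal–Wallis table with the correct subtype; ITH sits mid-scale for the
simulated clonal/subclonal VAF mixtures; and survival separates across the
recovered clusters because the generator ties hazard to subtype and ITH.

The same stages are available from the shell: `esckit simulate`,
`esckit subtype`, `esckit immune`, `esckit mutenrich`, `esckit cnclass`,
`esckit ith`, `esckit tilemeta`, `esckit survival`, `esckit enrich`
(see `esckit --help`).

## Documentation

See `docs/methods.md` for the models, parameter choices, numerical
conventions and known limitations.
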