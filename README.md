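# cagesym

Analysis pipeline for **cage-structured insect gut-symbiont acquisition
experiments**, with a fully synthetic data generator so every stage is
testable without field data.

## The problem

Many true bugs (Hemiptera: Coreoidea) must ingest a free-living soil
bacterium of the genus *Caballeronia* early in development; nymphs that
fail to acquire the symbiont rarely reach adulthood. A standard field
design confines lab-reared, aposymbiotic second-instar nymphs in mesh
cages on tree branches under different treatments (symbiont-fed control,
potential horizontal sources, phyllosphere only), then scores symbiont
acquisition by diagnostic PCR, developmental stage, and mortality, and
profiles the symbiont community of caged versus free-roaming wild bugs by
amplicon sequencing.

Analysing such data raises four recurring tasks, which this package
implements as a reusable, seeded pipeline:

1. **Community profiling.** ASV read tables are rarefied to a fixed depth
   (multivariate-hypergeometric subsampling, default 9123 reads) and ASVs
   are agglomerated into species-like *lineages* by hierarchical
   clustering of cophenetic (tip-to-tip path) distances on a phylogeny,
   cut at a threshold (default h = 0.1).
2. **Cluster-aware richness comparison.** Bugs within a cage are not
   independent. The permutation test draws, in each of *B* iterations
   (default 10 000), one bug per cage, computes the group-richness
   difference d = S(caged) − S(wild) where S(·) is the number of lineages
   present in the union of the selected samples, re-randomizes the
   caged/wild labels within the iteration's pool for a paired null
   difference, and reports p = (1 + #{d_null at least as extreme as
   d_obs}) / (B + 1), doubled for the two-tailed test. An exhaustive
   enumeration oracle covers small instances.
3. **Cage-level GLMs.** Per-cage proportions (symbiont-positive of
   tested; late-stage of surviving) are fitted by quasibinomial logistic
   regression (IRLS, dispersion = Pearson χ²/df, treatment term tested by
   the drop-one F test); per-cage death counts by Poisson regression with
   a likelihood-ratio test. Post-hoc pairwise comparisons are
   Holm-adjusted Wald contrasts with a compact letter display.
4. **Climate comparison.** Per-day temperature and humidity maxima are
   compared between years with a tie-corrected Mann-Whitney U test
   (exact enumeration for small samples).

The synthetic-data module simulates all inputs with known ground truth:
an ASV phylogeny whose true lineage partition is separable at the
clustering threshold by construction, per-treatment Bernoulli symbiont
acquisition with development coupled to symbiont status, per-bug
communities of 1–5 lineages (one dominant) drawn from origin-specific
pools, read counts with exact row-sum conservation, and two-year climate
series.

## Worked example

```python
import cagesym as cs, json

config = cs.SimConfig(seed=11)          # 2019-like design: 4 treatments x 10 cages x 12 nymphs
manifest = cs.run_pipeline(config, "demo_out", options=cs.PipelineOptions(n_iter=10_000))
report = json.load(open("demo_out/report.json"))
```

With this seed the run prints/reports:

```
caged richness 3 vs wild 14; p_two = 0.0002
fitted acquisition: {'adult': 0.329, 'burst_fruit': 0.414, 'caballeronia': 0.714, 'phyllosphere': 0.314}
F = 15.95, p = 9.25e-07, letters = {'adult': 'a', 'burst_fruit': 'a', 'caballeronia': 'b', 'phyllosphere': 'a'}
mortality LRT = 11.87, p = 0.00786
temperature: W = 652, p = 4.2e-12, medians 34.18 vs 38.37
```

Reading this: the caged bugs' pooled community (3 lineages) is
significantly poorer than the wild bugs' (14 lineages); the symbiont-fed
control (`caballeronia`, fitted acquisition 0.71) differs from all three
open treatments (≈0.31–0.41), which share a letter; treatment affects
per-cage mortality; and the simulated second year is significantly hotter
(median daily high 38.4 °C vs 34.2 °C).

The same pipeline is available from the shell:

```bash
cagesym run --outdir demo_out --seed 11
cagesym permtest --lineages demo_out/lineage_counts.tsv --meta demo_out/tested_bugs.tsv --seed 4
cagesym climate --series climate.tsv --compare-years 2019 2020
```

## Layout

- `src/cagesym/synthetic.py` — simulators (phylogeny, experiment, reads, climate, subsampling)
- `src/cagesym/profiles.py` — rarefaction, cophenetic distances, agglomeration, richness
- `src/cagesym/permutation.py` — cluster-aware permutation test and exact oracle
- `src/cagesym/cagestats.py` — filters, GLMs, contrasts, Mann-Whitney, climate summaries
- `src/cagesym/io.py`, `pipeline.py`, `cli.py` — TSV/newick/JSON I/O, the full pipeline, CLI
- `docs/methods.md` — models, assumptions, numerical choices, limitations
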