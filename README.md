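# qmpipe

Quantitative microbiota profiling (QMP) and exposure–outcome path analysis
for longitudinal infant gut cohorts.

Sequencing-based microbiome studies usually report *relative* abundances,
which confound real community dynamics with total bacterial load: a taxon
whose absolute population is rising can appear to decline simply because the
rest of the community grows faster, and absolute increases under an exposure
can be masked entirely in proportions. `qmpipe` is for researchers analysing
infant cohorts where birth mode and intrapartum antibiotic exposure shape
early colonisation: it anchors 16S amplicon profiles on per-sample qPCR
total loads, corrects for 16S rRNA gene copy numbers, and carries the
absolute scale through group comparisons, ordination and symptom mediation.

## What it computes

Given a sample × taxon count table, per-sample qPCR totals (copies/g feces),
and a taxon → mean 16S copy-number table:

- **Absolute profiles** — `copies(t,s) = rel(t,s) · load(s)` and
  `cells(t,s) = copies(t,s) / c(t)`, after blank-control contaminant
  subtraction, rare-read filtering and per-cohort coverage cutoffs.
- **Exposure groups** — the five-group design crossing birth mode with
  intrapartum antibiotic class (VD reference, VD-cep, VD-pen, CS-cep,
  CS-other), with post-natal antibiotic censoring.
- **Differential abundance** — per taxon and timepoint, a covariate-adjusted
  model cascade (negative binomial → Poisson → quasi-Poisson → weighted
  least squares on log abundance) against the VD reference, with
  Benjamini–Hochberg control (significant: P < .05 and FDR q < 0.1) and
  log10 fold changes capped at ±5 for display.
- **Ordination trajectories** — PCoA of log profiles under Pearson
  correlation distances (d = 1 − r), per-timepoint ANOVA of groups on the
  first two coordinates, median group trajectories, and smoothed class-level
  abundance curves with a 30% confidence band.
- **Path models** — per outcome (crying VAS, defecation rate, stomach pain,
  flatulence) and timepoint: outcome ~ birth mode + antibiotic class,
  stepwise selection of mediator taxa with a risk-inflation penalty,
  exposure → taxon edge tests, and a mediated/direct label per exposure from
  direct-effect attenuation, with variance explained = corr²(fitted,
  observed).
- **Synthetic cohorts** — a generator with planted group effects, an
  age-increasing load curve, contaminated blanks, copy-number inflation and
  planted exposure → taxon → symptom chains, with full ground truth for
  power studies.

See `docs/methods.md` for the models, defaults and design choices.

## Worked example

```python
from qmpipe import (SimConfig, simulate_cohort, absolute_profile,
                    run_differential_abundance)

sim = simulate_cohort(SimConfig(seed=1))          # 92 infants, 7 timepoints
prof = absolute_profile(sim.counts, sim.qpcr, sim.copy_numbers, sim.taxonomy)
res = run_differential_abundance(prof.cells, sim.metadata, timepoints=[4.0])
row = res[(res.taxon == "Bacteroides") & (res.contrast == "CS-cep")].iloc[0]
print(f"Bacteroides, CS-cep vs VD at week 4: "
      f"FC={row.fold_change:.3f}, p={row.p:.2e}, q={row.q:.2e}, "
      f"family={row.family}")
```

prints

```
Bacteroides, CS-cep vs VD at week 4: FC=0.096, p=3.30e-19, q=4.12e-18, family=negbin
```

i.e. the planted cesarean-associated *Bacteroides* depletion (true fold
change e⁻²·⁵ ≈ 0.082 in the default configuration) is recovered as a ~10-fold
reduction in absolute abundance, fit by the primary negative-binomial family
and significant after FDR correction.

The same stages are available from the shell:

```sh
qmpipe simulate --seed 1 --out data/
qmpipe profile --counts data/counts.tsv --taxonomy data/taxonomy.tsv \
    --qpcr data/qpcr.tsv --copynum data/copy_numbers.tsv \
    --metadata data/metadata.tsv --out run/
qmpipe da --profile run/profile_cells.tsv --cohort data/metadata.tsv \
    --taxonomy data/taxonomy.tsv --rank genus --out run/da.tsv
```

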