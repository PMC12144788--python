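# lungturnover

Temporal-turnover analysis of longitudinal lung-microbiota time series, built
for people studying how airway infection communities reorganize across a
pulmonary exacerbation (PEx) in chronic suppurative lung disease — cystic
fibrosis in particular. Given per-patient taxon-by-sample tables and clinical
metadata (%FEV1, BETR disease states, antibiotic-treatment dates), the
package quantifies how fast each patient's microbiota turns over, how that
turnover relates to lung-function change, and how far in advance of clinical
treatment a turnover excursion can date the onset of an exacerbation.

## The model

**Species–time relationships (STR).** Cumulative observed taxon richness *S*
grows with observation time *T* as a power law,

&nbsp;&nbsp;&nbsp;&nbsp;*S* = *c·T*<sup>*w*</sup>,

where the scaling exponent *w* measures temporal turnover (*w* ≈ 0 for a
static community, *w* = 1 for complete replacement every sample; across
ecosystems *w* typically stays below 0.5). STRs are built with the
moving-window method: for every window length *L*, cumulative richness is
averaged over all contiguous windows of that length, which credits
immigration, local extinction, and recolonization symmetrically. *w* and *c*
come from OLS on (log *T*, log *S*).

**Colonization classes.** A taxon is *chronic* for a patient when its
temporal persistence (fraction of samples in which it is detected) exceeds
50%, *intermittent* otherwise (modified Leeds criterion). The
persistence–abundance relationship (PAR) regresses log10 mean relative
abundance when present on persistence.

**Lung function.** Cumulative absolute change in %FEV1 between consecutive
non-missing timepoints is fitted as Δ%FEV1 = *a·T*<sup>*b*</sup> with *T* in
days; *b* is the rate of lung-function change.

**Fine scale and onset.** A 5-timepoint quadrat slides along each series;
inside each quadrat a local STR exponent *w*<sub>local</sub> (and, where
possible, a local *b*) is estimated and plotted at the quadrat's middle
timepoint. PEx onset is dated at the first quadrat midpoint whose
*w*<sub>local</sub> strictly exceeds a threshold (0.5 by default, 1.0 as a
conservative variant) at or before treatment start; the *lead time* is the
number of days that crossing precedes treatment.

A synthetic-cohort generator (`lungturnover.simulate`) reproduces the
statistical regime these analyses assume — a chronic core with a dominant
pathogen, a large pool of rare intermittent taxa under Poisson immigration,
BETR schedules, a known-onset immigration burst, and coupled %FEV1
trajectories — with ground truth recorded separately, so the whole pipeline
is testable without any data download.

## Worked example

```bash
lungturnover run -o demo --seed 42
```

simulates a 12-patient cohort (two patients never exacerbate), analyzes it,
and prints:

```
Cohort turnover analysis report
================================
w_whole                  n=12   mean=0.4918 sd=0.07327
w_chronic                n=12   mean=0.01929 sd=0.009985
w_intermittent           n=12   mean=0.879 sd=0.08877
n_chronic_taxa           n=12   mean=12 sd=0
n_intermittent_taxa      n=12   mean=47.67 sd=19.26
peak_w                   n=12   mean=0.5387 sd=0.1111
lead_days_thr_0.5        n=9    mean=33.44 sd=10.16
lead_days_thr_1          absent

Subset comparisons of w (Kruskal-Wallis + Dunn):
  whole vs chronic: z=2.790 p_adj=0.01581 (H=31.139, p=1.731e-07)
  whole vs intermittent: z=-2.790 p_adj=0.01581 (H=31.139, p=1.731e-07)
  chronic vs intermittent: z=-5.580 p_adj=7.205e-08 (H=31.139, p=1.731e-07)
```

Reading the numbers: whole-microbiota turnover averages *w* ≈ 0.49 across
patients while the chronic core barely turns over (*w* ≈ 0.02) and the
intermittent taxa churn fast (*w* ≈ 0.88) — the subset ordering the
Kruskal–Wallis/Dunn block confirms. Each patient carries the full 12-taxon
chronic core and ~48 intermittent taxa. Fine-scale turnover peaks above the
0.5 literature norm (peak_w), and for 9 of the 10 exacerbating patients the
first *w*<sub>local</sub> > 0.5 departure precedes antibiotic treatment by
33 ± 10 days — the onset lead. No patient crossed the conservative 1.0
threshold, so that row is absent.

Analysis outputs land in `demo/` as TSV tables (`colonization.tsv`,
`str_fits.tsv`, `lung_function_fits.tsv`, `fine_scale.tsv`, `onset.tsv`,
`cohort_summary.tsv`, …) plus `manifest.json` with content digests of every
input and output. `lungturnover simulate` / `analyze` run the two halves
separately; `lungturnover onset --threshold …` re-scans saved fine-scale
output at new thresholds without recomputation.

### Analyzing your own cohort

Place per-patient taxon tables (`taxon_table_<id>.tsv`; first column
`taxon_id`, remaining columns sample IDs; BIOM v1 JSON also accepted) and a
`sample_metadata.csv` with columns
`patient_id,sample_id,date,fev1_percent,disease_state,treatment_start,treatment_end`
(ISO dates, empty string for missing, disease states in {B0,E,T,R,B1}) in a
directory, then `lungturnover analyze -i <dir> -o <out>`. Deposited cohorts
with other column layouts need a one-off mapping to this schema.

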