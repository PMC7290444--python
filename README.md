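# somgait

Unsupervised gait-pattern classification for children with cerebral palsy
(CP), and evaluation of ankle–foot orthosis (AFO) outcomes within the
recovered patterns.

Clinical gait laboratories summarize a limb's three-dimensional gait
analysis with the **gait variable score** (GVS) — the RMS difference over
the gait cycle between a joint-angle curve and the typically developing
(TD) reference mean — and the **gait profile score** (GPS), the RMS average
of the GVSs.  `somgait` computes a *directional* variant: the sagittal hip,
knee and ankle angles and the foot progression angle are each split into
two one-sided scores (e.g. knee flexion vs. knee extension deviation), so 9
kinematic variables yield 13 scores:

    GVS_v            = sqrt( mean_t d_v(t)^2 ),        d_v(t) = x_v(t) - m_v(t)
    GVS_v^+ / GVS_v- = sqrt( mean_t max(+-d_v(t), 0)^2 )      (split variables)
    GPS              = sqrt( (1/13) * sum_s GVS_s^2 )

with the exact decomposition (GVS⁺)² + (GVS⁻)² = full-cycle RMS² for every
split variable.  Limbs are then clustered in the 13-dimensional score
space by a 10×10 batch **self-organizing map** followed by **k-means** on
the map's codebook, with the number of clusters chosen by a silhouette
sensitivity analysis.  Recovered clusters are compared per score (Levene,
Shapiro–Wilk, one-way ANOVA, Bonferroni-corrected pairwise Welch tests),
and orthosis effectiveness is quantified per cluster and orthosis design
through ΔGPS = GPS_barefoot − GPS_orthosis, annotated against the 1.6-point
minimal clinically important difference.

Because clinical gait datasets are rarely shareable, the package ships a
synthetic cohort generator producing labeled TD limbs plus five
pathological archetypes (mild, external foot progression, crouch,
rotational, jump/equinus) with paired orthosis conditions — every pipeline
stage is testable end-to-end without patient data.  See
[docs/methods.md](docs/methods.md) for the full model description.

## Input format

A long CSV dialect, one row per (limb, condition, kinematic variable):
metadata columns `limb_id, subject_id, side, cohort, condition,
orthosis_type, variable` followed by 51 angle columns `t000 … t100` (the
gait cycle at 2% steps, degrees, 0% = ipsilateral foot strike; flexion /
dorsiflexion / adduction / internal rotation / anterior tilt / inward foot
progression positive).  Laboratories export from their motion-capture
pipeline by time-normalizing and stride-averaging upstream; C3D files are
deliberately not read.  `somgait.resample_cycle` interpolates arbitrary
(percent, angle) samples onto the 51-point grid.

## Worked example

```sh
somgait run --outdir demo --seed 0
# run complete: k=6, 250 limbs, artifacts in demo
```

This simulates the default cohort (25 TD children contributing both limbs
plus 5 archetypes × 40 limbs), scores it, trains the map, and selects the
number of clusters.  `demo/select_k.csv` shows the sensitivity analysis —
the silhouette peaks at six clusters, matching the planted TD + five
pathological patterns:

```
k,inertia,silhouette
2,454.39,0.340
4,236.62,0.376
6,135.75,0.409   <- chosen
7,119.46,0.376
10,91.96,0.324
```

`demo/crosstab.csv` tabulates prescriptions per recovered cluster for the
200 CP limbs (group 0 is the TD-dominated cluster; the few CP limbs inside
it belong to the near-TD "mild" archetype):

```
,No Orthosis,GRAFO,PLS AFO,Solid/Rigid AFO,Hinged AFO,Others,Total
Group 0,5,0,4,2,0,0,11
Group 3,8,1,27,5,4,1,46
Total,56,4,98,25,14,3,200
```

and `demo/outcome_table.csv` reports, per (cluster, orthosis design), the
share of limbs whose GPS improved with the orthosis and the mean
improvement among them — e.g. a cell with ΔGPS values {+2, −1, +3} reports
67% improved, mean ΔGPS 1.33°, mean +ΔGPS 2.50°.  Cells where no limb
improved leave the +ΔGPS average empty rather than zero.

The same stages are available individually (`somgait simulate | score |
train | cluster | stats | outcomes | report`) and as library functions
(`somgait.compute_gvs`, `somgait.train_som`, `somgait.select_k`, …).

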