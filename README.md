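# rpflux

Radiation pneumonitis (RP) is an inflammatory lung injury that develops in a
large fraction of lung-cancer patients within roughly six weeks to three
months of thoracic radiotherapy, and it is the main dose-limiting toxicity of
chest irradiation. `rpflux` implements a pathway-flux scoring system that
turns a patient's **pre-treatment blood RNA-seq profile** into a single RP
risk score, together with the cohort-level statistics used to study RP risk
factors (dose-volume histogram parameters V5/V10/V20/V30, target dose, stage,
smoking, and so on). It is written for radiation-oncology and systems-biology
analysts who want the whole analysis — scoring, association testing, survival
analysis, and predicted-vs-observed evaluation — as one tested, scriptable
package.

## The model

Expression is projected onto a *molecular signaling map*: pathways P composed
of reactions, each reaction carrying gene symbols and a regulatory role
(activator / inhibitor / neutral), plus weighted directed crosstalk edges
between pathways. The flux of a pathway for one profile is

```
F(P) = ( Σ_i I_i(reaction, role) ) / N(P)  −  flux(Crosstalk(P))

I(reaction, role)   = sign(role) · mean_g log2(abundance_g + 1)
flux(Crosstalk(P))  = mean over incoming edges (Q →w P) of  w · F_raw(Q)
```

with N(P) the pathway's reaction count. The crosstalk term uses *raw* fluxes
in a single pass, so evaluation terminates on cyclic crosstalk graphs.

A deterministic irradiation surrogate produces the post-treatment state:
every gene of a radiation-responsive reaction is scaled by
`1 + sensitivity · dose / d0` (default d0 = 50 Gy, the scale of a typical
prescribed target dose). The RP score of a patient is

```
S = log2( F(RP_treat) / F(RP_control) )
```

averaged over the RP-relevant pathways, with both fluxes floored at a small
ε (default 1e-6) so S is defined everywhere. `S ≤ 0` predicts no RP,
`0 < S < θ` a low-grade event (grade ≤ 2), and `S ≥ θ` a severe event
(grade ≥ 3); θ is configurable (default 0.8).

Around the score, `clinical_stats` reproduces the standard cohort analysis:
dichotomization of continuous dosimetry at the control-group mean, Pearson
chi-square association tables (no continuity correction) for the three
outcome splits (grade ≥ 1 / ≥ 2 / ≥ 3), Mann-Whitney U, Spearman rho, rank
AUC, exact-binomial agreement, Cox proportional hazards (Efron ties, via
lifelines) and cumulative incidence (1 − Kaplan-Meier).

Because per-patient study data were never deposited, `synthetic_cohort`
generates seeded cohorts with the published summary structure (48 patients,
~50% RP prevalence, dose 52.6 ± 11.8 Gy, V5 42.75 ± 15.96%, V20
17.34 ± 7.38%, …) whose outcomes are planted on the real flux pipeline's
score, and `reconstruct_paper_cohort()` rebuilds the published categorical
cohort exactly from its printed cross-tabulations.

## Worked example

```
$ rpflux simulate --out sim --seed 11
simulated 48 patients -> sim
$ rpflux score --out out --expr sim/expression.tsv --map sim/map.json --clinical sim/clinical.csv
scored 48 samples -> out/scores.tsv
$ rpflux stats --out out --clinical sim/clinical.csv
statistics written -> out
$ rpflux evaluate --out out --scores out/scores.tsv --clinical sim/clinical.csv
n=48 agreement=0.2292 (95% CI 0.1203-0.3731) spearman_rho=nan mann_whitney_p=0.0000 auc=0.9497
```

`scores.tsv` holds one row per patient — the aggregate score, the predicted
severity class, and the per-pathway scores:

```
sample_id  s_value      predicted_class  s_P00        ...
S001       2.544991754  grade_ge3        2.753035623  ...
S002       4.474519596  grade_ge3        4.96087643   ...
```

The evaluation line reads: the continuous score separates patients who went
on to develop RP from those who did not with rank-AUC 0.95 (the synthetic
cohort plants a strong flux→outcome coupling; see `docs/methods.md`), while
exact three-class agreement is low (23%) because the default severity cutoff
θ = 0.8 sits far below the synthetic score scale — on these data nearly every
patient is predicted `grade_ge3`, which also makes the class-ordinal Spearman
rho undefined (`nan`) and the Mann-Whitney comparison of predicted versus
observed severity distributions highly significant. `out/` also contains the
three association tables (`association_rp_ge*.tsv`), Cox summaries where a
dosimetric covariate is univariately significant (`cox_rp_ge*.tsv`), and
cumulative-incidence curves (`cumulative_incidence.tsv`, plus PNGs with
`--plots`).

The same pipeline from Python:

```python
from rpflux import load_map, read_expression_tsv, cohort_scores
import pandas as pd

expr  = read_expression_tsv("sim/expression.tsv")
smap  = load_map("sim/map.json")
clin  = pd.read_csv("sim/clinical.csv")
scores = cohort_scores(expr, smap, dict(zip(clin.sample_id, clin.dose_gy)))
print(scores[["sample_id", "s_value", "predicted_class"]].head(4))
```

```
sample_id  s_value predicted_class
     S001 2.544992       grade_ge3
     S002 4.474520       grade_ge3
     S003 4.793929       grade_ge3
     S004 5.849157       grade_ge3
```

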