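# Methods

## Flux model

A signaling map is a set of pathways, each a non-empty list of reactions; a
reaction is a non-empty, duplicate-free list of gene symbols plus a role
(activator, inhibitor, neutral → sign +1/−1/0). Pathway flux for an
expression profile x is

    F(P) = (1/N(P)) Σ_r sign(role_r) · mean_{g∈r} log2(x_g + 1)  −  C(P)
    C(P) = mean_{(Q→P, w)} w · F_raw(Q)

**Choices and why.**

* *Influence functional.* The signed mean of `log2(abundance+1)` is the
  standard variance-stabilizing expression transform; the +1 pseudo-count
  makes an all-zero profile give exactly zero influence, flux, and crosstalk,
  which the tests assert as an exact identity.
* *Crosstalk from raw fluxes, single pass.* Crosstalk edges may form cycles.
  Using raw (uncorrected) source fluxes makes F well-defined and
  order-independent without fixed-point iteration; a net-flux fixed point
  could fail to converge and would make results depend on sweep order. The
  crosstalk term is the *mean* over incoming edges so that a pathway's
  correction does not grow mechanically with its in-degree.
* *Missing genes.* Genes named by the map but absent from the profile count
  as abundance 0 and are reported in a single warning per profile (up to 20
  symbols listed). Silently dropping them would change the within-reaction
  means invisibly.
* *Gene identifiers* are case-sensitive HGNC-style symbols; no alias
  resolution is attempted.

## Irradiation surrogate

Blood is drawn before radiotherapy only, so the post-irradiation state is
modeled, not measured. Every gene appearing in at least one
radiation-responsive reaction is scaled by `1 + s·dose/d0`, where s is the
reaction's sensitivity (the maximum over responsive reactions containing the
gene, applied once) and d0 = 50 Gy sets the dose scale — a sensitivity-1 gene
doubles at a typical prescribed dose. The surrogate is deterministic and
monotone in dose; it is a minimal stand-in for whatever perturbation model
produced the published treat-state fluxes, which was never described.

## RP score

Per pathway, `S = log2(max(F_treat, ε) / max(F_control, ε))` with ε = 1e-6.
Flooring rather than excluding non-positive fluxes keeps S total and gives
S = 0 whenever both states are non-positive — the least surprising
totalization. The patient score is the arithmetic mean of S over the
RP-relevant pathways (all pathways if none is flagged); the published
analysis reports one S per patient without stating an aggregation rule, so
the mean was chosen as the simplest symmetric option.

Severity classes: `S ≤ 0 → none`, `0 < S < θ → grade ≤ 2`, `S ≥ θ → grade
≥ 3`. No severity cutoff was published; θ = 0.8 plausibly partitions the
published score range (0.0–1.2, median 0.537) and is a configuration knob,
not a constant. On synthetic cohorts (whose scores span a wider range, see
below) a larger θ is more informative.

## Clinical statistics

* *Dichotomization.* Continuous dosimetry is split at the control-group mean
  of the outcome split under analysis, rounded to 2 decimals, upper group
  inclusive (≥) — this reproduces the published row labels and thresholds
  (e.g. V5 < 37.17% vs ≥ 37.17% against the non-RP group mean).
* *Chi-square.* Pearson's statistic without continuity correction, rows with
  zero total dropped, rows that are empty in only one column retained,
  df = (r−1)(c−1) on retained rows. This exactly reproduces (to the printed
  3 decimals) 22 of the 33 published table statistics; the remainder are
  inconsistent with their own printed counts (in one verified case — the
  grade ≥ 2 gender row — the printed *count* is demonstrably a typo, since
  the published statistic is recovered once the marginals are made to sum
  to 48).
* *Permutation cross-check.* The permutation null of the Pearson statistic
  on a 2×2 table is discrete with a sizeable probability atom at the observed
  value, so the continuous chi-square tail approximates its *mid-p* (half the
  tie mass). The Monte-Carlo agreement check therefore uses the mid-p
  convention and tables of n ≥ 100; at n ≈ 50 the discrete-vs-continuous gap
  exceeds Monte-Carlo error no matter how many permutations are drawn.
* *Mann-Whitney U.* U counts cross pairs favoring the second group plus half
  ties. Exact mode enumerates all label splits (used automatically up to 12
  observations, tie-safe); otherwise the tie-corrected normal approximation
  with continuity correction is used.
* *Agreement CI.* Clopper-Pearson (exact binomial). The published 95% CI for
  39/48 agreement (77.91–99.15%) does not correspond to any standard binomial
  interval; this package reports Clopper-Pearson (67.4–91.1%).
* *Cox model.* lifelines' partial-likelihood fit with Efron tie handling
  (the publication does not state its choice). Time is onset time for events
  and follow-up time for censored patients. Constant covariates are flagged
  `non_identifiable` without fitting; non-convergence and monotone-likelihood
  escapes (|coef| > 10) are flagged, never returned silently. A
  golden-section maximizer of the hand-written partial likelihood serves as
  an independent oracle in the tests.
* *Cumulative incidence* is 1 − Kaplan-Meier on the pooled event-time grid up
  to a 90-day horizon (the three-month clinical observation window); there is
  no competing-risk treatment, matching the simple incidence curves being
  emulated.
* The multivariate covariate set is "dosimetric covariates with univariate
  p < 0.05", mirroring the published procedure. No multiple-testing
  correction is applied anywhere, also mirroring it.

## Synthetic cohort

The generator's job is to give every stage of the pipeline data with the
*published summary structure* plus a known planted signal:

* **Dosimetry.** Dose ~ N(52.6, 11.8²) Gy truncated at 0; V5/V10/V20/V30
  from the published means/SDs (42.75/15.96, 30.10/12.22, 17.34/7.38,
  11.19/5.50 %), correlated with dose (loading 0.5) and with a shared
  lung-exposure factor (loading 0.7), clipped to [0, 100].
* **Map.** `map_size = (8 pathways, 2 reactions, 3 genes)` by default. The
  first half of the pathways are RP-relevant: all-activator,
  radiation-responsive reactions with sensitivities log-uniform in [20, 150]
  — low-baseline, strongly inducible inflammatory signaling. Background
  pathways are non-responsive, occasionally inhibitory, and are the only
  crosstalk targets (weights U(0, 0.5)), keeping RP-relevant control fluxes
  strictly positive so scores never hit the ε floor.
* **Expression.** log2-abundance = gene mean (N(−2, 1) for RP-pathway genes,
  N(5, 1) for background) + a patient inflammatory factor N(0, 5²) on
  RP-pathway genes only + N(0, 0.5²) noise. The patient factor models the
  orders-of-magnitude spread of circulating inflammatory transcripts and is
  deliberately not a library-size effect, so CPM normalization would not
  remove it.
* **Outcomes.** Each patient's latent S is computed by running the *real*
  scoring pipeline at that patient's dose (the tests assert bit-equality
  with `cohort_scores`). RP occurrence is Bernoulli(logistic(b0 + 2.0·S +
  0.5·dose/10)), with b0 calibrated by root-finding so expected prevalence
  is 0.5. Case grades come from a categorical over {1,2,3,4} with base
  weights (0.45, 0.30, 0.17, 0.08) tilted by 0.5·(S − median S) per grade
  step; onset times are uniform in [14, 90] days with 90-day follow-up.
* **Seeding.** One global seed fans out to fixed substreams (map,
  expression, dosimetry, outcomes), so changing `n_patients` leaves the map
  unchanged and everything is bit-reproducible.

**Score scale.** With the planted coupling of 2.0 log-odds per score unit
and a Bernoulli-logistic outcome, a rank-AUC above 0.9 at n = 200
mathematically requires the latent score to spread with SD ≈ 1.7 or more;
the generator's expression parameters were chosen once to produce that
spread (synthetic scores span roughly 0–7, median ≈ 3, versus the published
clinical range 0.0–1.2). Rank statistics are unaffected by the scale, but
absolute synthetic score values, and any θ-based class assignment with the
default θ, should not be read as clinically calibrated.

**What the generator does not model:** RNA-seq count noise
(overdispersion, library-size variation), gene-gene correlation beyond the
single patient factor, single-lung dosimetry, competing risks, or loss to
follow-up. Passing tests therefore demonstrate correctness of the pipeline's
arithmetic and its ability to recover planted effects — not clinical
performance on real cohorts.

`reconstruct_paper_cohort()` is separate from the random generator: it
deterministically rebuilds a 48-patient categorical cohort whose
cross-tabulations match the published association tables for every
reproducible row. The published stage rows are mutually inconsistent across
the three outcome splits (the occurrence split has no stage-IV cases, the
grade ≥ 2 split has two), so stage matches the occurrence split and its
grade assignment within cases is an arbitrary deterministic completion. The
joint covariate distribution is likewise one deterministic completion of the
published marginals — only the cross-tabs are identified, and only they are
consumed downstream. Continuous dosimetry is absent (never published
per patient); the published dichotomized counts are used directly as inputs
where needed.

## Survival-recovery data

`generate_survival_data` plants a log-hazard β on a balanced binary
covariate with exponential event times (baseline rate 1/60 per day) and
administrative censoring at 90 days (~13% censoring at β = 0.8), giving the
Cox fit ≈ 435 events at n = 500; the sampling SD of the estimate is then
≈ 0.1, so single-seed recovery within 0.15 is expected but not guaranteed
for every seed.

## Numerical conventions

* ε floor 1e-6 on fluxes; θ = 0.8; d0 = 50 Gy — all configurable
  (`PipelineConfig`, YAML file, CLI flags; precedence CLI > file > defaults).
* Dichotomization thresholds rounded to 2 decimals before comparison.
* Exact Mann-Whitney at pooled n ≤ 12 (≤ 924 enumerated splits).
* Cox convergence: lifelines defaults; flagged results on any warning.
* All tabular outputs are written with `%.10g` floats and sorted sample ids,
  so repeated runs with the same seed are byte-identical.
* Problem sizes used by the verification suite: 1000 random maps (≤ 5
  pathways) against a brute-force flux oracle, 1000 random score vectors for
  the AUC/U identity, 10,000-permutation chi-square null, 200 null-coupling
  replicates at n = 100, planted-effect recovery at n = 200, Cox recovery at
  n = 500.

## Known limitations

* The true influence and crosstalk functional forms of the original
  signaling-map software are unpublished; this package's forms are its own
  minimal formalization, so absolute flux values are not comparable to the
  original system's.
* Whether the published treat-state was measured or simulated is not
  determinable from the source; the surrogate here is explicitly a model.
* The severity cutoff θ has no published calibration; class-level outputs
  (agreement, class ordinal correlations) depend on it strongly.
* Published AUC/rho/consistency values for the clinical cohort (0.933,
  0.915, 81.25%) require the unreleased patient data and are therefore
  out of reach; the synthetic planted-effect analogues (AUC > 0.9 at the
  default coupling) are properties of the generator, not reproductions.
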