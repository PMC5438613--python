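# Methods

This note documents the models, defaults, and numerical choices behind
`tc6mm`, and what the synthetic cohorts do and do not establish.

## Synthetic cohort model

`tc6mm.synth.generate_cohort` draws, per tumor sample:

1. **Subgroup** from the six-class TC-6 mix (defaults D1-HRD 0.331, D2
   0.262, CCND1-11q13 0.183, CCND3-6p21 0.019, MMSET 0.142, MAF 0.063) and
   **disease stage** (untreated 0.23 / in-treatment 0.41 / relapse 0.36).
2. **Alterations** as independent Bernoulli draws per (gene, codon-class)
   with subgroup-specific rates taken from the published subgroup and stage
   tables (e.g. *NRAS* Q61 at 0.235/0.123/0.209 in D1/D2/CCND1 vs 0.022 in
   MMSET and 0.021 in MAF), multiplied by per-stage factors normalised so the
   marginal rate is preserved (e.g. *TP53* 0.58/0.86/1.50). Two structural
   constraints are enforced: *CDKN2C* and *RB1* alterations are mutually
   exclusive (the *RB1* draw is dropped on collision), and in MMSET the
   RAS-pathway rate is conditioned on FGFR3-low status (0.56 when the
   *FGFR3* locus expression is lost, 0.21 otherwise) with activating *FGFR3*
   mutations confined to FGFR3-expressing, RAS-wild-type cases. VAFs are
   Uniform(0.05, 0.6); deletions are recorded at VAF 1. Nuisance calls the
   variant filter must remove (sub-5% VAF calls, non-activating BRAF D594G)
   are planted at low per-sample rates (0.05 / 0.02).
3. **Expression** on the log2 scale: per-probe baselines (3–7) plus additive
   effects. Translocation spikes are +6 log2 over background (a two-component
   model with separation well above the 4-unit floor the classifier assumes);
   D1-HRD carries a moderate +2 *CCND1* elevation — deliberately far below
   spike level so the cyclin-dominance rule, not spike detection, separates
   D1 from t(11;14); CCND2-group subgroups (D2/MMSET/MAF) get +5 *CCND2*.
   Secondary discriminators (SLC8A1, DSG2, NUAK1/ITGB7, NCAM1 down, etc.)
   shift by 2–3 units. RAS-RAF mutation adds +1.5–2.5 to DUSP6, SPRED2,
   DKK1, ETV5 and −1.5 to COBLL1, and −1 to every NFκB-index probe outside
   MAF (MAF carries a +1.5 NFκB elevation regardless). GEP70 high-risk
   samples shift the risk-signature probes by ±2; CDKN2C-altered samples
   lose 3 units of FAF1, RB1-altered samples gain 3 units of CDKN2C
   expression, and either adds +1.5 to the proliferation probes. Gaussian
   noise SD is 0.5. NPC controls have low cyclins and +4 B-lineage markers.
   **Probes are independent given the sample's labels** — real microarray
   gene–gene covariance, batch structure, and probe saturation are not
   simulated, so passing tests demonstrate algorithmic correctness under the
   assumed generative structure, not robustness to real-array artifacts.
4. **Survival** from an exponential proportional-hazards model
   h = h₀ · 3.5^[adverse alteration] · 3.5^[GEP70-HR], with
   h₀ = −ln(0.865)/18 per month so the standard arm sits near 86.5%
   18-month OS and the double-positive arm near the published poor-arm
   level. Censoring is exponential with median 13.5 months (the cohort's
   median follow-up); a stated alternative — tuning the censoring rate to a
   50% event fraction — is unattainable under these hazards (≈13% of
   baseline-arm subjects can fail by 13.5 months) and was not used.

All draws flow from one `numpy` Generator seeded by the config, so a fixed
seed reproduces the cohort byte-for-byte through the writers.

## Subgroup classification

Spike thresholds come from a two-component 1-D Gaussian mixture per spike
probe (10 restarts, fixed seed); the threshold is the midpoint of the
component means, with a no-spike sentinel when the means are within 1 log2
unit. Rule labels apply the fixed precedence MAF > MMSET > CCND3-6p21 >
CCND1-11q13 among spiked samples (a strict precedence makes any secondary
tie-break unreachable, so none is applied), then cyclin dominance
(mean CCND1 vs mean CCND2 panel expression) for spike-free samples. NPC
contamination is a nearest-centroid rule over the panel probes: a sample is
flagged when its distance to the NPC centroid is below 0.7× its distance to
the cohort centroid — the margin keeps heterogeneous tumor outliers from
being discarded.

The classifier is a standardized linear one-vs-rest SVM (`LinearSVC`,
C = 1.0, fixed seed) over the 24-probe panel with seven classes (six
subgroups + NPC). The probe identities are configuration: the defaults name
the discriminating genes (CCND1/2/3, WHSC1, FGFR3, MAF, MAFB, SLC8A1,
SULF2, NCAM1, ITGB7, NUAK1, DSG2, PTP4A3, ISL2, TNFSF10, S100A4, NES,
USP49, DUSP6, plus two B-lineage NPC markers) rather than published probe
set IDs, which are external to this package. Reported confidence is the
softmax of the one-vs-rest margins. Agreement excludes NPC-flagged samples
from the denominator.

## Harmonization

`mcombat_adjust` anchors a target batch to a fixed reference batch: each
shared probe is standardised by its target moments and re-expressed in the
reference moments, so the adjusted batch matches the reference per-probe
mean and SD exactly and the transform is idempotent. An optional
empirical-Bayes mode first shrinks the per-probe target mean and
log-variance toward their cross-probe averages with method-of-moments
weights; it trades exact moment matching for stability in small batches and
is off by default because the moment-matching variant is the reproducible,
assumption-light choice. Zero-variance probes are an error by default
(`passthrough` shifts them to the reference mean with a warning).

## Contingency and trend statistics

The variant filter drops calls below 5% VAF (boundary kept) and restricts
KRAS/NRAS to missense G12/G13/Q61 and BRAF to missense V600E; other genes
keep all short-variant classes and deletions. Co-occurring RAS-pathway
calls collapse to the highest-VAF call, with exact ties broken
KRAS > NRAS > BRAF.

Fisher tests are two-sided by the probability-mass rule (sum of
hypergeometric point probabilities at most the observed one — the common
software default); tail-doubling is available as an option. The trend test
is the asymptotic Cochran-Armitage form with equally spaced scores 0, 1, 2
over untreated / in-treatment / relapse; "relapse vs prior" pools the first
two stages. No multiplicity correction is applied to the per-gene tables by
default (matching how such tables are conventionally reported); BH is
available. The stage-adjusted logistic model is a Binomial GLM fit by IRLS
(tolerance 1e-8, ≤100 iterations) with likelihood-ratio tests per factor;
coefficients beyond ±10 log-odds are flagged unstable (the footprint of
separation).

## Moderated t and the threshold scan

The differential-expression t statistic shrinks per-probe pooled variances
toward a prior fitted by method of moments on log-variances: with residual
df d, z = log s² has known digamma/trigamma mean and variance offsets; the
excess cross-probe spread of z identifies the prior df d₀ (via a Newton
trigamma inverse) and its location the prior variance s₀². The moderated
variance is (d₀s₀² + ds²)/(d₀ + d) with d₀ + d degrees of freedom;
d₀ = 0 recovers the ordinary pooled t exactly, and an infinite d₀ (no
excess spread) uses s₀² with normal tails. The implementation is
cross-checked against the Bioconductor limma eBayes fit in the test suite.

The threshold scan evaluates the 2×2 Fisher table (strictly-above vs
at-or-below × mutated vs not) at every unique observed value inside the
interior 60% of percentiles — the finest grid consistent with the stated
window — and reports the cut minimising the raw p (ties to the lower
threshold) with the mutated proportions on each side and the direction of
association. Because that minimum is selected over ~0.6·n correlated
candidate tests, the **significance flag** applies the 0.005 gate to the
Bonferroni-adjusted minimum (raw best p × candidates scanned): with the raw
gate the null flag rate runs near 5%, violating the intended ≤2%
calibration, while the adjusted gate keeps it well under 2% without
disturbing genuinely dichotomous associations (planted splits flag at
p ≪ 10⁻²⁰). Both raw and adjusted p are reported.

## Survival

Kaplan–Meier estimation wraps lifelines (Greenwood variance recomputed from
the event table); S(t) is the standard right-continuous step function, so a
death at exactly t is included in S(t) — the convention used when reading
off 18-month OS. The log-rank statistic is the observed-minus-expected form
with hypergeometric variance, implemented vectorised (and verified against
lifelines) because the tree search evaluates it thousands of times.

The conditional-inference tree tests every binary alteration candidate at a
node by the two-group log-rank test, Bonferroni-adjusts across the
candidates actually tested there, and splits on the minimum adjusted p when
below α = 0.05 with both children at least `min_node` = 20 — defaults
chosen as conventional values, since nothing stronger is specified. A
label-permutation p (fixed seed) is available per candidate in place of the
asymptotic one. Candidate features are genes altered in ≥1% of samples,
mutations and deletions pooled per gene. Non-relapse subsetting is always
an explicit caller decision. The three-arm stratification assigns poor =
GEP70-HR and adverse alteration, intermediate = exactly one, standard =
neither, and reports per-arm KM curves, 18-month OS, and the k-group
log-rank p; a cohort collapsing to one arm raises a "single stratum" error
rather than fabricating a comparison.

## Degenerate inputs and tie-breaks (summary)

Constant expression vectors yield the no-spike sentinel / a warned
non-significant scan; all-zero or all-full trend counts give Z = 0, p = 1
with a warning; zero-margin 2×2 tables are errors; equal-VAF RAS calls and
equal-p scan thresholds break ties deterministically (gene order; lower
threshold). Every stochastic routine takes an explicit seed.

## Problem sizes used in the checks

The validation analog runs at n = 900 with noise SD 0.5 and ≥4 log2 spike
separation; recovery and calibration suites use 200 simulations (trees,
three-arm ordering, log-rank power), 500 replicates (threshold-scan null,
permutation uniformity), n = 2000 for logistic parameter recovery, and
n = 5000 cohorts where near-continuous null p distributions are needed —
sizes at which binomial error bands are decisive for the asserted bounds.

## Known limitations

- The generator's independence of probes given labels understates real
  expression covariance; classifier margins on real arrays will be smaller.
- The 24-probe panel, GEP70, NFκB-11 and proliferation probe lists are
  configuration; shipped defaults are gene-symbol stand-ins for the
  published lists.
- Fisher p-values are discrete and conservative in small strata; null
  uniformity holds only asymptotically (the suite checks it at n = 5000).
- Cohort-level outcome percentages (five-year OS by subgroup, published
  18-month OS per arm) depend on the real cohort and are out of scope; the
  package asserts their qualitative structure (ordering, separation) on
  synthetic data instead.
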