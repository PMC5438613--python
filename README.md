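# tc6mm

Molecular subgroup classification and codon-level mutation association
analysis for multiple myeloma cohorts with paired expression profiling and
targeted DNA panels.

## The scientific problem

Multiple myeloma is organised by its primary genetic event: an IGH
translocation that drives extreme "spike" overexpression of a partner gene —
t(11;14)/*CCND1*, t(6;14)/*CCND3*, t(4;14)/MMSET (*WHSC1*, often with
*FGFR3*), t(14;16)/t(14;20) *MAF*/*MAFB* — or, in non-translocated
hyperdiploid disease, dysregulation of a D-group cyclin. The TC-6
(translocation / cyclin-D, six-subgroup) classification assigns each
expression profile to one of **D1-HRD, D2, CCND1-11q13, CCND3-6p21, MMSET,
MAF**. The mutational spectrum of the RAS pathway is strongly structured by
these subgroups — *NRAS* Q61 hotspot mutations are common in D1-HRD/D2/
CCND1 and rare in MMSET/MAF — and alterations of *TP53*, *CDKN2C* and
*RB1* mark progressive, high-risk disease.

This package implements that analysis chain as a tested library:

| stage | module | method |
|---|---|---|
| synthetic cohorts | `tc6mm.synth` | planted spikes, subgroup/stage-dependent Bernoulli alteration rates, proportional-hazards survival |
| expression I/O + harmonization | `tc6mm.expression` | probe→gene means; M-ComBat mapping of a batch onto a fixed reference batch: x ↦ (x−μ_t)/σ_t·σ_r + μ_r per probe |
| subgroup calls | `tc6mm.tc6` | 2-component Gaussian-mixture spike thresholds, rule labels, linear one-vs-rest SVM over a 24-probe panel with a normal-plasma-cell (NPC) contamination class |
| signature scores | `tc6mm.signatures` | GEP70 risk (mean(up)−mean(down)), 11-gene NFκB index, proliferation index, mixture-threshold dichotomous calls |
| mutation statistics | `tc6mm.assoc` | VAF ≥ 5% / RAS-hotspot variant filter, two-sided Fisher exact, Cochran-Armitage trend Z = Σsᵢ(kᵢ−nᵢp̄)/√(p̄(1−p̄)[Σnᵢsᵢ²−(Σnᵢsᵢ)²/N]), rank tests, stage-adjusted logistic models |
| expression scans | `tc6mm.exprscan` | empirical-Bayes moderated t (variances squeezed toward a method-of-moments prior), BH adjustment, Fisher threshold scan over the interior 60% of percentiles |
| survival | `tc6mm.survival` | Kaplan–Meier, log-rank, conditional-inference tree over binary alterations (Bonferroni-gated log-rank splits), GEP70 × adverse-alteration three-arm stratification |

No patient data ship with the package: `tc6mm.synth` generates cohorts with
the published statistical structure (subgroup mix, stage mix, per-subgroup
and per-stage alteration rates, hazard ratios) so every stage is exercised
end to end.

## Worked example

The `analysis/` scripts chain the stages on the default synthetic cohort
(805 tumor samples + 20 NPC controls, seed 1):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_classify_subgroups.py
python analysis/07_survival_stratification.py
```

prints (abridged):

```
samples: 825 (805 tumor, 20 NPC controls)
alteration calls: 721 (RAS-RAF mutated fraction 0.359)

classifier vs truth agreement: 100.0% (validation bar: 97.9%)
NPC-contamination flagged: 20 samples (20 true controls)

conditional inference tree:
split on TP53 (Bonferroni p=0.00029, n=515)
  leaf: n=481
  leaf: n=34
CDKN2C/RB1 co-occurrence among non-relapse cases: 0
arm sizes: {'poor': 10, 'intermediate': 114, 'standard': 391}
18-month OS by arm: poor=0.0%, intermediate=54.6%, standard=83.4%
three-arm log-rank p: 1.84e-16
```

Reading this: the SVM recovers the planted subgroups above the 97.9%
validation bar and quarantines all contamination controls; the survival
tree finds the planted adverse gene (*TP53*) as its first, significant
split; *CDKN2C* and *RB1* alterations are mutually exclusive as planted;
and the GEP70 × adverse-alteration arms separate cleanly, ordered
poor < intermediate < standard. A `tc6mm` console script exposes the same
stages as subcommands (`tc6mm all --n-samples 500 --seed 7 --out run/`).

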