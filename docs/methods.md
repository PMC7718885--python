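# Methods

## The diagnostic model

The package treats ccRCC diagnosis from urine as a composite-score problem
over qPCR measurements. Six assays per subject — three candidate markers
(miR-122, miR-1271, miR-15b) and three internal controls (miR-16 as the
endogenous urine control, cel-miR-39 as the extraction spike-in, miRTC as
the reverse-transcription control) — define twelve parameters: the three
raw Cts (#1–#3) and the nine ΔCts of each marker against each control
(#4–#12, target Ct − control Ct). The controls are kept as score
ingredients rather than pure normalizers because their own Cts shift in
ccRCC urine (≈1, 4 and 6 cycles for miR-16, cel-miR-39 and miRTC in the
discovery data), so "normalization" carries diagnostic signal of its own.

Each parameter is compared against the disease training range. Let m_p and
s_p be the mean and sample SD (n−1) of parameter p in the ccRCC training
group, and let the direction flag record whether the ccRCC mean is below or
above the healthy mean. The derivative is

    D_p(x) = x − (m_p + s_p)        if ccRCC mean is lower,
    D_p(x) = (m_p − s_p) − x        if ccRCC mean is higher,

i.e. the signed distance from the edge of the one-SD disease band, oriented
so D < 0 always means "inside the diseased range". The panel score is the
sum of D_p over a parameter subset, and a subject is called diseased when
the score is strictly below the cutoff.

Assumptions worth stating: the derivative is a location shift, not a
standardized effect (the SD enters only as the band edge, so
high-variance parameters get *wider* healthy bands rather than
down-weighted contributions); direction flags are estimated from group
means and are unstable for parameters with near-zero group separation;
and the subset search is purely in-sample (see Limitations).

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| up/down screen thresholds | 1.73 / 0.77 log2 | 3.3-fold over, 1.7-fold under |
| screen α | 0.05 | per-miRNA, uncorrected (BH available via `fdr_correct`) |
| marker weights (w1…w5) | 3, 1, 1, 2, 1 | w1 fixed by convention; w4 > w5 encodes that kidney spread hurts more than tumour spread |
| Ct detection limit | 38 cycles | above it the assay is repeated; two late runs → absent, Ct := 40 |
| gates | RNU6-2 < 30 (tissue), miR-16 < 35 (urine) | strict inequalities |
| replicate aggregate | arithmetic mean of melt-passing wells | median by option |
| panel sizes searched | 7–11 of 12 | 1,585 subsets, exhaustive |
| cutoff | −6.7 | packaged default for scoring; new fits use the Youden midpoint |

The Youden-midpoint rule picks the lowest midpoint between adjacent
distinct scores that maximizes J = sensitivity + specificity − 1; on the
packaged discovery scores it lands at −6.71, consistent with the −6.7
default, and the alternative −7.10 cutoff yields identical confusion
counts on that cohort.

"Best subset" is the training-AUC maximum with a deterministic tie-break
chain (higher AUC → higher J → smaller subset → lexicographic index
order); the number of subsets sharing the maximal AUC is reported. On the
discovery derivatives the global maximum (0.9945) is attained by the
eight-parameter subset {1,2,4,5,7,10,11,12}, not by the shipped
seven-parameter panel (0.9560); since the original selection criterion for
"best" is an in-sample judgement, the package reports both rather than
privileging the search result.

## Statistical conventions

AUC is the Mann–Whitney concordance probability with ties counted ½,
oriented so that low scores indicate disease; its p-value is the two-sided
Mann–Whitney test. Sensitivity/specificity CIs are exact Clopper–Pearson
intervals from beta quantiles (at x = n the lower bound is (α/2)^(1/n));
percents are reported with round-half-up (12/14 → 86%). Group comparisons
go through a normality gate: the Lilliefors-corrected Kolmogorov–Smirnov
test at α = 0.05 on each group, choosing t-test/ANOVA+Tukey when all groups
pass and Mann–Whitney / Wilcoxon signed-rank / Kruskal–Wallis+Dunn (Bonferroni)
otherwise; correlations switch between Pearson and Spearman the same way.
Samples with fewer than 4 observations or zero variance cannot support the
Lilliefors test and are routed to the non-parametric branch — a
deterministic, conservative convention.

Numerical details: derivative ties in the direction fit (exactly equal
group means) default to "lower" with a warning; classification at the
cutoff uses strict inequality, so a score equal to the cutoff is healthy;
panel sums of the packaged fixtures reproduce the printed two-decimal
values to ±0.01 (the precision of the stored inputs); AUC tie detection in
the search uses a 1e-12 tolerance.

## The synthetic generators

The urinary-cohort generator draws each target's Ct independently as
Normal(control mean + case shift, SD), clips to the instrument range
[10, 38] (clipping, not resampling, so boundary atoms can occur), and
replaces a Bernoulli fraction with absent calls at Ct = 40. Defaults
emulate the discovery conditions: control means 31.46 / 28.31 / 29.48 for
miR-122 / miR-1271 / miR-15b (the observed population medians) with 27 /
30 / 23 for miR-16 / cel-miR-39 / miRTC; case shifts −3.9, −1.74, −0.86,
−1, −4, −6 cycles; SDs 3.0, 2.0, 2.5, 2.5, 5.0, 4.0 cycles, chosen so that
the implied two-group p-values at 13 vs 14 subjects match the discovery
report (e.g. the miR-122 shift is ≈1.3 SD, the cel-miR-39 shift only
≈0.8 SD and borderline-significant); miR-122 gets a 20% absent rate in
controls, mirroring the repeated boundary derivatives visible in the
discovery matrix. An optional shared per-subject offset models urine
concentration differences; it is off by default.

The bank generator draws per-miRNA baselines uniform on [4, 12] log2 with
tissue-specific offsets (SD 0.5) for kidney, bladder and prostate; the
ccRCC tissue shares the kidney offset and differs only by the planted
effects (+2.0 log2 on 10 miRNAs, −1.0 on 10 disjoint ones, by default),
because tumour tissue *is* kidney tissue — giving it an independent offset
would plant spurious differential expression in every miRNA. Within-tissue
noise is 0.5 log2 per array, a realistic spread for RMA-normalized
microarrays; at 20 arrays per group this puts the standard error of a
group-mean difference near 0.16 log2, so the planted +2.0 effect clears the
1.73 threshold with high probability while null miRNAs essentially never do.

What the generators do **not** model: correlation between targets within a
subject (beyond the optional shared offset), PCR-efficiency differences,
plate/batch effects, non-normal Ct tails, and the unknown covariance
structure among the three internal controls. Passing recovery tests
therefore show that the pipeline's arithmetic and search behave correctly
under the assumed noise model — not that the panel generalizes to real
urine cohorts.

## Problem sizes

The packaged discovery fixtures are 27 subjects × 12 parameters. Synthetic
validation trains and evaluates at 100 vs 100 subjects (held-out cohorts
freshly simulated from the same specification); across seeds the held-out
AUC under informative shifts averages ≈0.92 (single runs scatter roughly
±0.03), while null shifts give chance-level held-out AUC against training
AUCs around 0.6 — the in-sample optimism inherent to exhaustive subset
search on small panels. Screen recovery experiments use 340 miRNAs with
20 kidney / 20 ccRCC arrays (9 bladder, 21 prostate).

## Limitations

The subset search reproduces an ad-hoc in-sample procedure; no
cross-validation or penalization is applied in default mode, and the null
experiment above shows exactly how optimistic the training AUC can be. The
marker-prioritization weights beyond w1 are ordered judgements, not fitted
quantities. The screen applies no multiple-testing correction by default
(matching common practice in small candidate screens); with 340 miRNAs at
α = 0.05 roughly 17 false significance calls are expected, which the fold
thresholds then mostly filter out. Absent calls (Ct = 40) enter ΔCt
arithmetic numerically; downstream code can censor them via the carried
flag, but the default pipeline keeps them, as the conventional value is
itself diagnostic.
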