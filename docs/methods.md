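# Methods

This note records the models, conventions, parameter defaults, and design
choices behind `methet`, and what the simulation-based tests do and do not
establish about real data.

## Data model and coordinates

All coordinates are 1-based inclusive base pairs; a segment or atom of span
[start, end] has length end − start + 1. Only the 22 autosomes are
modelled: hemizygous allosomal signal is not comparable between sexes and
is excluded on input. A segment covering probes i…j extends from probe i's
position to one bp before the next segment's first probe (the last segment
of a chromosome ends at its last probe). This convention makes the covered
territory identical for every sample on a panel regardless of breakpoint
placement, which is what lets atomic segments tile the genome exactly and
keeps base-pair denominators consistent across samples.

Missing probe values are imputed by nearest-neighbor carry within the
chromosome (ties to the left) before segmentation, with the count logged.
Duplicate probes at one locus keep the first in genomic order.

## Winsorization

Extreme probe values are clamped to a running median ± τ·(1.4826·MAD) band
computed in a centered window of k probes, truncated at chromosome ends
(defaults k = 25, τ = 2.5, the conventional settings for this procedure).
One property worth knowing: on *exactly* piecewise-constant (noiseless)
data the running MAD is zero near a breakpoint, and the clamp overwrites
minority-side probes with the window median, shifting apparent boundaries
by up to half a window. Any amount of probe noise removes this degeneracy.
The noiseless recovery checks in the test suite therefore run without
winsorization; every noisy analysis uses it.

## Segmentation

The piecewise-constant fit minimizes total within-segment squared error
plus γ per breakpoint, subject to at least k_min probes per segment
(defaults γ = 100, k_min = 5). The package computes the exact minimizer by
an O(n²) dynamic program over breakpoint positions rather than a pruned
heuristic: the model is defined by (γ, k_min), and exactness is what the
oracle-equivalence tests certify (the test oracle is an independent
recursive search over all admissible segmentations, with a literal
enumeration cross-check at small n). Joint (multi-sample) segmentation
minimizes the across-sample total SSE with shared breakpoints and
per-sample means, and reduces to the single-sample fit at one sample.

Penalty scale. A raw-SSE penalty of 100 only makes sense at a particular
noise level. With `normalize=True` (default) each sample's noise SD is
estimated robustly from lagged differences (MAD/√2 scaled by 1.4826,
floored at 10⁻⁴) and the penalty applied is γ·σ̂² — the same convention the
established segmentation tools use when they standardize data before
penalizing. This keeps γ = 100 meaningful from noiseless simulations to
noisy arrays; `normalize=False` gives the literal raw objective. The σ̂
floor means a zero-noise cohort still carries an infinitesimal positive
penalty, so constant stretches are never split gratuitously and noiseless
recovery is exact. For joint segmentation the penalty uses the mean of the
samples' σ̂².

Chromosomes with fewer than k_min probes become a single segment with a
warning. Segmentation is per chromosome; no arm-wise constraint is
imposed. Aberration calls use strict inequalities: gain iff estimate >
+0.1, loss iff < −0.1, so a value exactly at the cutoff is neutral. The
same strictness applies to every other cutoff in the package (variance
> 0.03, pairwise difference > 0.1, blacklist frequency > 10%).

## Probe blacklist

Regions recurrently aberrant in non-cancer samples reflect germline copy
number variation and platform artefacts. An atomic segment is blacklisted
when its aberration frequency (|estimate| > 0.1, gains and losses pooled)
is strictly above the threshold (default 10%) in **every** supplied
non-cancer cohort; flagged atoms merge into maximal intervals. The
frequency rule is applied to atomic segments (the partition the rest of
the pipeline works on). A probe is excluded when its position lies in a
closed blacklist interval. Filtering is idempotent, and a blacklist built
at a lower threshold is a superset of one built at a higher threshold.

## Heterogeneity scores

The Euclidean score for a patient is the mean, over all unordered pairs of
their first-resection deposits, of √Σ_atoms (a−b)². Atoms are unweighted
dimensions; the base-pair-weighted perspective is deliberately a separate
statistic (below) rather than a weighting option, so the two can be
cross-checked. The variance filter (sample variance, ddof = 1, strictly
> 0.03; 0.05 and "none" as robustness variants) is computed across **all**
samples in the analysis set, not per patient: the filter's job is to select
atoms that are informative in the cohort, and per-patient filtering would
make patients' scores live in different spaces. Patients with fewer than
two deposits get an absent score with a recorded reason.

The proportion-of-genome-different score is, per pair, the percent of
covered base pairs in atoms where |a−b| > 0.1 (no variance filter),
averaged over pairs. It is invariant to refining the atomic partition.

The longitudinal variant averages cross-resection pairs (first × second)
only, since it measures change between surgeries; an all-pairs option
exists. The ploidy-adjusted variant divides each deposit's total allele
copies (nA+nB) by its ploidy ψ before the Euclidean score (no filter), so
a whole-genome duplication with no other change scores zero.
Cancer-cell-fraction diversity is the mean absolute pairwise CCF
difference, skipping deposits with a missing estimate.

For survival grouping, a patient exactly at the cohort median score goes
to the HIGH group: with an odd number of scored patients this yields the
(n−1)/2 low / (n+1)/2 high split.

## Genomic complexity

Percent of covered base pairs in segments called gain or loss at ±0.1. The
denominator is the retained (post-filter) territory, not the full genome
length: excluded regions carry no calls, and using the analyzed span keeps
the percentage interpretable across panels. Patient-level complexity
averages the first-resection deposits. The cohort aberration-frequency
profile counts a patient as gained (or lost) at an atom if **any** deposit
is, so one patient can contribute to both the gain and loss frequency at
the same atom. Copy-neutral LOH is the percent of base pairs with allele
copies {0, 2} exactly.

## Clustering and bootstrap support

Complete-linkage agglomeration on Euclidean distances over
variance-filtered atoms, with tied merge heights broken toward the pair
containing the smallest sample index (fully deterministic). Cluster
support resamples **atoms** (the feature columns) with replacement at
scales r ∈ {0.5, …, 1.4}: per scale, round(m·r) atoms are drawn, the tree
rebuilt, and BP_r is the fraction of replicates whose tree contains the
node's exact member set. AU comes from the weighted least-squares fit
Φ⁻¹(1−BP_r) = v√r + c/√r (weights n·φ(z)²/(BP(1−BP))), AU = 1 − Φ(v−c);
BP is reported at r = 1. Per-scale BPs of 0 or 1 are continuity-corrected
to 1/(2n) from the boundary; a node recovered in every replicate at every
scale is reported AU = BP = 1, and a node never recovered gets AU = 0 with
a flag. Replicate trees are built with the scipy linkage routine (tie
behavior in replicates only affects counting noise); the reported primary
tree uses the deterministic in-package agglomeration, which tests verify
against scipy on random inputs. A patient is "monophyletic" when some tree
node's member set equals exactly their deposit set; solitary deposits are
not assessable.

## Survival statistics

Endpoints are months from the start of metastasis treatment; three-year
analyses apply administrative censoring (time′ = min(t, 36), events only
within 36). Kaplan–Meier rates at 36 months carry the last estimate
forward when follow-up ends earlier (the standard product-limit
convention). The log-rank test of linear trend uses equally spaced scores
over ordered strata, the usual hypergeometric variance, and one degree of
freedom; with two strata it reduces exactly to the ordinary log-rank test
(verified against lifelines). Cox models use lifelines (Efron ties);
rank-deficient covariate matrices raise immediately, and non-convergence
is returned as a flagged row rather than silently dropped. Multivariable
models enter, in one step, every covariate with univariable Wald P < 0.1.
The complexity prognostic threshold is fixed at 25% (configurable).
Segment-wise group comparisons are Welch t-tests (Satterthwaite df) per
atom with Benjamini–Hochberg q-values; atoms constant in both groups get
p = q = 1 by convention, and two zero-variance groups with equal means
give p = 1.

## The synthetic cohort generator

The generator emulates a 45-patient multi-deposit liver-metastasis cohort
with branched copy-number evolution:

- **Deposits per patient**: 1 + min(Poisson(1.7), 6), giving mean ≈ 2.7,
  median 2, range 1–7; about 18% of patients get a second resection with
  1–2 additional deposits.
- **Ancestor clone**: diploid plus Poisson(λ_anc = 25) events. An event is
  arm-level with probability 0.5, otherwise focal with lognormal length
  (median 10 Mb before genome scaling, σ = 0.8, at least 5 marker
  spacings); it adds ±1 copy to one allele (clipped at zero after summing
  overlapping deltas). Arm choice is weighted 3:1 toward the arms
  recurrently altered in colorectal cancer, with direction biased 0.8
  toward gain on the gain-recurrent arms (7p, 7q, 8q, 13q, 20q) and toward
  loss on the loss-recurrent ones (1p, 4p, 4q, 8p, 17p, 18q). Copy-neutral
  LOH is an explicit rare event type (lose one allele, gain the other),
  rate λ_cnLOH = 1.2 per clone. λ_anc and λ_cnLOH are set so the simulated
  cohort reproduces realistic medians: patient-wise complexity near 28% of
  the genome and cnLOH near 3% of base pairs, with copy-number aberration
  an order of magnitude more territory than cnLOH.
- **Branch divergence**: each deposit adds Poisson(rate) private events,
  where the patient's rate is Gamma(shape = 1, mean = λ_div = 2). The
  gamma layer matters: real cohorts show several-fold between-patient
  variation in inter-deposit heterogeneity, and a fixed rate for everyone
  would compress true divergence into a narrow band that no score could
  meaningfully rank.
- **Purity**: hierarchical — a patient-level mean uniform on (0.26, 0.95)
  with per-deposit Gaussian jitter (SD 0.05, clipped to the range). The
  hierarchy is essential: with purity drawn independently per deposit, the
  same clonal event renders at different log-ratio amplitudes in different
  deposits, and purity variation — not genomic divergence — dominates the
  heterogeneity scores. Sample CCF equals purity, missing in ~4.5% of
  samples (emulating occasional estimation failure).
- **Rendering**: per probe, LRR = log₂(((1−ρ)·2 + ρ·(nA+nB))/2) + N(0, σ)
  with σ = 0.1 by default; a homozygous deletion at ρ = 1 is floored at
  −8. Markers are evenly spaced (700 bp full scale).
- **Survival**: exponential event times with hazard h₀·exp(β·1[true
  divergence above cohort median]); baselines give the low group a median
  PFS of 17 months and OS of 52 months, with β = log 2.5 (PFS) and
  log 10/3 (OS), i.e. low-vs-high hazard ratios of 0.4 and 0.3. Censoring
  is independent Uniform(0, u) with u solved numerically so the expected
  censoring fraction matches the configuration (default 30%); a censoring
  fraction of 1 censors everyone at 60 months.
- **Reproducibility**: one RNG stream per patient derived from the master
  seed, so a patient's genomic truth is invariant to cohort size; the
  survival stream is separate (it needs the cohort median). File outputs
  are byte-identical across runs of the same configuration.
- **Scaling**: `SimulationConfig.small()` uses a 1/10-length genome with
  100 kb marker spacing (≈ 2,900 probes). Every downstream statistic is a
  base-pair proportion, per-atom value, or rank statistic, hence invariant
  to this scaling; the full-scale configuration is the same model with
  more probes. Tests and the acceptance script use the scaled genome; the
  problem sizes they run (8–50 patients per check, 45 for the headline
  run) are stated in the respective scripts.

What the simulations do **not** emulate: B-allele frequencies and
genotypes, subclonal mixtures within a deposit, whole-genome doubling
dynamics, GC waves or other spatial artefacts, and platform-specific probe
classes. Passing recovery tests therefore demonstrates the statistical
machinery — segmentation exactness, score arithmetic, truth recovery under
the stated noise model, FDR control, bootstrap calibration — not
robustness to every artefact of real arrays.

## Numerical choices and degenerate inputs

- Exact ties in the DP objective resolve toward fewer segments (the
  penalty is strictly positive even at the σ̂ floor).
- Winsorization with zero MAD clamps to the window median.
- `variance_filter` errors when nothing survives, advising `cutoff=None`,
  rather than silently returning an empty space.
- KM at a horizon past the last follow-up carries the last value forward.
- Cox collinearity is detected by a rank check before fitting.
- Welch tests on zero-variance data use the conventions above instead of
  propagating NaNs into the BH correction.
- All seeds are plain integers; every stochastic routine takes one
  explicitly and seeded runs are bit-reproducible.

## Known limitations

- The Euclidean score inherits the resolution of the atomic partition:
  with cohort-wide atoms its value depends on the cohort composition
  (adding very fragmented samples refines everyone's atoms). The
  proportion-of-genome score is invariant to refinement and is the more
  comparable quantity across analyses.
- Heterogeneity measured on purity-uncorrected log ratios mixes genomic
  divergence with residual purity differences between deposits; the
  ploidy-adjusted variant exists precisely to check this.
- Hazard-ratio estimates for the median-split score on simulated cohorts
  are attenuated relative to the generator's true group effect, because
  the measured split misclassifies patients near the median — an inherent
  property of dichotomized noisy biomarkers, visible here because the
  truth is known.
- The exact DP is O(n²) per chromosome; at full SNP-array density
  (~10⁵ probes per chromosome) it is compute-intensive, and the scaled
  genome or coarser panels are the intended operating point for
  exploratory work.
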