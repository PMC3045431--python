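# Methods

## The measurement model

A pool of N diploid individuals (the screen modelled here used N = 311 cases
and N = 360 controls) is sequenced as one library over a set of PCR
amplicons. At a covered position, reads arrive on each strand independently;
a variant present on k of the 2N chromosomes contributes alternate reads at
frequency p = k/(2N), and sequencing/PCR error contributes additional
alternate reads whose rate depends on the ordered base change (ref → alt).
Only aggregate frequencies are observable; no per-individual genotype exists
at this stage.

The caller treats error as a constant per-substitution-type proportion and
estimates it empirically rather than parametrically: for each of the 12
substitution types, the per-strand frequencies observed at every non-primer
position whose reference matches the type's reference base form an empirical
error distribution, and the 97.5th percentile of that distribution is the
calling cutoff t for that type and pool. A candidate is called when its
frequency strictly exceeds t on **both** strands. The dual-strand rule is
the central artefact filter: under independent strand errors the chance of a
false dual-strand exceedance is near (1 − 0.975)² ≈ 0.06%, and the
strand-balance score s = |f_fwd − f_rev| / mean(f_fwd, f_rev) (0 = balanced,
2 = single-strand) is attached to every candidate for downstream QC.
Thresholds are computed per pool, so a variant may clear calling in one pool
and not the other.

Derived quantities: estimated pool allele count k̂ = round(f_combined · 2N)
(ties away from zero), and the detection limit of a cutoff,
k_min(t) = the smallest integer k with k/(2N) > t. Note k̂ is taken at face
value from the observed frequency, which includes the error background — at
an error rate λ the estimate is biased upward by about λ·2N allele copies.
Recovery to ±1 copy therefore holds for low-error substitution types
(λ ≲ 0.001 at 2N = 622) and degrades for noisy ones; no background
subtraction is attempted because the published workflow reported raw pool
frequencies.

Association uses 1-df Pearson χ² without continuity correction and odds
ratios with Woolf CIs, on two bases: allele counts (2 per individual;
primary, and what the screen's in-text statistics use) and carriers
(≥ 1 minor allele; what its replication table uses). Published
frequency-only tables are converted back to nearest-integer allele counts;
for rare variants every carrier is assumed heterozygous, making carrier and
allele counts equal. No multiplicity adjustment is applied to the primary
p-values (a Bonferroni column is emitted for transparency).

Meta-analysis is standard DerSimonian–Laird: θ = ln OR, SE = CI log-width
/ 3.92, method-of-moments τ² truncated at zero, normal two-sided p. The CI
inversion uses the multiplier 1.96 exactly (not a higher-precision normal
quantile): published intervals are built with 1.96, and inverting them with
anything else fails to reproduce published pooled values. Q and
I² = max(0, (Q − df)/Q) are reported even when not used.

## The synthetic generator

`poolscreen.simulate` emulates the pooled-amplicon design: per amplicon and
strand, depth is Poisson around a per-amplicon mean; variant reads are
Binomial(d, p); each alternate base b ≠ ref then receives
Binomial(d − variant reads, λ_{ref→b}) error reads, independently per b (a
variant read mis-read as a third base is ignored — negligible at the rates
modelled; in the astronomically rare event that independent error draws
exceed the available reads, the position's error draws are redrawn so read
counts always conserve). Overlapping amplicons contribute additively to one
pileup line per position. Output is byte-identical under a fixed seed.

Defaults mirror the screen's geometry: N = 311, 16 amplicons of 250 bp with
20 bp primers at each end, and per-strand mean depth 20,000 (the screen's
per-position depths ran ~24,000–120,000 summed over strands, varying by
amplicon). The per-substitution error rates are not published; the defaults
span 0.001–0.01 with G→A lowest (0.001) and A→C highest (0.010), matching
the reported ordering in which G→A variants were detectable down to 3 copies
in 622 while A→C required 7. Under these defaults the simulated cutoffs at
screen-scale depths imply detection limits of roughly 1–7 copies depending
on type. λ is capped at 0.05: beyond that the "rare error" approximations
above stop being reasonable.

What the generator does *not* model: read-level effects (alignment artefacts,
indels, PCR duplicates, base-quality structure), systematic strand bias
(strands are exchangeable by construction, so the strand-balance score is
exercised only by sampling noise and planted one-strand patterns in tests),
unequal DNA contribution of pool members (pool frequency is treated as
exactly k/2N), and position-dependent error (rates depend only on the base
change). Passing tests therefore demonstrate the pipeline's statistical
behaviour under its own stated model, not robustness to the full messiness
of real pooled libraries — which is precisely why the original workflow
validated calls by individual genotyping.

## Numerical and design choices

* **Quantile definition** — linear interpolation between order statistics
  (numpy's default), switchable to nearest-rank; the choice matters at the
  tail with discrete counts, so it is explicit and configurable.
* **Strict inequality at the cutoff** — f = t is *not* a call; with
  empirical thresholds equality occurs with nonzero probability and the
  conservative direction is chosen.
* **One-pass thresholds by default** — variant positions are not excluded
  before computing the error percentiles. Rare variants inflate the 97.5th
  percentile negligibly when they occupy ≪ 2.5% of a type's observations; a
  two-pass mode (exclude first-pass calls, re-estimate, re-call) is provided
  and can only lower thresholds.
* **Pooled strand distributions by default** — both strands' frequencies
  enter one error distribution per substitution type; a per-strand mode is
  available.
* **Minimum depth 50 reads/strand** for a position to be *callable*
  (thresholds use all positions with nonzero depth on both strands);
  frequencies at lower depth are too granular to compare against cutoffs of
  order 0.001–0.01.
* **Minimum 40 observations** per substitution type for a trustworthy
  threshold; below that the type is flagged unreliable (still computed),
  zero observations is an error.
* **Primer masking** — any amplicon's primer excludes a position, even
  inside an overlapping amplicon's insert (conservative tie-break).
  Intervals are half-open, 1-based internally; BED input is 0-based.
* **Degenerate inputs** — ref = N or an empty strand skips a position;
  both-zero frequencies give an undefined (NaN) strand-balance score; a zero
  2×2 margin gives NaN χ² with a warning; a zero cell makes the OR undefined
  unless the Haldane +0.5 correction is explicitly enabled; meta-analysis
  requires ≥ 2 studies and rejects degenerate CIs (SE = 0).
* **"Not present" pool entries** — a substitution absent from a pool enters
  validation-correlation analyses as frequency 0 with a missing strand-
  balance score; missing scores are retained by the score filter (only
  scores measured and > 1 exclude).

## Problem sizes used by the test suite

Simulation-backed checks are sized to give stable statistics at interactive
runtimes: caller calibration uses one pure-error pool of 10⁴ positions at
200 reads/strand (observed single-strand exceedance of the 97.5% cutoff
≈ 2.5%, dual-strand ≪ 0.5%); threshold ordering uses 100 seeds × 600
positions at 500 reads/strand; planted-variant recovery uses 20 seeds ×
3,000 positions at 10⁴ reads/strand with variants of 3–12 copies of the
cleanest type (G→A); the end-to-end case/control check uses 50 seeds at
2,000 reads/strand with 11 vs 3 planted copies. The Poisson depth model is
load-bearing for the calibration check: varying denominators break the ties
that a fixed depth would create in the discrete frequency lattice, keeping
the empirical-quantile exceedance near its nominal 2.5%.

## Known limitations

* The validation-correlation value depends on exactly which variants enter
  the comparison; the bundled computation (case pool, strand-balance ≤ 1,
  absent entries as 0) gives r ≈ 0.83. The analogous control-pool set
  includes a high-frequency strand-balanced artefact that individual
  genotyping refuted, so the control correlation is not meaningful without
  further curation; the function reports whatever set it is given.
* Count reconstruction from rounded published frequencies is not always
  invertible (nearest-integer counts can disagree with a published OR in the
  third decimal); meta-analysis therefore consumes published ORs/CIs
  directly rather than reconstructed counts.
* The caller has no indel support, no base-quality model, and no genotype
  likelihoods — none of which exist meaningfully for pooled data at this
  design.
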