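# poolscreen

Rare-variant screening from pooled-DNA amplicon deep sequencing.

When the genomic DNA of hundreds of individuals is pooled, PCR-amplified and
deep-sequenced as a single library, individual genotypes are lost but the
*pool allele frequency* of every variant is observable: a variant carried on
k of the 2N chromosomes in a pool of N diploid individuals appears in the
reads at frequency p = k/(2N). At the depths such screens reach (tens of
thousands of reads per position), the limiting factor is not coverage but
sequencing/PCR error, which differs systematically between the 12 ordered
base changes (ref → alt). `poolscreen` implements the full analysis chain of
such a screen:

1. **Pileup parsing** (`poolscreen.pileup`) — strand-aware base counts from
   samtools text pileup, with primer-region masking from a BED-like amplicon
   file.
2. **Empirical-error variant calling** (`poolscreen.caller`) — for each of
   the 12 substitution types, the per-strand frequencies observed across all
   non-primer positions of a pool form an error distribution; its 97.5th
   percentile is that type's calling cutoff t. A substitution is called only
   if its frequency exceeds t on **both** strands. Each candidate carries a
   strand-balance score s = |f_fwd − f_rev| / ((f_fwd + f_rev)/2) ∈ [0, 2]
   (high s flags strand-biased artefacts), an estimated pool allele count
   k̂ = round(f·2N), and the design's detection limit is the smallest k with
   k/(2N) > t.
3. **Case-control association** (`poolscreen.association`) — 2×2 tables on
   an allele basis (minor/major allele counts) or carrier basis
   (carriers/non-carriers), 1-df Pearson χ² without continuity correction,
   odds ratios with Woolf confidence intervals
   exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)), reconstruction of counts from
   published frequencies, and Pearson correlation between pool and
   individual-genotyping frequencies for validation.
4. **Random-effects meta-analysis** (`poolscreen.meta`) — DerSimonian–Laird
   pooling of per-study (OR, 95% CI): θᵢ = ln ORᵢ, SEᵢ = (ln hi − ln lo)/3.92,
   τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw)), pooled θ* with weights
   1/(SEᵢ² + τ²).
5. **Synthetic pooled sequencing** (`poolscreen.simulate`) — a generator
   with known ground truth: per strand, depth is Poisson, variant reads are
   Binomial(d, p), and each alternate base receives Binomial error reads at
   its substitution type's rate, so the whole pipeline is testable without
   external data.

The package ships the published tables of the Nicastrin (NCSTN)
pooled-sequencing Alzheimer's screen it models (311 cases / 360 controls,
16 amplicons) as bundled datasets (`poolscreen.datasets`), used by the
examples and tests below.

## Worked example

Association and meta-analysis straight from the bundled screen data:

```python
from poolscreen import GenotypeCounts, allele_table, pearson_chi2, odds_ratio, woolf_ci, dl_meta
from poolscreen.datasets import replication_effects

# N417Y: 11 heterozygotes of 287 cases vs 3 of 345 controls
table = allele_table(GenotypeCounts("case", 287, 0, 11),
                     GenotypeCounts("control", 345, 0, 3))
chi2, p, _ = pearson_chi2(table)
print(f"chi2={chi2:.2f} p={p:.3f} OR={odds_ratio(table):.3f} CI={woolf_ci(table)}")

res = dl_meta(replication_effects())
print(f"pooled OR={res.or_:.3f} CI=({res.ci_lo:.3f}, {res.ci_hi:.3f}) "
      f"z={res.z:.2f} p={res.p:.3f} tau2={res.tau2}")
```

prints

```
chi2=6.28 p=0.012 OR=4.474 CI=(1.2421701723038894, 16.116044161666533)
pooled OR=2.318 CI=(1.007, 5.340) z=1.98 p=0.048 tau2=0.0
```

i.e. the rare N417Y variant is over-represented in cases (χ² = 6.28,
p = 0.012, allele OR ≈ 4.47), and pooling the three replication cohorts with
a random-effects model leaves a weakly significant overall effect (z = 1.98,
p = 0.048; τ² truncates to 0 because Cochran's Q falls below its degrees of
freedom, so the pooled value equals fixed-effect inverse-variance pooling).

The same workflow is available from the shell:

```bash
poolscreen simulate --config design.yaml --out-pileup pool.pileup \
    --out-truth truth.tsv --out-amplicons amps.bed
poolscreen call pool.pileup --amplicons amps.bed --n-individuals 311 \
    --out-calls calls.tsv --out-thresholds thresholds.tsv
poolscreen assoc genotypes.tsv --out assoc.tsv
poolscreen meta effects.tsv --out pooled.tsv --weights-out weights.tsv
```

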