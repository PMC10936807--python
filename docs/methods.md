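# Methods

## Problem and model

Haplotagging assigns each long sequencing read to the parental haplotype
it originated from, using the alleles the read shows at known phased
heterozygous SNVs. Within a phase set *p* with haplotypes
H_p = {h_1, …, h_l} (l = ploidy, 2 for a diploid), a read *r* overlapping
*n* phased het sites is scored per haplotype with a multinomial
likelihood. An observed base matching h_i's allele is a true match with
probability 1 − e; an observed mismatch is a true mismatch with
probability e/3 (three possible wrong nucleotides), where e is the
sequencing error probability. With k_m matches and k_nm = n − k_m
mismatches at a constant error rate ε:

    P_hi = n! / (k_nm! · k_m!) · (ε/3)^k_nm · (1 − ε)^k_m

The per-base generalization replaces ε with the site-specific error
e_r[a] = 10^(−0.1·q) from the Phred quality q of the aligned base, and is
evaluated in log10 space:

    log10 P_hi = Σ_a [ x_a·log10(1 − e_r[a]) + y_a·log10(e_r[a]/3) ]
                 + log10 n!/(k_nm!·k_m!)

with x_a/y_a the match/mismatch indicators. Uniform priors β_hi = 1/l
produce posteriors and likelihood ratios in an *odds-like* form: each
haplotype's term is divided by the sum of the **other** haplotypes'
terms,

    P(r)_hi = P_hi·β_hi / Σ_{j≠i} P_hj·β_hj ,
    LR_hi   = P(r)_hi / Σ_{j≠i} P(r)_hj .

This is implemented exactly as specified, not normalized; a consequence
(asserted by tests) is that for a diploid the best haplotype's log10 LR
equals twice the raw log10 probability gap. The read is tagged with the
argmax-LR haplotype when its LLR strictly exceeds the threshold
(default 0) and no tie is present; reads overlapping zero het sites are
*untaggable*; phaseable reads failing the test are *untagged*.

### Numerical choices

- All probability arithmetic in log10 with log-sum-exp; factorials via
  log-gamma. A naive linear-space evaluation is kept in the test suite as
  an oracle for reads with ≤8 sites (above that, and in the posterior
  denominator generally, linear space cancels catastrophically — the
  reason the implementation is log-space throughout).
- Per-base errors are clamped to [1e−12, 1−1e−12]; a q=0 base is
  uninformative, not fatal.
- Tie tolerance 1e−9 on log10 LR.
- Reads spanning several phase sets are scored only within the phase set
  contributing the most observations (cross-phase-set likelihoods are not
  comparable); an equal split leaves the read untagged.
- Records without base qualities fall back to the global ε for every
  base.

## Error model (FDR control)

A sequencing error at a het site can reduce the tagging decision to a
coin flip; with three possible wrong bases each read mistags with
probability ≈ ε/3 (the number of sites per read is deliberately ignored
— a conservative simplification). Treating reads as Bernoulli trials
with success probability 1 − ε/3, the expected number of mistags among N
phaseable reads is N·ε/3 (the mean of the implied negative-binomial
error distribution). To enforce a target FDR, the
floor(N·(ε/3)·(1 − FDR)) lowest-LLR tagged reads are relabeled
untagged; ties at the cut break by read name. ε defaults to the mean of
the BAM `de` tags (aligner divergence) over processed reads, with a
quality-string fallback and a user override. `fdr = 0` disables the
filter. A `mean_mode="eps"` switch exposes the alternative N·ε reading
of the expected-error mean for sensitivity analysis; the default ε/3
reading is the one consistent with the per-read error rate above. The
filter only ever demotes tagged → untagged; it never flips a haplotype
and never touches untaggable reads.

## Synthetic data generator

The simulator emulates a nanopore-style whole-genome run on a diploid
sample with fully phased het SNVs:

| parameter | default | why |
|---|---|---|
| genome_length | 1 Mb (8 Mb in the benchmark) | desk-scale surrogate for a human chromosome |
| het_snv_rate | 1/1500 bp | human heterozygous SNV density (individual genomes differ at a few million sites) |
| read length | gamma, mean 25 kb, sd 20 kb, truncated to [100, 1 Mb] | MinION R10.4-class length profile |
| per-read accuracy | truncated normal, mean 0.98, sd 0.02 on [0.01, 1] | R10.4-class accuracy |
| error ratio | 23:31:46 sub:ins:del | nanopore error-type composition |
| read_depth | 1× per haplotype (5× in the benchmark) | coverage per haplotype |

Reference bases are uniform random; variant positions are sampled
without collision (count ~ Poisson(L·rate)); each site gets a random
non-reference alternate and a random phase orientation, all in one phase
set per contig. Haplotype consensus sequences apply each haplotype's
alleles to the reference (SNV-only, so coordinates are preserved;
verified against `bcftools consensus`). Reads are drawn uniformly from
each consensus until the per-haplotype coverage target is crossed; each
base errs independently with probability 1 − accuracy and erring
positions become single-base substitutions, insertions or deletions in
the 23:31:46 proportions. Records are emitted directly as a
coordinate-sorted, indexed BAM whose coordinates and CIGARs come from
the error-injection trace — no external aligner in the loop — with the
truth haplotype and origin interval encoded in the read name, the
realized per-read error rate in the `de` tag, and base qualities set to
its Phred equivalent. Output is byte-identical under a fixed seed.

What the generator does **not** emulate: homopolymer-context error
clustering (errors are i.i.d. per base), multi-base indels, chimeric or
supplementary alignments, mapping error, reference bias, variant-calling
and phasing errors in the input VCF. Passing tests therefore demonstrate
correctness of the scoring/labeling machinery under the model's own
assumptions, not performance on biological data, where misalignment and
VCF errors add failure modes the model does not see. One distributional
subtlety: capping accuracy at 1.0 pulls the realized mean accuracy of
the truncated normal to ≈0.974 for the default (0.98, 0.02) setting; the
simulator tests oracle against the analytic truncated mean.

## Evaluation

A read is *phaseable* when its alignment overlaps ≥1 phased het SNV by
coordinate (engine tag `XV`). Per read: correct tag → TP; wrong tag on a
phaseable read → FP; phaseable read without a tag (untagged, or
untaggable because its only variant bases were deleted) → FN;
nonphasable read left untaggable → TN. A nonphasable read carrying a tag
would also be FP; it is counted and asserted zero, since the engine
cannot tag a read without observations. Derived rates: IHR = FP /
phaseable, FNR = FN / phaseable, recall = TP / phaseable. The PR curve
sweeps every distinct LLR threshold descending (precision among tags at
or above the threshold; recall over all phaseable reads, so
never-tagged reads cap it) and PR-AUC is the trapezoid over recall,
anchored at recall 0 with the strictest threshold's precision. The
low-LLR error-concentration check uses a Kruskal–Wallis rank test of
correct versus incorrect tag LLRs.

## Benchmark problem sizes

The packaged benchmark (tests and `scripts/acceptance.py`) uses an 8 Mb
(6 Mb in tests) genome at 1/1500 bp het density with 5× coverage per
haplotype — about 3,000 phaseable reads carrying ~17 het sites each —
which preserves the quantities the model depends on (variant density per
read, error rate, read-length law) at desk scale. Error-model behavior
(FDR monotonicity, rank tests) is exercised under a deliberately harsher
configuration (accuracy 0.90, mean length 2.5 kb) because the default
conditions produce too few errors for rank statistics at this scale.

## Known limitations

- The scoring model is l-general but the simulator and CLI workflows are
  validated for diploids only.
- Indels are never used as markers; non-SNV records are filtered out.
- One primary alignment per read name is assumed (duplicates and
  supplementary records pass through unscored).
- The FDR filter controls the *expected* error count under the ε/3
  approximation; it is not a per-read error probability and low-LLR
  reads remain a mixture of correct and incorrect tags.
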