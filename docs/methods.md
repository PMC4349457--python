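# Methods

## Scope and data model

`centroseq` analyses the sequence properties of centromere central-domain
DNA and their predicted consequences for nucleosome occupancy.  Sequences
are `SequenceRecord`s (uppercase A/C/G/T/N with an explicit linear or
circular topology — circular plasmid templates differ from linear
fragments only by declaration, never by inference).  Intervals are
0-based half-open `Region`s; BED output uses the same convention, and
origin-spanning intervals on circular records are written start > end
with length `(end − start) mod L`.

## Composition features

AT content excludes N from numerator and denominator; reported integer
percentages round half-up, so a 0.715 fraction prints as 72%.
Dinucleotide frequencies are overlapping counts (L−1 linear, L circular
including the wrap pair), N-containing pairs dropped before
normalization.  Poly(dA:dT) tracts are maximal homopolymer A or T runs of
at least a configurable minimum (default 5 bp); a mixed A/T mode is
available for AT-patch analysis.  N breaks every tract.

### Periodicity estimation

The periodicity of a dinucleotide set (default AA/TT/TA/AT, the
rotational-signal set) is estimated from the binary indicator of
positions starting such a dinucleotide.  Two statistics are computed on
the mean-centred indicator and combined multiplicatively into the score
whose argmax is `peak_period`:

1. the Hann-windowed, zero-padded periodogram interpolated onto a uniform
   period grid (default 2–50 bp, 960 points), and
2. an autocorrelation comb: for each candidate period p, the
   autocorrelation sampled at multiples of p up to a lag ceiling of one
   nucleosome footprint (150 bp), each tooth averaged over ±1 bp,
   triangularly tapered and normalized by the root of the effective tooth
   count so that pure noise scores equally at every period.

The two estimators fail in complementary ways, which is why neither is
used alone.  The periodogram assumes one coherent phase along the whole
sequence; rotational signals phased to different nucleosomes need not be
in register (two dyads 200 bp apart with a 10.1-bp signal are 8.1 bp out
of phase), and out-of-register patches cancel in a full-length transform.
The comb is phase-insensitive within its lag window but, like any comb
statistic, responds at integer multiples and fractions of the true
period; the periodogram vetoes those because a genuine fundamental has no
subharmonic Fourier component, while the comb vetoes the periodogram's
harmonic ambiguity for strictly periodic (impulse-train) signals whose
Fourier harmonics all carry equal power.  On clean planted signals at
periods 5, 10, 10.1 and 11 bp the combined estimator recovers the period
to well under 0.1 bp; a flat indicator (no marked dinucleotides, or a
homopolymer where every position is marked) yields a warning and
`peak_period = nan`.

## Nucleosome occupancy model

The model scores every footprint start `i` with

    E(i) = −λ Σ_j cos(2π j′/P) [d_j ∈ AT-set] − (… GC-set, opposite sign)
           + γ · #(footprint bases inside poly(dA:dT) runs ≥ L_min)

with the helical phase j′ measured from the dyad to the *center* of
dinucleotide j (the half-base offset makes E exactly symmetric under
reverse complement, since both dinucleotide sets are reverse-complement
closed).  Defaults: footprint F = 147 bp (odd, so the dyad is a base),
period P = 10.1 bp, amplitude λ = 0.05 kT per in-phase dinucleotide,
poly(dA:dT) penalty γ = 0.02 kT per tract base under the footprint,
L_min = 5 bp.  These are conventional magnitudes — large enough that a
fully in-phase footprint (~±0.7 kT) or a long tract (~+2 kT for a
15-mer plus flanking coverage) moves occupancy visibly at kT scale — and
all are exposed in `NucleosomeModelParams`.  The model is a
re-implementation in spirit of published sequence-based occupancy
predictors, not a clone of any specific one.

Occupancy is the exact equilibrium of hard rods of length F with start
weights `exp(μ − E(i))`: forward/backward partition-function recursions
give start probabilities `s(i) = Zf(i)·w(i)·Zb(i+F)/Z`, and occupancy is
the F-window running sum of s.  All recursion arithmetic is in the log
domain (10-kb sequences at high μ would overflow otherwise); μ = −∞ is
honoured as the empty-lattice limit.  Circular topology conditions on a
cut bond: the partition function adds configurations with no rod crossing
the cut and one rod crossing at each possible register, and each start
probability conditions on that rod, giving an O(L²) computation used for
plasmid-sized inputs and an O(L) linear path used everywhere else.  On
every lattice with L ≤ 14, F ∈ {2,3,4}, random energies and both
topologies, the recursions agree with exhaustive enumeration of all rod
configurations to < 1e−9.

μ is calibrated to a target mean coverage (default 0.75, a typical bulk
nucleosome density) by bisection, valid because mean occupancy is
non-decreasing in μ; coverage at or above the maximum packing fraction
`F·⌊L/F⌋/L` raises an infeasibility error rather than diverging.  Peak
calls on occupancy tracks are strict local maxima with plateaus reporting
their midpoint; track similarity offers Pearson and Spearman correlation
on mean-centred tracks (constant tracks raise rather than returning NaN)
and a peak-match fraction within ±20 bp.

## Constrained randomization (SynR design)

`window_shuffle` partitions the sequence into non-overlapping windows
(default 5 bp; a trailing window of ≥ 2 bases is shuffled too) and
replaces each window with a uniform random permutation of its own bases,
so the global and per-window base multisets are conserved *exactly* —
`at_delta` is identically zero by construction, not approximately.

`design_synr` starts from a full shuffle and then proposes single-window
re-permutations, accepted by simulated annealing (T₀ = 1, geometric
cooling ×0.995 per iteration, equal unit weights) on the summed
constraint violations:

    max(0, min_occ_r − occ_r) + max(0, dinuc_l1 − tol)
                              + max(0, identity − max_identity)

Defaults: max_identity 0.75, dinucleotide L1 tolerance 0.02, occupancy
Pearson ≥ 0.8, ≤ 5000 iterations.  The occupancy correlation compares
both profiles at a *single* chemical potential, the one calibrated on the
original at the target coverage; calibrating each candidate separately
would let the global normalization absorb sequence differences and makes
each proposal ~40× more expensive, while a shared μ isolates the effect
of the sequence itself.  Identity has a hard floor — positions inside
single-base windows can never change — which is computed up front; an
identity cap below the floor returns `accepted=False` with a diagnostic
rather than burning iterations.  The run is a pure function of the seed.
Tract conservation is reported (Jaccard of mixed-AT tract base sets) but
not constrained by default, since within-window permutation already
preserves most runs of length ≥ window.  Divergence achieved in practice
on the 2-kb fixture is ~49–51% identity, comfortably past the 75% cap;
the identity actually reached is an outcome of the run, not a target.

## ChIP-qPCR quantification

Percent of input: `%IP = 100·f·E^(Ct_input − Ct_IP)` with amplification
efficiency E (default 2.0, perfect doubling; no standard curves are
modelled) and input fraction f supplied per experiment (never defaulted
silently in reports).  Enrichment relative to a reference amplicon is the
ratio of mean %IPs with first-order (delta-method) SEM propagation,
checked against Monte-Carlo resampling in the tests.  Transcript levels
use ΔΔCt normalized over genomic DNA so template copy-number differences
cancel.  Replicate comparisons use the two-sided Welch t-test (the
unequal-variance form is the safer reading of a generic "t-test";
a paired variant is available by flag), significance at α = 0.05, no
multiple-testing correction.  Two zero-variance groups with equal means
return p = 1 by convention.

## Synthetic data

`gen_background` draws i.i.d. bases at a chosen AT fraction (64% genome
average by default).  `gen_central_domain_like` emulates a 2-kb
central-domain fragment at 72% AT with, by default, 12 planted
homopolymer tracts of 5–15 bp (a realistic poly(dA:dT) density for
AT-rich centromeric DNA) and 9 planted dyads on a 200-bp ladder (the
nucleosomal repeat scale), each dyad receiving AA/TT dinucleotides at
every cosine maximum of the 10.1-bp helical phase within its footprint.
Planted tracts get non-A/T flanking bases so each is maximal at exactly
its recorded interval, and tract placement avoids dyad footprints so the
two kinds of truth never overwrite each other.  Because planted features
skew composition AT-ward, background positions are flipped (uniformly
across the sequence, protecting only the planted features) until the
realized AT count equals the target exactly.  Ct tables are generated by
inverting the percent-input formula and adding Gaussian noise on the
cycle scale — multiplicative log-scale noise, the usual qPCR error
structure — so a noise-free table round-trips exactly.

What the fixtures do not emulate: real central-domain sequence is not
i.i.d. around its features (it carries promoters, TSSs and transcription-
factor sites the generator knows nothing about); planted periodicity is
written as literal dinucleotide substitutions rather than a statistical
bias, so truth is exact but the signal shape is idealized; and occupancy
"tracks" are the model's own output plus Gaussian noise, not ChIP-seq
fragment pileups.  Passing recovery tests therefore demonstrates that the
estimators detect the features they were built for at realistic density
and noise — not that the model reproduces in-vivo nucleosome maps.

## Numerical and reproducibility notes

Problem sizes in the test suite and acceptance script — 2-kb sequences, a
20-seed recovery panel, 1000 conservation runs, 50-table statistical
oracles — were chosen to exercise every code path at the scale the
analysis targets while keeping a full run in seconds.  The recovery panel
is the fixed seed set 0–19 so the reported recovery numbers are a stable
benchmark; at fixture signal-to-noise the period estimator's per-seed
failure probability is below 1%.  All randomness flows through explicit
`numpy` Generators; identical seeds give identical results, including the
designer's full trajectory.  The lattice kernels are JIT-compiled with
numba when available and run as identical pure-Python code otherwise.

## Known limitations

* The occupancy model is thermodynamic only: no remodelers, no
  CENP-A-specific nucleosome geometry, no training of λ/γ against
  measured nucleosome maps.
* In-silico PCR is exact-match after tail trimming; degenerate bases and
  mismatch tolerance are out of scope, and N never matches.
* Circular occupancy is O(L²); fine for plasmids, not for chromosomes.
* The periodicity score is a detection/point-estimation statistic; it has
  no calibrated null distribution and should not be read as a significance
  test.
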