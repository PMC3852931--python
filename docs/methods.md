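# Methods

## Scoring model

The engine scores a query gene signature (m genes, flags s(g) ∈ {+1, −1})
against reference profiles that assign every gene of an N-gene universe a
signed rank R(g) whose magnitudes form the permutation 1..N. The
per-profile connection strength is

    c = raw / maxsum,   raw = Σ_g R(g)·s(g),   maxsum = mN − m(m−1)/2,

and a refset of K profiles scores the mean of its members. Because every
member shares the same maxsum, the mean is computed as
(Σ_k raw_k) / (K · maxsum): all summation is exact int64 arithmetic and a
single double-precision division happens at the end. This removes
accumulation-order effects entirely — the batched array kernel and a
per-profile scalar loop agree bit for bit, which the test suite asserts
rather than assumes. The batched kernel additionally exploits linearity
(Σ_k Σ_g R_k s = Σ_g s · Σ_k R_k), collapsing each refset to one summed
rank vector before the gather.

Assumptions: the score treats ranks linearly (no Kolmogorov–Smirnov-style
enrichment statistic, no gene weights), and refset aggregation is the plain
mean so a singleton refset reduces to the single-profile score and the set
score stays in [−1, 1]. Whether a √K-style normalisation would be
preferable is deliberately isolated in `refset_score` / the K·maxsum
divisor, so the alternative is a one-line change.

## Null distribution and p-values

A random signature of length m is built from m uniforms u ∈ [0,1): with
v = u·N, floor(v) indexes the gene (universe order) and the fractional
part sets the flag (+1 below 0.5). One uniform therefore carries both gene
identity and direction — the draw budget is exactly m·n_rdsigs live
uniforms per query, there is no rejection step, and the rule is branchless.
Sampling is with replacement; a duplicated gene simply contributes twice.
For the target regimes (m ≤ a few hundred, N in the tens of thousands) the
duplicate probability is ≈ m²/2N and negligible; at desk-test scales
(m = 10, N = 500) it is a few percent and harmless to calibration, which
the uniformity test confirms empirically.

The two-sided empirical p-value uses the add-one convention,
p = (#{|c'| ≥ |c|} + 1)/(n_rdsigs + 1), so p is never 0 and lives on the
lattice k/(n_rdsigs+1). Two-sidedness treats mimicking and reversing
connections symmetrically; both choices are isolated in
`empirical_pvalue`. One pool of random signatures per query is shared
across all refsets (they all see the same m), which matches the
m·n_rdsigs budget; it correlates p-values *within* a query but leaves each
marginal p-value valid, so calibration statistics in the tests use one
p-value per query (for uniformity) or across-query empirical standard
errors (for the expected-false-positives check).

## Determinism and the batch contract

Randomness comes from numpy's counter-based Philox generator keyed by the
run seed. Philox skips ahead in whole 4×64-bit counter blocks, so each
random signature's draws are aligned to a block boundary: signature i
occupies uniforms [i·stride, i·stride + m) with stride = ceil(m/4)·4, and
the padding is discarded. Any chunking of the signature index range
re-reads exactly the same stream positions, making null scores invariant
to `chunk_size` and to evaluation order — the hardware-agnostic form of a
GPU-style batch kernel, enforced by byte-identical results files in the
tests. Multi-query runs draw one uint32 sub-seed per query from
`SeedSequence(seed)`, with queries processed in lexicographic filename
order.

Numerical details: u·N can round up to N for u just below 1, so gene
indices are clamped to N−1; the flag threshold compares the exact double
v − floor(v) against 0.5; rank sums fit int64 with enormous margin
(|raw| ≤ mN ≤ ~4·10⁶ per profile at full scale).

## Significance control

With M refsets tested per query and a tolerated expected number of false
positives T (default 1), each refset is called at p ≤ T/M — the
Bonferroni-type inversion of E[FP] = M·α. On the discrete p-value lattice
the attained per-test level is floor(α(n_rdsigs+1))/(n_rdsigs+1), slightly
conservative; at the defaults the expected calls per null query are ≈0.999
rather than 1. Results are ranked by ascending p-value, ties broken by
descending |score| then set id.

## Synthetic data

The generator emulates the *structure* of a connectivity-mapping reference
database, not microarray biology: null profiles have uniformly random rank
magnitudes and i.i.d. ±1 signs (the simplest null consistent with signed
ranks, making the score's null symmetry exact); filenames encode
drug_cell_dose_replicate so both grouping modes are exercised; universes
use probeset-style identifiers. Planted refsets place a rounded fraction θ
of a signature's genes into the top rank slots with matching signs — the
plant operates on rank placement because ranks are all the engine sees —
giving θ = 1 a score of exactly +1 and θ = 0 the null model. A separate
constructor pins a profile's score against a given signature to a chosen
value exactly (distinct magnitudes summing to round(score·maxsum)), used to
park an observed score at the ~1% null quantile for convergence checks.
What passing tests show is therefore engine correctness and statistical
calibration under this idealised null; they say nothing about batch
effects, correlated genes, or realistic expression distributions, which
are out of scope.

## Default parameters

- `n_rdsigs = 10000` random signatures per p-value (floor 100, warning
  below 1000): p-value resolution 1/(n_rdsigs+1); raise to 10⁵–10⁶ for
  tail precision.
- `efp_tolerance T = 1` expected false positive per query.
- `refset_mode = by_drug_cell_dose` (the finer grouping; `by_drug` pools
  cell lines and doses).
- `chunk_size = 4096` signatures per kernel invocation — throughput only,
  never results.
- Test problem sizes: desk-scale trees use N = 1000 genes, 50 profiles and
  query lengths 10/25/189; calibration uses 200 null queries × 20 refsets
  at n_rdsigs = 1000; the full-scale smoke test runs N = 22283 genes, 100
  singleton refsets, m = 10, n_rdsigs = 10⁵.

## Known limitations

- The on-disk filename convention (drug_cell_dose_replicate, parsed right
  to left) is this package's own; a `metadata.tsv` sidecar overrides it so
  arbitrary real databases can be adapted without code changes.
- No FDR (Benjamini–Hochberg) mode, no closed-form or importance-sampled
  tail approximations, and no alternative similarity metrics.
- Signature genes absent from the universe are dropped with a warning (m
  is the post-filter count); an entirely foreign signature is an error.
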