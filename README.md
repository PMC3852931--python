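# connmap

Gene-expression connectivity mapping: match a query gene signature against a
database of drug-induced expression profiles to find compounds that mimic —
or reverse — a biological state of interest, with Monte-Carlo statistical
significance and expected-false-positives control. The intended users are
computational biologists doing candidate-therapeutics discovery and drug
repurposing from differential-expression signatures.

## The model

A **reference profile** represents one drug-treated instance (a drug /
cell-line / dose combination) as signed ranks over an N-gene universe: for
gene *g*, the sign of *R(g)* is the direction of differential regulation and
the magnitude its strength, with |*R*| = *N* the most extreme gene. The
magnitudes of a valid profile are exactly the permutation 1..N. A **query
signature** is a list of *m* genes with flags *s(g)* ∈ {+1, −1} (up/down).
Profiles are grouped into **refsets** — by drug, or by distinct
drug–cell–dose combination — and scored as a unit.

The **connection strength** of a signature against one profile is

    c = Σ_g R(g) · s(g)  /  maxsum(m, N),      maxsum = mN − m(m−1)/2

where the sum runs over the signature genes and maxsum is the largest raw
sum any *m* distinct genes can reach. Hence *c* ∈ [−1, 1], with +1 exactly
when the signature genes are the *m* most extreme genes with every flag
matching the rank sign (perfect mimicry) and −1 for the perfect reversal.
A refset's score is the arithmetic mean over its K members.

Significance is empirical: for each query, `n_rdsigs` random signatures of
the same length *m* are generated (each from *m* uniform draws — the integer
part of *u·N* picks the gene, the fractional part the flag), scored against
every refset, and the two-sided p-value is

    p = (#{ random |c'| ≥ |c observed| } + 1) / (n_rdsigs + 1).

With M refsets tested and a tolerated expected number of false positives T
(default 1), a refset is called significant when p ≤ T/M. The null kernel
is seed-deterministic and batch-parallelizable: scores are a pure function
of (inputs, `n_rdsigs`, seed), never of chunk size or evaluation order.

## Worked example

Build a small synthetic database (20 profiles over 1000 genes, with one
drug–cell–dose refset planted to perfectly match a 10-gene query) and run
the mapper:

```python
from connmap import standard_manifest, write_fixture_tree
from connmap.cli import main

manifest = standard_manifest(
    N=1000, n_profiles=20, query_lengths=(10,), n_drugs=5,
    planted=(("sig010", "drug00_MCF7_1e-6", 1.0),),
)
write_fixture_tree("demo/tree", manifest, seed=7)
main(["--non-interactive", "--seed", "11", "--n-rdsigs", "10000",
      "--ref-dir", "demo/tree/ref-files", "--query-dir", "demo/tree/queries",
      "--out-dir", "demo/out"])
```

`demo/out/sig010.results.tsv` then begins:

```
query_id  set_id            set_size  connection_score  p_value    threshold  significant
sig010    drug00_MCF7_1e-6  2         1.000000          9.999e-05  1.000e-01  yes
sig010    drug01_MCF7_1e-6  2         -0.396786         2.300e-03  1.000e-01  yes
sig010    drug03_PC3_1e-6   2         0.207333          1.070e-01  1.000e-01  no
```

The planted refset scores exactly +1.000000 and gets the smallest p-value
the add-one estimator allows at 10 000 random signatures, 1/10001. The
threshold 0.1 is T/M = 1/10 for ten refsets at the default tolerance T = 1 —
so about one false positive per query is expected, and here one null refset
(`drug01_MCF7_1e-6`, a *negative*/reversing connection) is indeed also
called. Raise `--efp` sensitivity by lowering T to suppress such calls.

The same run works from a shell via the `connmap` console script; without
`--non-interactive` it prompts for the refset characterisation, the EFP
tolerance and the number of random signatures, with defaults accepted on
empty input.

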