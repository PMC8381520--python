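# kneebench

Noninferiority benchmarking of total knee replacement (TKR) constructs from
joint-registry survival data.

National joint registries monitor how often implanted prostheses need
revision surgery, but their headline summaries (revision rates per 100
component-years) are absolute measures, not head-to-head comparisons.
`kneebench` implements an internal-benchmark noninferiority analysis: at
each post-operative time point it finds the best-performing construct used
in sufficient numbers within the registry itself, then asks of every other
construct whether its revision probability is demonstrably within a
clinically acceptable margin of that benchmark, demonstrably outside it, or
not yet decidable.

## The statistics

A *construct* is a TKR brand subdivided by fixation (cemented/uncemented),
bearing mobility (fixed/mobile) and constraint (CR/PS). For each construct
the cumulative probability of all-cause revision by time *t* ("net
failure") is estimated as

    F(t) = 1 − ∏_{t_i ≤ t} (1 − d_i / n_i)

— one minus the Kaplan–Meier survivor function, with first revision as the
event and death treated as independent censoring — with the classical
Greenwood variance

    Var[F(t)] = S(t)² · Σ_{t_i ≤ t} d_i / (n_i (n_i − d_i)).

At each time point (3, 5, 7 and 10 years by default):

1. **Reference**: the construct with the lowest F(t) among those with at
   least 1000 procedures still at risk. The 1000 threshold is a design
   choice that keeps the reference's own 95% CI width near 3 percentage
   points at ~5% failure.
2. **Comparators**: every other construct with at least 500 still at risk
   (CI width near 5 points).
3. **Test**: for each comparator, Δ = F_comp(t) − F_ref(t), with pooled
   Greenwood standard error √(Var_comp + Var_ref), a 95% CI on Δ, and a
   Wald statistic Δ/SE (reported descriptively).
4. **Classification** of the CI on Δ against margins m20 = 0.2·F_ref(t) and
   m100 = 1.0·F_ref(t) (a doubling of failure), first match wins:
   CI lower limit above m100 → *inferior at 100%*; above m20 → *inferior at
   20%*; CI upper limit below m20 → *noninferior at 20%*; below m100 →
   *noninferior at 100%*; otherwise *inconclusive*.

Because real national-registry extracts are not public, the package ships a
synthetic registry generator (construct-specific exponential revision
hazards, death as independent censoring, staggered enrolment, and
administrative censoring at a data-lock date) that reproduces the
statistical structure the analysis assumes, with closed-form truth for
validation.

## Worked example

```
kneebench demo --seed 1 --out demo/
```

generates a 46 050-procedure synthetic registry (25 constructs: one
reference-grade construct with ~1.2% true failure at 3 years plus 24
comparators spanning parity to over treble that hazard) and benchmarks it at
3, 5, 7 and 10 years. With seed 1 it prints:

```
wrote 46050 records to demo/registry.csv
t=3y stratum=all: reference Cascade/mobile/cemented/CR (1.06%), 24 comparators -> demo/benchmark_all_3y.csv
t=5y stratum=all: reference Dunewood/fixed/uncemented/CR (1.79%), 24 comparators -> demo/benchmark_all_5y.csv
t=7y stratum=all: reference Concord/fixed/cemented/CR (2.76%), 23 comparators -> demo/benchmark_all_7y.csv
t=10y stratum=all: reference Concord/fixed/cemented/CR (4.04%), 18 comparators -> demo/benchmark_all_10y.csv
```

Note the benchmark is *dynamic*: at 3 years a mobile-bearing construct
happened to have the lowest estimated failure among qualifying constructs,
while at 7 and 10 years the long-run best construct takes over. At 3 years
the 24 comparators split into 9 noninferior at the 100% margin, 7
inconclusive, 6 inferior at the 20% margin and 2 inferior at the 100%
margin; the last rows of `benchmark_all_3y.csv` show, e.g.

```
construct                     n_at_risk  failure  diff    ci_low  ci_high  category
Wrenfield/mobile/cemented/CR  813        0.0358   0.0252  0.0127  0.0377   inferior_100
```

— the CI on the failure difference lies wholly above m100 = F_ref = 0.0106,
so this construct has demonstrably more than double the reference's failure
probability. Each report also gets a caterpillar figure (`*.png`):
comparators ranked by failure difference in percentage points, CI whiskers
coloured by band, dashed/dotted vertical lines at the two margins.

Other subcommands: `simulate` (YAML scenario → registry CSV), `benchmark`
(registry CSV → report CSVs, with `--stratify-by gender`), `plot` (report
CSV → figure). The same functionality is available as a library
(`kneebench.run_benchmark`, `kneebench.km_net_failure`, ...).

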