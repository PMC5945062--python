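# Methods

## The model

Degrees are positive integers. The scale-free hypothesis is the discrete
(zeta-normalized) power law on {k_min, …, k_max}:

    P(k) = k^(−α) / C,   C = ζ(α, k_min) − ζ(α, k_max + 1)

with ζ the Hurwitz zeta function (evaluated by `scipy.special.zeta`); with
k_max unbounded the second term vanishes and α > 1 is required for
normalizability. `PowerLawModel` refuses α ≤ 1 on unbounded support.
Sampling is exact inverse-CDF: a tabulated CDF for finite k_max, bisection
on the zeta survival function otherwise — the sampler and the estimator
share one family, so recovery tests are meaningful.

Networks are directed TF→target graphs. A node is a TF iff it has at
least one out-going edge; a TF that is also a target is a single node;
self-loops (auto-regulation) are allowed; duplicate protein–DNA
interactions (PDIs) collapse to one edge with merged evidence
annotations. Out-degree = targets per TF (the direction all exponent
claims are about); in-degree fitting is possible but nothing is asserted
about it, because gene-centered assays undersample it.

## Estimation of α and k_min

Two estimators on the tail k ≥ k_min:

* the closed form α̂ = 1 + n [Σ ln(kᵢ/(k_min − ½))]⁻¹ (`method="hill"`),
  and
* the exact MLE maximizing −α Σ ln kᵢ − n ln C(α) by bounded scalar
  minimization on α ∈ (1, 25], xatol 1e−8 (`method="exact"`).

They agree to < 0.01 for k_min ≳ 6. The default is the exact MLE: the
closed form is biased low at k_min = 1 (≈ 1.79 for true α = 2), and the
bias corrupts k_min selection — with the closed form, the KS scan almost
never chooses the true k_min = 1 on pure power-law samples; with the
exact MLE it does in ≈ 98% of them. The exact MLE at fixed k_min matches
python-igraph's plfit to ≤ 1e−5, which the test suite uses as an
independent cross-check (never as the implementation).

k_min is selected by scanning every unique observed degree whose tail
keeps ≥ `tail_floor` observations (default 10) and ≥ 2 distinct values,
fitting α at each, and keeping the KS-minimizing candidate (ties to the
smaller k_min). The KS distance is computed exactly without enumerating
the support: the empirical CDF is a step function, so the supremum over
all integers is attained at an observed value or immediately before the
next one, and both are checked. On contaminated data (uniform noise
spliced below a power-law regime) the selected k_min never lands inside
the contamination but may overshoot the splice point by a few tens of
percent — the exponent is still recovered.

## Goodness of fit and model selection

The bootstrap p-value is semiparametric: each replicate resamples
below-k_min degrees empirically (with the observed below-tail
probability) and draws the rest from the fitted model, then is refitted
and its KS distance recorded; p = fraction of replicate distances ≥ the
observed one. n_boot < 100 is refused. Two refit modes:

* `reselect` (default): the replicate's k_min is re-selected, matching
  how the observed fit was obtained. Under the null, p is approximately
  uniform (mean ≈ 0.46 over seeded runs). Its power against
  exponential-tailed data is limited, because the free k_min escapes into
  a short upper tail that cannot be rejected — a property of the
  selection procedure worth knowing, not a defect of the bootstrap.
* `fixed`: k_min held at the observed fit's value, only α re-estimated.
  Use it to test a *specified* k_min; at k_min = 1 it rejects geometric
  data decisively (p ≈ 0 at n = 5,000).

Alternatives are discrete distributions left-truncated at the same k_min
so log-likelihoods are comparable: Poisson (rate by 1-D likelihood
optimization of the truncated pmf) and exponential (geometric on
{k_min, …}, closed-form rate log(1 + 1/mean(k − k_min)); the all-equal
boundary is the degenerate point mass with log-likelihood 0). Vuong's
statistic is the mean per-observation log-likelihood difference over its
standard error times √n, referred to a standard normal; positive and
p < 0.05 favors the power law, the zero-variance case is defined as
statistic 0 / undecided. No Schwarz correction is applied by default —
both families here have one free parameter, so the term cancels anyway;
a flag exists for unequal-dimension comparisons. On very heavy-tailed
samples (α ≲ 3) a single extreme degree can dominate both the mean and
the SD of the differences, pulling the statistic toward ~1 and the
verdict to "undecided"; decision-frequency guarantees are therefore
stated at α = 3.5.

Two-sample comparisons between degree sequences use the asymptotic
two-sample KS test; ties (inevitable on integers) make the p-value
conservative and are flagged.

## Lorenz curves

TFs are ranked by increasing out-degree; the curve is the cumulative
share of degree mass vs the cumulative share of TFs, (0,0) prepended, no
binning (observed GRNs have at most a few hundred TFs). Top-share at
fraction f is 1 − (curve linearly interpolated at 1 − f); Gini = 1 − 2 ×
trapezoidal area. Simulated curves draw from the discrete power law with
k_min = 1 and k_max = n (a TF cannot bind more genes than exist) and
average the cumulative shares pointwise over replicates, which share one
rank grid. Gini decreases strictly in α over {2.0, …, 4.5}: lower
exponents mean hub-dominated ("capitalistic") binding.

## Monte-Carlo inference for complete GRNs

A population of 10,000 degrees is generated at the (known or fitted)
exponent with k_min = 1 and k_max = population size; samples of the
genome's TF count are drawn with replacement, r = 1,000 times, and
refitted. The per-replicate refit policy matters and both are
implemented:

* `reselect` — k_min re-selected per sample. Occasional thin-tail,
  high-k_min refits inflate the SD of α̂ several-fold beyond the
  asymptotic (α−1)/√n, increasingly so for steep exponents; at α = 4.12,
  n = 934 the inflation is so strong that prediction intervals for
  α = 3.04 and α = 4.12 overlap.
* `fixed` — k_min frozen at the population's k_min, exact MLE. The SD
  tracks the asymptotic rate (with mild inflation from the finite
  population and truncation), the sampling distribution is approximately
  normal for large samples and visibly right-skewed with inflated
  variance below n ≈ 30, and the intervals for exponents 4.12 / 3.04 /
  2.00 at genome TF counts 934 / 1052 / 301 are disjoint —
  {≈3.84–4.40}, {≈2.90–3.18}, {≈1.88–2.12}.

The prediction-interval pipeline uses `fixed`: interval non-overlap
across organisms is the property the analysis rests on, and only this
policy delivers it. Intervals are center ± 1.96·SD by default
(`normal_sd`); a `percentile` method (central 95% mass of deviations) is
reported alongside for non-normal regimes.

The interaction-count estimator simulates, per replicate, N out-degrees
(N = TFs in the genome): below-k_min degrees resampled empirically with
the observed below-tail probability, tail degrees drawn from the fitted
model capped at the genome gene count; I is the replicate sum, reported
as mean ± SD over r replicates, with a two-sided Z-test against an
observed count. The generation scheme mirrors the observed degree
structure, which is what makes the N = n self-test (simulated total ≈
observed total) pass; it requires a plausible fit (GOF p > 0.1) unless
forced. Pathological all-equal samples are excluded and counted, never
silently retried.

## Edge-sampled subnetworks

Subnetworks take exactly round(p·|E|) edges uniformly without replacement
(hypergeometric, half-up rounding; a Bernoulli(p) variant exists behind a
flag); nodes are the endpoints of chosen edges, so no singletons arise —
the key contrast with node sampling. A node's inclusion probability
follows 1 − (1−p)^k ≈ p·k/k_T for small p, and inclusion frequency over
replicates correlates > 0.99 with degree. Exponent-vs-size sweeps refit
each replicate with the full selection stack; the SD of subnetwork
exponents decreases monotonically in p. The knee finder fits two
least-squares lines at every interior bisection (the bisection point
belongs to both segments) and returns the bisection with minimal total
SSE, ties toward smaller x; exactly collinear input is flagged as having
no knee. By default the knee is taken on the SD-of-exponents vs
proportion curve.

## In-silico GRNs

The generator is the static (fitness-based) power-law model: with
tf_fraction = 0.05 (the typical share of TF-coding genes), TF number i
carries weight i^(−1/(α−1)); each edge draws its TF proportionally to the
weights and its target uniformly among all nodes; duplicates are removed
and the deficit redrawn until the edge count is exact, so Σ out-degrees
= n_edges always. This construction — not "draw each TF's degree from
the power-law pmf, then wire" — is what reaches realistic interaction
densities: 60,000 edges from ~265 TFs needs a mean out-degree of ~226,
far beyond the mean of the pmf itself. Saturation of the top TF's target
repertoire during deduplication slightly flattens the extreme head; the
fitted exponents over 1,000 replicates at the yeast-complete scale
(60,000 edges, 5,301 nodes) span ≈ [1.99, 2.15] around the target 2.0.
Generation stalls only near the feasibility bound n_edges ≈ n_tfs·n_nodes
and is then reported, not looped forever.

## What the synthetic data does and does not emulate

Synthetic GRNs reproduce the degree structure of TF-centered assays
(exact edge counts, a small TF set, heavy-tailed out-degrees, shared
targets) but not identifier namespaces, tissue structure, false-positive
peaks, or the gene-centered (in-degree) sampling bias of Y1H data.
Passing tests therefore demonstrate the statistical machinery under the
stated generative model, not the correctness of any biological claim
about a particular organism.

## Numerical choices and problem sizes

Explicit seeds are required on every stochastic operation; populations,
samples, bootstraps and sweeps derive child seeds from
`numpy.random.SeedSequence`. Default problem sizes follow the study
conditions (populations of 10,000; r = 1,000 resamples; 1,000 in-silico
GRNs; 1,000 subnetworks per proportion); the test suite runs reduced
replicate counts (30–300) for the frequency-style checks, chosen for
statistical stability of the asserted bounds. Degenerate inputs are
handled explicitly rather than by retry: all-equal degree sequences fall
back to k_min = min(degrees) with a warning, zero-SD sampling
distributions yield degenerate intervals, and the Z-test with zero SD is
reported as undefined.

## Known limitations

* The per-sample k_min re-selection policy's variance inflation is
  heavy-tailed; its prediction intervals are honest about analyst-style
  refitting but not organism-separating. The `fixed` policy is the
  default for interval construction (see above).
* The GOF bootstrap with free k_min has limited power against
  exponential tails (documented above); test a specified k_min when the
  question is "is the whole distribution power law".
* Peak→gene assignment is summit-to-TSS, strand-ignored, inclusive 2 kb
  window; peaks without an explicit summit column use the interval
  midpoint. BED peaks are 0-based half-open, TSS tables 1-based;
  conversion happens at read time.
* Clustering coefficients and continuous-network-model comparisons are
  out of scope.
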