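# Methods

## Model

The package measures the heterogeneity of a mortality profile
$p = (p_1,\dots,p_k)$, $p_c \ge 0$, $\sum_c p_c = 1$, over $k$ mutually
exclusive causes of death with the quadratic form

$$ I \;=\; \sum_{i=1}^{k}\sum_{j=1}^{k} d_{ij}\,p_i p_j , $$

the expected dissimilarity between the causes of two deaths drawn
independently from the profile. The double sum runs over *ordered* pairs —
both $(i,j)$ and $(j,i)$ — so the per-cause decomposition
$I = \sum_c p_c I_c$ with $I_c = \sum_i d_{ci} p_i$ is exact without a
factor of two. This is a Rao-type quadratic entropy; structurally it is the
categorical analogue of the Gini coefficient, with the income gap
$|x_i - x_j|$ replaced by a cause dissimilarity.

The dissimilarity is derived from an $L$-level hierarchical cause
classification in which all analysis causes sit at depth $L$:
$d_{ij} = (L - \ell)/L$, where $\ell$ is the deepest level at which $i$ and
$j$ belong to the same group. The implementation generalises the 3-level
case to arbitrary $L$ — the formula is the natural normalisation of the
shortest-path length between same-depth leaves, and it makes $d$ an
ultrametric ($d_{ij} \le \max(d_{ih}, d_{hj})$), which the test suite
verifies on random trees. With constant off-diagonal $d_{ij} = 1$ the index
reduces to Gini–Simpson diversity $S = 1 - \sum_c p_c^2$; hence
$0 \le I \le S \le 1$ for any tree-derived matrix.

Assumptions worth stating explicitly:

- Causes are mutually exclusive and exhaustive within the profile; the
  index is blind to *how* the shares were produced (observed all-age death
  shares and life-table death distributions are both accepted).
- The dissimilarity depends only on the classification tree. Two causes
  with similar aetiology placed in distant branches are treated as distant;
  comparisons across space/time are only meaningful under one fixed
  classification.
- A cause with $p_c = 0$ contributes exactly 0 to $I$, $S$, $I_c$-weights
  of others, and every aggregate (a tested invariance), so dropping or
  retaining zero-death categories is purely an I/O convenience. Readers
  expose this as the `zero-fill` / `renormalize` policies; the default
  (`error`) forces the caller to choose.

## Estimator shape

The core arithmetic lives in two scikit-learn transformers
(`CodInequality`, `SimpsonDiversity`): rows of an `(n, k)` share matrix map
to an `(n, 1)` column of index values, with `contributions` /
`mean_distances` exposing the decomposition terms. This makes the indices
composable with sklearn pipelines (e.g. a `FeatureUnion` producing S and I
side by side). The domain layer (`CauseProfile`, `cod_inequality`,
`simpson_diversity`, `decompose`, `aggregate_contributions`) wraps these
with cause-id alignment and metadata.

## Uncertainty propagation

Inputs in the GBD results dialect carry a per-cause 95% interval
`(lower, val, upper)`. The engine samples each cause independently from a
family calibrated so that its central `ci_level` mass spans the interval,
clamps at zero, renormalises each draw onto the simplex, evaluates the
index on every draw, and reports the central `ci_level` percentiles.

- **truncated-normal** (default): Normal(`val`, $\sigma$) truncated at 0
  with $\sigma = (\text{upper}-\text{lower}) / (2 z_{(1+\gamma)/2})$. Chosen
  as default because GBD intervals for the large causes that dominate the
  index are nearly symmetric, and the zero-truncation handles small causes
  gracefully.
- **scaled-beta**: Beta on $[0,1]$ moment-matched to the same mean and
  $\sigma$ (with $\sigma$ capped just below the Bernoulli limit
  $\sqrt{m(1-m)}$, where the moment match degenerates).
- **dirichlet-calibrated**: one Dirichlet over all causes with total
  concentration set to the median per-cause moment match — the only family
  with built-in (negative) cross-cause dependence.

Numerical details: degenerate intervals (`lower = val = upper`) reproduce
the point value exactly; an all-zero draw (possible only in pathological
configurations) falls back to the point profile rather than dividing by
zero; all sampling flows from one `numpy` `Generator` seeded by
`McConfig.seed`, so runs are bit-reproducible. The plug-in point estimate is
*not* guaranteed to lie inside the percentile interval: a profile at an
index extremum (e.g. exactly uniform shares under $S$) has every
renormalised draw on one side of the point. Only `lower <= upper` is
asserted.

Significance of a change between two years is flagged when the central
`ci_level` interval of the paired draw differences $b_i - a_i$ (independent
draw streams, paired by index) excludes zero. The more conservative
criterion — disjoint marginal intervals — is reported alongside, since
interval-overlap reasoning is common in applied work.

A matched-generative-model check (observed shares really are
truncated-normal perturbations of a known truth; 200 replicates at 1000
draws) is run by both the test suite and `scripts/acceptance.py`; empirical
coverage of the nominal 95% interval must be at least 90%, a deliberately
loose bound acknowledging the distortion introduced by renormalisation and
the normalisation of the observed vector.

## Panels and association

`compute_panel` evaluates S and I per (location, sex, year), deriving one
independent sub-seed per row from `McConfig.seed` via `SeedSequence` spawning
so that panel runs are reproducible yet rows are independent.
Kendall's $\tau_b$ (tie-corrected, via `scipy.stats.kendalltau`) quantifies
the ordinal I–S association; tau-b is used because index values reported at
3 decimals can tie. Both cross-sectional (across locations within a year —
the default) and longitudinal variants are exposed. Constant input vectors
make $\tau$ undefined; the function warns and returns NaN rather than
raising, so panel pipelines survive degenerate series.

## Synthetic data

The generator produces the *statistical skeleton* of a GBD share panel:
uniform-branching classification trees; symmetric-Dirichlet share vectors
(concentration 1 by default — flat on the simplex; no claim of demographic
realism); relative interval bounds $p_c(1 \pm h)$ with half-width $h = 0.1$
by default, matching the order of magnitude of GBD cause-share intervals in
high-income countries; multiplicative per-cause annual drift, renormalised
(the discrete analogue of differing cause-specific decline rates); and
one-off multiplicative shocks (an epidemic or disaster year).

It deliberately does **not** emulate: age structure, cross-cause
correlation of estimation errors, serial correlation of GBD draws over
years, or calibration to any real country's magnitudes. Passing tests on
synthetic panels therefore validate the *arithmetic and its invariances*,
not the epidemiological realism of any scenario.

Two packaged scenarios reproduce qualitative phenomena of real panels by
construction (both are assertion-checked in the test suite and recomputed by
the acceptance script):

- **Divergence** (`divergence_scenario`): a dominant cause in one level-2
  group decays (factor 0.85/year over 30 years) while four causes in a
  sibling level-2 group absorb the mass. Deaths spread over more causes
  (S rises) that are closer together in the tree (I falls) — the pattern
  where diversity and inequality run in opposite directions.
- **Shock** (`shock_scenario`): mass sits overwhelmingly in one level-1
  branch; a cause in another level-1 branch (distance 1 from the bulk) is
  multiplied sixfold in a single year. The relative spike is larger in I
  than in S because the shock cause is *more dissimilar than average* to the
  rest of the profile.

## Numerical choices

- Shares summing to 1 within `1e-6` are renormalised silently (results-tool
  percent extracts carry rounding); larger deviations raise, with
  `profile_from_counts` as the explicit normalisation path. Percent tables
  are accepted when group sums are within 0.01 of 100.
- Decomposition conservation ($\sum_c C_c = I$) is enforced to `1e-9`;
  oracle agreement of the quadratic form is tested to `1e-12`.
- Decomposition rows are ordered by descending contribution with a stable
  tie-break on cause id; percent contributions are computed in full
  precision and rounded only at presentation.
- A zero-valued index makes percent contributions undefined; they are
  reported as 0 with `attrs["contribution_pct_defined"] = False` rather
  than raising or emitting NaN.
- Cause matching is by opaque id everywhere; display names (which contain
  apostrophes and commas) are never keys. A cause appearing under two
  parents is rejected as a duplicate id, never silently resolved.
- Tree generation refuses more than $10^5$ leaves.

## Design decisions

- **Arbitrary depth $L$** rather than hard-coding the 3-level case; $L$ is
  inferred from the hierarchy file.
- **Independence across causes** in uncertainty propagation (except the
  Dirichlet family): cross-cause correlations of the underlying estimates
  are not published in results-tool extracts. Intervals for I and S are
  therefore approximate and likely slightly conservative for S (whose
  sampling error is dominated by large causes that would be negatively
  correlated after renormalisation).
- **Difference-interval significance** rather than marginal-interval
  overlap as the primary criterion: overlap tests are conservative; both
  are reported.
- **Zero-death categories retained by default**: provably inert (see
  above), so exclusion is offered only as an input-handling policy.

## Limitations

- Tree-path distance is one of many possible cause dissimilarities;
  aetiological or genetic distance functions are out of scope (the
  `DissimilarityMatrix` container accepts any symmetric matrix in $[0,1]$
  as an extension point).
- Findings are contingent on the classification tree used; alternative
  groupings can reorder populations by I.
- The uncertainty recipe approximates, not replicates, the GBD posterior:
  validating published country values additionally requires the exact
  extraction query (age standardisation, metric) behind them, so external
  validation is left to users with a results-tool download.
- The packaged 133-cause hierarchy is a representative GBD-style fixture,
  not an official extract; ids are package-internal.
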