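# Methods

## Model

`pathcontext` ranks a fixed universe of n pathways by a convex combination
of two channels measured on a common [min CS, max CS] scale:

    Score(π_i, k) = w_θ · CS(π_i, k) + (1 − w_θ) · IS(π_i)

**Context channel.** A literature search for keyword k yields a
nonnegative, unbounded entity score s_i per pathway; a pathway absent from
the table has s_i = 0 (literature indexes do not cover all pathways — the
formulas are defined at zero, so missing-as-zero is the contract
everywhere). Scores become likelihoods through

    P(k | π_i) = log_b(s_i + 1),   b = s_max + 2,

with s_max taken over the analysis universe only — the package never sees
an external entity catalogue, so the universe is the natural scope. The
base choice puts the top score just below 1 while the concavity of the
logarithm spreads out densely packed small scores. The prior P(π_i) uses
the same transform on total-evidence values t_i (prepared upstream, e.g.
by summing top-ranked entity scores across search categories), and Bayes'
rule normalizes the products into a posterior Context Score. Implementation
detail: `log1p` is used so that tiny-but-nonzero scores keep strictly
positive likelihood in floating point. With multiple keywords, per-keyword
posteriors are averaged (averaging operates on posteriors, not raw
scores). If every product P(π_i)P(k|π_i) is zero, the posterior is defined
as the all-zero vector rather than an error: with no literature signal the
Discovery rate is 0 and the ranking degrades gracefully to the expression
channel.

**Impact channel.** IS*(π_i) = −log₁₀ max(p_i, floor) with a default
floor of 1e−15 (configurable): upstream tools do emit p = 0 and the
transform must stay finite. IS* is min-max rescaled onto the range of the
final (keyword-averaged) CS vector, so the two channels have equal
influence in the combination and the rescaling is order-preserving in the
p-values. Degenerate ranges need conventions the formula does not supply:

- all IS* equal → every pathway gets the midpoint of the CS range, a
  neutral value that neither dominates nor vanishes in the combination;
- all CS equal (e.g. all zero) → IS* is rescaled to [0, 1] instead, so a
  run without literature evidence still ranks by p-value.

**Discovery rate.** w_θ = |{i : p_i > θ and CS_i > 0}| / n, θ = 0.05 by
default (the conventional significance cutoff). Inequalities are strict as
written: CS is exactly zero whenever s_i = 0, so no epsilon is needed. The
weight is the fraction of pathways "missed by expression, found in
literature", which is precisely when the context channel carries
information the p-values lack.

**Ranking and significance.** Pathways are sorted by combined score,
ties broken by pathway id ascending so identical inputs always produce
identical output. Significance is assessed against the permutation null of
all n² ordered recombinations {w·CS_a + (1−w)·IS_b}; p_i is the fraction
of null values ≥ Score_i. The observed pairs are included, which makes the
p-values conservative, well-defined multiples of 1/n² with minimum 1/n².
Enumeration is exact up to 3000 pathways (9·10⁶ null values — the default
for any realistic pathway universe); above that a seeded subsample of one
million pairs plus the observed pairs is used.

## Evaluation

Given a known relevant set π* (and complement π−), three views:

- **PSEA** — walking the ranked list, the running sum RS rises by
  r_i / Σr at relevant pathways (r_i = n − i + 1) and falls by 1/|π−|
  otherwise. Σr is the sum of r_i over the ranks π* occupies, so up-moves
  and down-moves each total exactly 1, RS(n) = 0, and ES = max RS ∈ [0, 1]
  with ES = 1 iff all of π* precedes all of π−. A subtlety worth knowing:
  because Σr depends on where π* sits, promoting one relevant pathway by a
  single rank can very slightly lower ES (the larger Σr shrinks an earlier
  peak) — ES is a global front-loading measure, not a per-swap monotone
  one.
- **KS D** — the two-sample Kolmogorov–Smirnov distance between the rank
  positions of π* and π−, computed by a direct ECDF sweep (no asymptotic
  p-value is attached; the statistic itself is the measure). Rank
  positions are used rather than scores; for distinct scores the two give
  identical D.
- **F1** — precision/recall/F1 of a significant set against π*, with the
  conventions precision(∅) = 0 and F1 = 0 when precision + recall = 0.

## Synthetic benchmarks

The generator (`pathcontext.simulate`) plants a relevant subset of
n_relevant pathways in a universe of n_pathways and draws, fully
determined by one seed:

- **p-values**: relevant pathways from Beta(a_sig, 1) — the standard
  one-parameter alternative whose a_sig = 1 case is the Uniform(0, 1)
  null — except a `miss_rate` fraction drawn from the null anyway (the
  missed-by-expression pathways the Discovery rate exists to find);
  background pathways from Uniform(0, 1).
- **entity scores** (per keyword): nonzero with probability
  `literature_coverage` (relevant) or `spurious_rate` (background), drawn
  lognormal with σ = 1 around a median of 50 (relevant) or 5
  (background) — right-skewed, like citation-weighted literature scores.
- **prior totals**: lognormal around 20, independent of the labels, so
  posterior behaviour in tests is driven by the likelihood channel.

Defaults are the benchmark conditions used throughout the test suite:
n = 200 pathways, 15 relevant, a_sig = 0.1, miss_rate = 0.3, coverage 0.8,
spurious rate 0.05, one keyword. The replicate counts (50 seeds) and the
universe size were chosen as the smallest design in which the paired
signal-recovery comparison is stable across seeds. The null-calibration
design sets a_sig = 1, equalizes the score scales at 10 **and** equalizes
coverage (0.4 = 0.4): exchangeability of relevant and background pathways
requires equal coverage probabilities, not just equal scales, otherwise
the context channel still carries label information.

What the generator does **not** emulate: the internal scoring model of a
real literature search engine (publication dates, citation counts, journal
weights), correlation between pathways sharing genes, and p-value
miscalibration of upstream tools. Passing the synthetic benchmarks shows
the integration machinery ranks planted signal correctly under the stated
generative assumptions — not that any particular literature source is
well-calibrated for a given biological context.

## Numerical choices

- p-value floor 1e−15; log1p for the evidence transforms; posterior
  normalization guarded against a zero denominator.
- Rank ties broken by pathway id ascending, everywhere, for determinism.
- PSEA maximum is taken over RS(0..n) including the starting zero (never
  binding, since RS(n) = 0 guarantees a nonnegative maximum).
- Permutation p-values use ≥ (ties counted as extreme).
- Result TSVs render numbers with 8 significant digits; a parse→write
  round trip preserves ranks exactly and scores to well under 1e−6.

## Limitations

- The Context Score inherits every bias of the upstream literature
  search: heavily studied pathways score high in any context, and the
  prior only partially compensates.
- s_max and t_max are computed over the analysis universe, so adding or
  removing pathways rescales all likelihoods and priors; CS values are
  comparable within a run, not across runs.
- The permutation null treats CS and IS as independent across pathways,
  which overstates the null spread when the two channels are correlated;
  the resulting p-values are conservative.
- Multi-keyword averaging weights all keywords equally; there is no
  notion of keyword quality.
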