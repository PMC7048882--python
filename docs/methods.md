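# Methods

## Model and conventions

`tscoremap` implements Samejima's graded response model (GRM) in the pure
logistic metric: boundary curves `P*_k(θ) = 1/(1 + exp(−a(θ − b_k)))` with a
common slope `a` per item and strictly increasing thresholds `b_k`, category
probabilities as adjacent differences, and the reporting metric
`T = 50 + 10·θ`. No 1.7 normal-ogive scaling constant is applied by
default — operational PROMIS-style calibrations are published on the
logistic metric — but every probability routine accepts a
`scaling_constant` argument (default 1.0) for banks calibrated on the
ogive-approximation metric. Categories are coded 1..K with higher index
meaning more of the named trait; items displayed in reverse order carry
that fact in `direction_note` and are never re-ordered internally.

The modal category at a score is the argmax of the category probabilities,
with ties broken toward the **lower** index. The rule is deterministic and
conservative toward less severity; exact ties occur only on a measure-zero
set of scores, so the choice never affects band widths, only which band owns
a single boundary point.

## Map construction

Bands are found by scanning the modal category on a 0.01-T grid over the map
range and refining every change point by bisection on the difference of the
two competing category curves to a bracket narrower than 1e-6 T. Intervals
are half-open `[t_low, t_high)`: a score exactly at a crossing belongs to
the lower-category band, consistent with the tie rule. The default range is
[20, 80] (±3 SD around the reference mean), configurable. Categories that
are never modal in range are omitted from the map rather than drawn as
zero-width bands; their labels are recorded per item in `omitted_labels`.
Because the modal category of a GRM item is non-decreasing in θ, a 0.01-T
scan cannot skip a band wider than the grid step; bands narrower than 0.01 T
would be missed, which at slope 4 would require threshold gaps below ~0.003
θ — far outside anything seen in practice.

JSON map output keeps full floating precision. The tidy CSV carries both
full-precision endpoints (so JSON→CSV→JSON round trips are exact to 1e-6
and better) and display columns rounded to 0.1 T for publication-style
reporting. Figures are rendered with matplotlib; SVG output suppresses the
embedded timestamp so reruns are byte-stable.

## Scoring

Respondents are placed on the T metric by expected-a-posteriori (EAP)
estimation under an N(0, 1) prior discretized on 81 equally spaced nodes
over [−4, 4]; against a 10,001-node grid this is accurate to well under
0.005 θ for 4-item forms. The default pipeline path converts the summed raw
score through a summed-score → T table built with the Lord–Wingersky
recursion, mirroring operational short-form scoring; pattern-level EAP is
available everywhere via `method="pattern"` and is the automatic fallback
(with a warning) for incomplete forms, since missing items simply contribute
likelihood 1. T is reported to one decimal in tables; map placement always
uses the unrounded value, with an `integer_t` compatibility flag that rounds
to the nearest integer first for maps published at integer resolution.

A caveat discovered while testing: summed-score EAP is **not** guaranteed
monotone in the raw score when item slopes are grossly heterogeneous. An
independent dense-integration check confirms that mixing a slope-0.8 item
with slope-4 items produces a genuinely non-monotone table — the classical
monotone-likelihood-ratio results for summed scores cover dichotomous
items, and the polytomous analogue fails under extreme slope mixing.
`summed_score_to_t` computes the honest table and emits a warning
recommending pattern EAP in that case; for banks of comparable,
well-functioning items the table is strictly increasing, and the suite
asserts that.

## Snapshot inversion

`fit_item_from_snapshots` recovers GRM parameters from printed category-
probability vectors at known T-scores (at least two distinct scores; one
five-category snapshot alone is underdetermined). Printed values are rounded,
so cumulative probabilities are clamped to [1e-6, 1−1e-6] before logits are
taken. The fit is deterministic: a cumulative-logit linear regression
(`logit P*_sk = a·θ_s − a·b_k` is linear in `a` and `a·b_k`) supplies the
starting point, and Levenberg–Marquardt least squares on the *category*
probabilities refines it, with positivity of the slope and strict threshold
ordering enforced by a log/log-gap parametrization rather than explicit
bounds. Noiseless round trips recover parameters to 1e-4; the two published
worked-example vectors are reproduced with maximum residual ≈ 2e-4.

## Validation pipeline

Difference scores are observed − predicted (positive = more severe than the
map predicts). Respondents enter each item's table wherever that item is
observed (per-item Ns can differ) and are excluded from the perfect-match
denominator if any item is missing. Spearman correlations are Pearson on
midranks (scipy's tie handling, cross-checked in the suite against a
hand-rolled midrank oracle); a constant predicted or observed vector raises
an explicit error rather than silently returning 0. Percentages are printed
to one decimal; the report is invariant to respondent row order.

## Synthetic data and what it shows

The fixture generator draws slopes uniformly in (2.5, 4.2) and spreads
thresholds evenly over [0.0, 2.6] with ±30% jitter of the spacing — the
territory occupied by operational symptom calibrations, and consistent with
the package's own fit of the worked-example item (a ≈ 3.7, thresholds
0.37–2.69). The default 8-item fixture bank replaces its last item with a
fixed engineered item (a = 0.8, b = [−0.1, 0.1, 1.5, 1.7]) whose second
category is never modal, to exercise band omission;
`make_short_form_bank` builds 4-item forms *without* it, emulating the
well-functioning short forms used in observed-data concordance studies. The
clinical-like respondent preset is n = 1594 with T ~ N(52, 9.5) — a single
θ distribution standing in for a chronic-condition sample's four scale
distributions — and simulation is inverse-CDF sampling from the item curves,
fully reproducible from an explicit seed recorded in the truth sidecar.

The generator draws from the same GRM that scoring and mapping assume, so
passing pipeline tests demonstrate *internal consistency* (simulation →
scoring → prediction → tabulation agrees with the analytic expectation
computed by pattern enumeration, within 3 binomial standard errors), not
robustness to local dependence, multidimensionality, differential item
functioning, or response styles present in real data. Reproducing a specific
published concordance table additionally requires the original respondent
data and the official calibrations, neither of which is bundled; the I/O
layer accepts user-supplied files for that purpose.

`expected_match_rates` enumerates all K^n patterns exactly when the count is
tractable (≤ 20,000 patterns, i.e. any ≤ 5-item five-category form + margin)
and otherwise falls back to seeded Monte Carlo over the same discretized
population distribution, so the two estimates converge to each other by
construction. The population grid for clinical-like checks uses 161 nodes
over mean ± 4 SD.

## Problem sizes

Default test and validation runs use 4-item forms (625-pattern
enumeration), 8-item banks for recovery (2000 simulees), n = 1594 per
clinical-like replicate with three seeds, and 200,000-draw Monte Carlo for
the sampling-vs-enumeration cross-check — sizes at which every quantity the
suite asserts is stable at the stated tolerances while the whole suite runs
in well under a minute.

## Known limitations

- Calibration from raw response matrices is out of scope; parameters come
  from files or snapshot inversion. Non-GRM polytomous models (GPCM,
  nominal) are not supported.
- Cross-domain structure (correlated θ across scales) is not modelled.
- Whether published maps were computed at integer-T or continuous
  resolution is not generally documented; the default here is continuous,
  with `integer_t` provided for comparison.
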