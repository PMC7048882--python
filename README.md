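# tscoremap

Interpretation aids for IRT-scored patient-reported outcome (PRO) measures.

Questionnaire systems such as PROMIS report a respondent's symptom or
function level as a **T-score** (mean 50, SD 10 in a reference population).
A number like "T = 61 on Anxiety" is hard to act on clinically. A **T-score
Map** translates it back into the language of the questionnaire: for every
score on the T continuum it shows, per item, the response option a person
with that score is *most likely* to choose, drawn as contiguous shaded
bands. `tscoremap` builds such maps from graded-response-model (GRM) item
calibrations, scores short forms onto the T metric, and runs the
predicted-vs-observed concordance analysis used to validate map predictions
against real responses. It is aimed at psychometricians and outcomes
researchers working with GRM-calibrated item banks.

## The model

For an item with K ordered response categories (coded 1..K), slope `a > 0`
and thresholds `b_1 < … < b_{K-1}` on the latent trait θ, the GRM boundary
curves are logistic:

    P*_k(θ) = 1 / (1 + exp(−a(θ − b_k))),   k = 1..K−1

with category probabilities as adjacent differences, `P_k = P*_{k−1} − P*_k`
(`P*_0 = 1`, `P*_K = 0`), and `T = 50 + 10·θ`. At each T the **modal
category** is `argmax_k P_k`; the map's band for category k is the interval
of T where k is modal, with band edges located exactly by bisection on
`P_{k+1} − P_k`. Respondents are placed on the map via expected-a-posteriori
(EAP) scoring under a standard-normal prior — either from their exact
response pattern or through a summed-score → T table built with the
Lord–Wingersky recursion. Concordance between map predictions and observed
data is summarized by difference scores (observed − predicted category),
per-item Spearman correlations, and the scale-level perfect-match rate.

## Worked example

The only public numeric anchor for an operational calibration is a pair of
printed probability vectors for the anxiety item *"My worries overwhelmed
me"* (categories never/rarely/sometimes/often/always) at T=60 and T=61.
Inverting them recovers the item and reproduces the published transition:

```python
from tscoremap import (ProbabilitySnapshot, fit_item_from_snapshots,
                       category_probabilities, ItemBank, build_map)

snaps = [ProbabilitySnapshot(60, [0.089, 0.442, 0.415, 0.052, 0.002]),
         ProbabilitySnapshot(61, [0.063, 0.376, 0.484, 0.073, 0.003])]
item = fit_item_from_snapshots(
    snaps, K=5, item_id="worries_overwhelmed",
    labels=["never", "rarely", "sometimes", "often", "always"])
print(round(item.slope, 3), [round(b, 3) for b in item.thresholds])
# 3.672 [0.366, 1.034, 1.78, 2.686]

tmap = build_map(ItemBank(bank_id="anx", items=[item]))
for band in tmap.bands["worries_overwhelmed"]:
    print(f"{band.label:9s} [{band.t_low:5.2f}, {band.t_high:5.2f})")
# never     [20.00, 54.18)
# rarely    [54.18, 60.20)
# sometimes [60.20, 67.63)
# often     [67.63, 76.66)
# always    [76.66, 80.00)
```

The fitted slope (≈3.7 per θ unit) and thresholds are in ordinary symptom-
item territory, the rarely→sometimes crossing falls at T≈60.2 — between 60
and 61 as published — and the fitted curves reproduce every printed
probability to better than 0.001. The same flow is available from the shell
(`tscoremap fit-snapshots`, `tscoremap map`, `tscoremap score`, `tscoremap
simulate`, `tscoremap validate`); see `tscoremap --help`.

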