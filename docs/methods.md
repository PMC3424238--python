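# Methods

## Problem and model

Conformational B-cell epitopes are antigen surface residues, distant in
sequence but spatially adjacent, that antibodies bind. `episeq` treats
per-residue epitope prediction as binary classification of sliding
sequence windows: the instance for residue i is the odd-length window
(default L = 9) centred on i, labelled by the epitope state of i. The
terminals are handled by appending (L−1)/2 `X` symbols to each end, so
every residue — not just the N−L+1 interior ones — receives a window
and a score.

Three stages follow:

1. **Feature views.** Nine window encodings (see the registry in
   `episeq.features`). Per-residue views concatenate one block per
   window position in sequence order; `X`/padded positions contribute
   all-zero blocks and are excluded from both numerator and denominator
   of the composition-type views (composition, functional composition,
   adjacent pair profile), which are simplex vectors whenever defined.
   The evolutionary view consumes a PSI-BLAST PSSM whose integer
   log-odds are rescaled elementwise by the standard logistic function
   1/(1+e^(−x)); secondary structure and RASA come from an external
   structure predictor and are consumed as files.
2. **Imbalance-handling ensembles.** Per view, the negatives are
   shuffled once and split into n = max(1, round(neg/pos)) near-equal
   chunks; each chunk plus all positives forms a balanced sample; one
   random forest (scikit-learn defaults, pinned `random_state`) is
   fitted per sample. The view's score is the mean positive-class vote
   fraction of the n forests. An independent bootstrap-with-replacement
   sampling mode exists behind `sampling="bootstrap"`; the partition
   default uses every negative at least once and is deterministic under
   the seed.
3. **Fusion.** Raw scores are mapped by the tanh-estimator
   s′ = ½(tanh(c·(s−μ)/σ)+1) with (μ, σ) the per-sub-classifier
   training-score mean and population standard deviation (ddof = 0,
   σ floored at 1e−9), then combined as Σ w_i s′_i with w on the
   probability simplex. Mean and median scoring are alternatives.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `window_length` L | 9 | odd window; the full 5–15 sweep is supported and `episeq loocv -L 5,7,...` reports it per dataset |
| `c` (tanh gain) | 0.01 | the small-gain constant of the tanh-estimator from the score-normalization literature; configurable; only the ranking, not the calibration, matters for AUC |
| weights | published 7-view optimum / uniform | grid step 0.05 on the simplex; `"search"` runs the exhaustive search (C(1/step+k−1, k−1) candidates) |
| `n` (sub-samples) | derived | round(neg/pos), half-up; balanced data degenerates to one forest |
| forest hyperparameters | library defaults | the method deliberately uses default base learners; only `random_state` is pinned |
| `threshold` | 0.5 | for SN/SP/ACC/F only; AUC is threshold-free and is the primary metric |
| `terminal_policy` | `full_ensemble` | X-padded windows already cover terminals; `composition_only` instead scores the first/last (L−1)/2 residues with a separate window-composition ensemble that sits outside the weight vector |

## Design choices where the design was open

* **Canonical alphabet order.** All 20-dimensional axes use
  ACDEFGHIKLMNPQRSTVWY; PSSM files declare their own column order in
  the header and are remapped on read.
* **Ambiguity codes.** B, Z, J, U, O map to `X` on input; `X` behaves
  exactly like terminal padding inside every encoder.
* **Propensity scales.** The six scales (Karplus–Schulz flexibility,
  Parker hydrophilicity, Janin buried-surface transfer, a
  Ponnuswamy-type polarity table, Chou–Fasman β-turn propensities,
  Emini accessibility) ship as plain-text data files with source
  citations; several published variants exist for the polarity and
  turn scales, and substituting another total residue→value map is
  supported.
* **Pair profile.** Ordered adjacent pairs within the window
  (20×20 = 400 dims); pairs touching an `X` are dropped.
* **Normalization scope.** (μ, σ) are computed per sub-classifier over
  the training scores, the standard choice in score-fusion; the
  alternative reading — z-scoring across the k sub-classifiers within
  one instance — is provided as `normalize_per_instance` and satisfies
  the same within-instance monotonicity.
* **Grid-search objective.** `loocv(weights="search")` first collects
  out-of-fold normalized sub-scores (ensembles and (μ, σ) fitted inside
  each fold only), then searches the simplex once on the pooled
  out-of-fold scores, maximizing mean per-antigen AUC with ties broken
  toward the lexicographically smallest vector. A fully nested search
  (one grid search inside every fold) would square the cost while the
  searched quantity — a 7-vector on a 0.05 grid — generalises well;
  the single pooled search is also how the published optimum was
  derived. `EpitopeEnsembleModel.fit(weights="search")` searches on
  training scores, which is optimistic and is reported as such
  (`train AUC` column in `summary()`).
* **Rounding of n.** Half-up (`floor(x+0.5)`) so the sub-sample count
  is platform-stable.
* **Numerical edges.** Constant score lists floor σ at 1e−9 with a
  warning; antigens lacking either class are excluded from mean AUC and
  logged; undefined SN/SP/ACC/F denominators propagate as NaN, never
  as 0; a score exactly at the threshold counts positive.

## Synthetic data: what it emulates and what it does not

The generator plants contiguous epitope patches in otherwise i.i.d.
background chains and gives each patch up to four signals with
independent effect-size knobs:

* composition: patch residue frequencies interpolate toward a
  hydrophilic/charged profile (K, R, D, E, N, S boosted) by
  `composition_shift`;
* conservation: PSSM rows are one-hot-like (+7 true residue, −3
  elsewhere) with integer jitter of amplitude `pssm_noise`; inside
  patches the peak drops to +3 and the jitter grows by
  3·`pssm_patch_noise` (epitopes are less conserved);
* exposure: `rasa_shift` percentage points are added to patch RASA
  (baseline: clipped normal, mean 40, sd 18);
* structure: patch H/E/C probabilities mix toward coil by `coil_bias`
  (background 0.35/0.25/0.40).

Presets fix the study conditions. `complementary-signals` (the default
config): 20 antigens, 1–2 chains of 130–170 residues, one 15–35-residue
patch per chain, `composition_shift` 0.6, `pssm_patch_noise` 3.0,
`rasa_shift` 30, `coil_bias` 0.4 — three views (composition,
evolutionary, RASA) carry distinct signal. `single-signal`: composition
only. `null`: every effect knob at 0, so labels are independent of all
features; it uses 36 antigens with three short (8–14-residue) patches
per chain because windows overlapping one patch are near-duplicates —
each patch is roughly one independent unit in a per-antigen AUC, and
with one long patch per chain the chance-level mean AUC is too noisy to
resolve against its expected 0.5.

What passing tests on this generator show: the pipeline recovers
planted signals through the intended view, fused scoring is at least as
good as the best single view, and nothing is learned when no signal
exists. What they do not show: performance on real antigens. Real
epitopes are discontinuous in sequence, background composition is not
i.i.d., PSI-BLAST profiles encode homology structure far richer than
jittered one-hots, and secondary-structure/RASA predictors have
correlated errors. Benchmark-scale claims require real bound/unbound
datasets with genuine PSSMs and structure predictions.

## Problem sizes used in the shipped checks

The acceptance script and the signal-recovery tests run LOOCV with
three sub-classifiers on the complementary preset (20 antigens, ~4,300
windows, n = 5 sub-samples per view per fold) and the composition
sub-classifier on the null preset (36 antigens, ~4,500 windows); both
finish in a few minutes on one CPU. Protocol-level unit tests use
25-tree forests on toy datasets where only the plumbing, not the
learning curve, is under test.

## Known limitations

* Random-forest implementations differ in split randomisation and vote
  semantics across libraries; the score contract (mean positive-vote
  fraction in [0, 1]) is what is pinned, not bit-level behaviour of a
  particular forest engine.
* The tanh-estimator with c = 0.01 compresses scores into a narrow band
  around 0.5; thresholded metrics at 0.5 effectively compare raw scores
  to their training mean. AUC, the primary metric, is unaffected.
* `predict` with the published default weights requires PSSM, SS and
  RASA tracks (the nonzero-weight views); views with weight exactly 0
  are pruned from the required-track set.
* PSSM parsing accepts the PSI-BLAST `-out_ascii_pssm` dialect only.
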