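# Methods

This note documents the models implemented in `braakadl`, the choices
made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the package's numerical
conventions and limitations.

## Staging model

Tau-PET uptake is summarised as SUVR in six composite ROIs ordered by
Braak's anatomical sequence (I = transentorhinal → VI = primary
cortices). The abnormality threshold of each ROI is
`mean + k·SD` over a young cognitively-unimpaired reference sample
(default k = 2.5; sample SD with the n−1 denominator; the reference age
cut, default < 26 years, is a parameter of the reader and the
generator). A participant's stage is the highest ROI whose SUVR
*strictly* exceeds its threshold, 0 if none; stages are binned into the
simplified groups 0, I–II, III–IV, V–VI.

Open choices and how they were resolved:

* **Tie rule.** Boundary-equal SUVR is classified normal, for
  consistency with the strict amyloid-positivity rule (SUVR > 1.55).
* **Skip patterns.** Abnormality that skips an intermediate ROI has no
  interpretation under the spreading model. The literal latest-abnormal
  rule is still applied, a `contiguous` diagnostic is reported, and the
  event is logged as a warning, never an error.
* **Baseline only.** Stages are assigned from baseline SUVR; follow-up
  scans play no role in any model.

A consequence of the k-SD rule worth stating explicitly: with Gaussian
reference noise the rule flags a truly normal ROI with probability
≈ Φ(−2.5) ≈ 0.6% (more once the threshold's own estimation noise from a
30-scan reference is included, ≈ 1%). Over six ROIs this puts roughly
3–6% of truly stage-0 participants into a higher group. Group-recovery
accuracy on synthetic cohorts therefore hovers around 96–97%, not 100%,
and the recovery test averages over seeds rather than relying on one.

## Functional instruments

FAQ: sum of 10 items each 0–3 (total 0–30). ECog: mean of 39 items each
1–4. CDR-SB-F: sum of the three functional boxes (community affairs,
home and hobbies, personal care), each in {0, 0.5, 1, 2, 3} — the
standard instrument's value set, assumed because half points exist in
the CDR's box scoring. Higher is always worse. Scores are computed only
from complete item sets; there is no imputation, and records without a
score are excluded per analysis, not globally.

## Regression models

All continuous variables are z-scored (mean 0, SD 1, n−1 denominator)
before entering a model; sex enters as a male = 1 indicator and stage
groups are dummy-coded against group 0, so a stage beta is an adjusted
group difference in outcome-SD units. The default adjustment set is age,
sex and neocortical amyloid SUVR; clinical diagnosis (vs CU) can be
added for the exploratory variant. 95% CIs use the t distribution with
residual degrees of freedom. Models are fitted on complete cases, and by
default the z-scoring statistics come from each model's analytic sample;
a flag switches to whole-table scaling (the two readings of "z-scored on
the whole sample"). No multiple-testing correction is applied across the
three instruments; significance is p < 0.05 throughout.

Annual change is `(follow-up − baseline) / years` per participant (a
single follow-up visit; intervals from dates are converted at 365.25
days/year). Outliers are rates more than 2.5 SD from the whole-sample
mean of that instrument's rates — a single pass, two-sided by default
(a one-sided low-tail variant is available), detected per instrument.
Flagged records are excluded from the change models with a logged
reason.

## Voxelwise mapping and random-field correction

Per voxel, intensity is regressed on the score plus covariates by OLS;
the t-statistic of the score term forms the map. Voxels with zero
residual variance (to float precision) are set to t = 0 and annotated
rather than producing infinities. Residual smoothness is estimated from
the normalised residuals: per axis, the mean squared spatial derivative
λ gives FWHM = √(4 ln 2 / λ) voxels; the resel count is the masked
volume divided by the product of the FWHMs.

The corrected threshold is peak-level and one-sided (positive contrast:
higher tau, worse function, matching the direction of every modelled
association): the smallest t at which the expected Euler characteristic
of the excursion set, Σ_d R_d ρ_d(t) with the standard t-field EC
densities up to d = 3, falls to α (default 0.001). The resel counts
R_0..R_3 use a cube model of the search region (side = R_3^{1/3}); this
is exact for box-shaped regions such as the simulated masks and full
grids, and an approximation for irregular brain masks whose
lower-dimensional boundary terms differ — for large search regions the
R_3 term dominates and the approximation is mild. Cluster-extent
inference and permutation correction are out of scope. On simulated
null smooth fields (30³ voxels, FWHM 3 voxels, df 40) the empirical
familywise error at α = 0.05 sits at or below nominal, reflecting the
well-known mild conservatism of RFT on discrete lattices.

Overlap between the suprathreshold map and a Braak ROI mask has no
unique denominator; both conventions are reported — the fraction of ROI
voxels that are suprathreshold (default) and the fraction of
suprathreshold voxels inside the ROI.

## Trial design

The per-arm sample size uses the classical two-arm difference-of-means
normal approximation, n = 2σ²(z₁₋α/₂ + z_power)²/(f·μ)², rounded up,
where μ and σ are the control arm's mean and SD of annual decline and f
the fractional slowing attributed to treatment (default 25%; equal SDs
across arms; defaults α = 0.05 two-sided, power 0.80). An iterated
t-quantile correction is available for small n. `simulate_power`
verifies any design by simulating two-arm trials and testing with the
two-sided pooled t-test; across σ/μ ∈ {0.5, 1, 2, 4} the empirical power
at the formula's n stays within about ±3 points of the target.
Recruitment-inflation ratios divide each earlier group's n by the V–VI
n per instrument and are rounded to 2 decimals.

## Synthetic-data generator

The generator emulates the *structure* the analysis assumes, with
defaults matching the study conditions: n = 291 split 112/78/35/66
across groups; a 30-scan young reference; follow-up for 188/291 after a
truncated-normal interval (mean 1.97 y, SD 0.66, range 0.8–3.6); age
N(70.60, 7.48²); 62.8% female; amyloid SUVR means rising by group
(1.38/1.75/2.01/2.64); group-dependent MMSE and diagnosis mixes. ROI
SUVR profiles are abnormal (mean shift +0.5, ROI noise SD 0.05) exactly
through each participant's true top stage, drawn uniformly within the
group's stage pair.

Functional scores arise from latent z-variables: latent =
group effect + noise, with baseline effects (0, 0, 0.45, 1.2) SD for
FAQ- and ECog-like outcomes and (0, 0, 0, 1.2) for the CDR-SB-F-like
outcome, and annual-decline effects confined to V–VI (1.69 / 1.05 /
1.29 SD). Latents map affinely to the raw scales and are realised as
item-level responses (uniform random compositions under the per-item
caps, via multivariate hypergeometric draws; CDR box triples drawn
uniformly among valid triples at the nearest achievable total), so the
scoring operators are exercised end to end.

Free parameters the source tables do not pin down were fixed once, by
design analysis, and not revisited:

* **Noise scales.** Latent noise SD 0.45 (baseline) and 0.7 (rates),
  with correlation 0.7 between instruments. The rate value makes the
  between-group share of rate variance ≈ 0.5, matching the strongest
  printed longitudinal model fit (adjusted R² 0.50); the baseline value
  puts the realized III–IV t-statistics near 3.5 — deliberately above
  the marginal t ≈ 2.2 of the corresponding real-data cell — so the
  qualitative pattern (FAQ/ECog effects from III–IV, CDR-SB-F and
  decline only at V–VI) is a reliable property of the testbed rather
  than a coin toss.
* **Raw-scale mappings.** Chosen so floor censoring stays modest for
  FAQ/ECog (≈ 5–10% at the floor) while CDR-SB-F keeps the heavy zero
  floor the real instrument shows in unimpaired participants. Heavier
  floors were found to induce wrong-sign artifacts in null stage terms
  and to attenuate decline effects, which real-data models would also
  suffer but which would contaminate the generator's calibration tests.

What the generator does *not* emulate: PET physics (resolution, scatter,
meningeal spill-over), longitudinal SUVR change, item-level response
psychology (items are exchangeable given the total), missing data
(complete by construction; tests inject missingness explicitly), and
real-world staging ambiguity beyond Gaussian ROI noise. Passing
recovery tests therefore show the *pipeline* is correct and calibrated
under the stated generating process — not that the effect sizes would be
recovered from real scans.

Toy image sets add a score-coupled signal inside Braak-like box masks to
stationary smooth Gaussian noise (periodic smoothing, renormalised to
unit marginal SD), on grids small enough for simulation studies
(default 16³–30³; the familywise calibration uses 30³ with ~1000
resels).

## Numerical conventions

* Sample SDs use n−1 everywhere.
* Strict inequalities at every classification boundary (staging,
  amyloid, outliers, suprathreshold).
* Sample sizes round up; inflation ratios round to 2 decimals.
* All generators accept a seed and are bit-reproducible under it.
* Degenerate inputs fail loudly with the offending item/ROI/group named,
  except where the contract says otherwise (zero-SD rates → no outliers
  with a warning; skip patterns → warning).

## Known limitations

* The RFT implementation is peak-level only, with the cube resel model
  described above; no cluster inference.
* The outlier rule is the single-pass whole-sample version; no
  iterative or robust variant.
* Change models assume one follow-up per participant; longer
  trajectories would need mixed models, which are out of scope.
* The trial formula ignores dropout and covariate adjustment.
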