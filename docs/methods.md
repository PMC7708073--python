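# Methods

## Model and assumptions

`hybridnn` treats an RNA/DNA hybrid as a fully Watson–Crick paired,
bimolecular, non-self-complementary duplex whose formation is a two-state
transition (single strands ⇌ duplex) with temperature-independent ΔH° and
ΔS° (ΔC_p = 0). Under the nearest-neighbor model each of ΔH°, ΔS° and
ΔG°₃₇ is the sum of one contribution per adjacent base-pair stack plus a
helix-initiation term. A duplex of N pairs has N−1 stacks; the i-th stack
is written `r<XY>/d<Z W>` with both dinucleotides 5'→3' (the DNA
dinucleotide is the reverse-complement pairing of the RNA one), giving 16
distinct stacks for hybrids — unlike homo-duplexes there is no
strand-exchange symmetry to halve the count. Two initiation terms exist:
`init_GC` applies when at least one terminal base pair is rG−dC or rC−dG,
`init_AU` when both terminals are rA−dT or rU−dA. Hybrids of two distinct
strands cannot be self-complementary, so the bimolecular T_m relation
always uses C_t/4:

    1/T_m = R ln(C_t/4)/ΔH° + ΔS°/ΔH°,  R = 1.987 cal mol⁻¹ K⁻¹.

Constants: T₃₇ = 310.15 K, °C = K − 273.15. Units are kcal/mol for ΔH°
and ΔG°₃₇ and cal/(mol K) for ΔS°; the factor 1000 appears only in
`consistent_entropy` and `predict_tm`, and is unit-tested there.

## The two entropy conventions for predicted T_m

The bundled 100 mM NaCl parameter set carries ΔH°, ΔS° and ΔG°₃₇ columns
that were each fitted independently, so the three columns are not exactly
related by ΔG°₃₇ = ΔH° − T·ΔS° (`internal_consistency_report` shows
stack discrepancies ≤ 0.05 kcal/mol but initiation discrepancies up to
~0.5 kcal/mol). Consequently a predicted T_m can be computed two ways:

* `dg_consistent` (default): ΔS° = (ΔH°_pred − ΔG°₃₇,pred)·1000/310.15.
  This keeps the reported triple thermodynamically coherent and
  reproduces the reference predictions of the bundled panel.
* `stack_entropy`: ΔS° is the plain NN sum of the ΔS° column. For the
  bundled set this runs systematically ~2–4 °C warmer.

Both modes are exposed; the divergence is deliberate and tested. The
panel-wide ΔS° prediction error is likewise reported under both
conventions (10.1 % dg-consistent, 9.9 % stack-sum) since the choice is
not uniquely determined.

Two rows of the bundled panel (labels 10 and 16) carry reference
predicted values that differ from strict sums of the rounded bundled
parameters by 0.3 kcal/mol (and ~1 °C in T_m); their printed T_m is
self-consistent with their printed ΔG°₃₇, indicating those reference
rows were computed with unrounded parameters that are not recoverable
from the published table. The golden test over the panel documents this
by failing on exactly those two rows; all summary statistics are
unaffected.

## Sequence factors and salt-response groups

ƒ(G−C) = (N_G−C − N_A−U/T)/N_total and ƒ(rPu) = (N_pu − N_py)/N_total are
pure composition statistics of the duplex (purines counted on the RNA
strand). Group A is ƒ(G−C) > 0 and ƒ(rPu) > 0, Group B both negative,
Group C everything else. Sequences with exactly one zero factor are not
explicitly assigned by the original grouping prose; this package uses
strict sign tests so any zero factor lands in Group C, consistent with
the balanced exemplar sequences. The affine 1 M → 100 mM corrections are
ΔG°₃₇: 0.63x − 1.667 (global), 0.698x − 2.065 / 0.662x − 0.682 /
0.664x − 1.637 (Groups A/B/C), and T_m: 0.876x − 5.148 (global only; no
group-specific T_m model exists, and requesting one is an error).

## Least-squares parameter derivation

`build_design_matrix` maps each duplex to its 16 stack counts plus two
initiation indicators; for the ΔH° fit the initiation columns are dropped
entirely, which is exactly the constraint ΔH°_init = 0 (initiation is
modelled as entropy-only, reflecting the translational/rotational freedom
lost on first-pair formation). The three quantities are fitted in
separate unweighted ordinary least-squares regressions via SVD
(`numpy.linalg.lstsq`); the rank is always reported and a rank-deficient
design triggers a `RankDeficientWarning` with a minimum-norm solution,
because stack-count designs are collinearity-prone. Standard errors are
classical OLS SEs, √diag(s²(XᵀX)⁺) with s² = RSS/(n − rank); a
Monte-Carlo test checks they match the empirical scatter of repeated
noisy fits. A weighted option (weights = 1/σ) and an optional terminal
rA−dT/rU−dA count column exist for experimentation but are off by
default — the terminal column was found not to improve hybrid
predictions, the two initiation classes already absorbing the terminal
H-bonding difference. Exact reproduction of the published parameter
decimals from the bundled panel is out of scope (the original fit's data
handling is not fully recoverable); the self-consistency requirement is
that a refit re-predicts the panel at least as well as the published set
(≤ 3.2 % mean ΔG°₃₇ error), which holds.

Error propagation into ΔG°₃₇ uses
σ² = σ_H² + 310.15²σ_S² − 2·310.15·R_{H,S}·σ_H·σ_S with the ΔH°–ΔS°
estimate correlation R_{H,S}; because van't Hoff estimates are almost
perfectly correlated (R → 1), ΔG°₃₇ errors are an order of magnitude
smaller than ΔH° errors, which the panel's measured ±values exhibit.

## Melting simulation and van't Hoff analysis

The synthetic melting-curve generator emulates UV absorbance melting of
an equimolar two-strand duplex: duplex fraction α(T) solves
K = 2α/((1−α)²C_t) with K = exp(−(ΔH·1000 − TΔS)/(RT)), absorbance is a
linear-baseline mixture A(T) = ss(T)(1−α) + ds(T)α (defaults: ~15 %
hyperchromicity, gently sloping baselines, grid 0–90 °C in 0.5 °C steps
matching a 0.5 °C/min ramp), plus optional i.i.d. Gaussian noise with an
explicit seed (σ = 0 by default, so fixtures are deterministic). α = ½
exactly where K = 4/C_t, i.e. at the T_m of the 1/T_m relation — the
generator and the predictor are two routes to the same algebra, which the
round-trip tests exploit. The generator does not emulate: ΔC_p ≠ 0
curvature, intramolecular structure or aggregation (non-two-state
transitions), instrument drift or hysteresis, or concentration error
between cells. Passing tests therefore validate the estimators under the
two-state model, not against every pathology of real melting data.

`extract_tm` fits linear baselines over the lower and upper 15 % of the
temperature span and interpolates the 0.5 crossing of the
baseline-normalized fraction (the median method; the last crossing is
taken, which is robust to baseline-edge noise). Identical baselines (no
hyperchromicity) are an error. A caveat discovered in testing: a window
that misses the true transition still normalizes whatever residual tail
it contains into an apparent full sigmoid — the absolute duplex fraction
is unidentifiable from a single normalized curve — so a missed transition
cannot be detected mechanically; the guard is a warning whenever the
extracted T_m falls outside 20–55 °C, the range in which extrapolation of
ΔH°, ΔS° to 37 °C is trusted.

`vant_hoff_fit` regresses 1/T_m (kelvin — Celsius inputs are converted at
the boundary, a classic silent-bug site that is explicitly unit-tested)
on ln(C_t/4): ΔH° = R/slope, ΔS° = intercept·ΔH°. The (ΔH°, ΔS°)
covariance comes from the regression covariance by the delta method,
yielding σ_ΔH, σ_ΔS and their correlation for the propagation formula
above. At least 3 points with distinct C_t are required; practice is
10–12 concentrations spanning ~100-fold.

## Problem sizes used in tests and the acceptance script

All reference statistics are computed on the bundled 38-duplex panel
(6–14-mers, C_t = 8 μM). Synthetic fitting studies use 40–60 random
duplexes of length 6–14 (full-rank designs verified explicitly);
Monte-Carlo calibration checks use 120–200 replicates with ±0.3 °C T_m
jitter over 10–11 concentrations spanning 100-fold — sizes chosen to make
the standard-error comparisons stable at a few-percent level. All seeds
are fixed.
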