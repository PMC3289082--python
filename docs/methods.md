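# Methods

## Fragment mass arithmetic

All mass tests derive from the b/y fragmentation identities of peptide
CID. For a peptide of neutral monoisotopic mass M (residue-mass sum plus
one water), cleavage at bond i gives a b ion at
`mz(b,1) = Σ residues(1..i) + m_H+` and a y ion at
`mz(y,1) = Σ residues(i+1..n) + m_H2O + m_H+`; a doubly protonated
fragment sits at `(mz(+1) + m_H+)/2`. Substituting the precursor relation
`M = z·m_p − z·m_H+` eliminates the unknown sequence and yields the
pair-sum identities used by the predicates in `cidcharge.fragments`
(documented in that module's header). Because the identities are linear in
the member m/z values, adding a neutral loss back to one pair member
shifts the tested linear form by the loss mass times that member's
coefficient (1 for a +1 slot, 2 for a +2 slot); the implementation
therefore reduces all loss variants to a set of scalar shifts and
evaluates every pair against every (kind, charge-hypothesis) combination
in a single vectorized pass. An exhaustive scalar re-enumeration in the
test suite guards this reduction.

Masses are monoisotopic: residue masses from pyteomics' standard table,
proton 1.00728 Da, H2O 18.01056, NH3 17.02655, CO 27.99491, NH 15.01090.
All constants are overridable (e.g. for an average-mass table) via
`MassConstants` or a `key: value` config file. The match tolerance is a
symmetric absolute window, default **0.5 Da**, the customary fragment
accuracy of ion traps; no instrument-specific calibration is attempted.
Only single neutral losses are applied, to one pair member at a time:
stacked losses explode the combinatorics without adding discriminant
signal at this tolerance.

## Features

* **δ_cp** counts distinct peak pairs satisfying the (+1, +1) identity
  under either charge hypothesis, minus distinct pairs satisfying the
  (+1, +2) identity in either orientation. A pair contributes once per
  set however many variants it matches. The feature is integer-valued.
* **δ_Rcp** is the intensity analogue. Intensities are aggregated by
  *set sums*: the numerator sums each distinct lower-m/z member of a
  (+1, +1) pair once, the denominator each distinct higher-m/z member,
  and likewise (+2-designated members vs their +1 partners) for the
  (+1, +2) sets. Set sums are robust to zero denominators; per-pair ratio
  averaging is available as `ratio_mode="pair_mean"` for sensitivity
  analysis. The +0.5 offset compensates the known y-over-b intensity
  asymmetry and is added only when the (+1, +1) set is non-empty — a
  spectrum with neither pair type scores exactly 0, and a spectrum with
  only (+1, +2) pairs scores the negative ratio rather than 0.5 minus it,
  which keeps the sign of the evidence.
* **I_dc** sums the intensity of peaks consistent with a doubly charged
  fragment (a +1 counterpart at `2m − m_H+`, or membership as the +2 slot
  of a (+1, +2) pair under z = 3) inside the closed region
  `[m_p, 1.5·m_p]`. Only +3 precursors can populate that region with +2
  fragments, since a +2 fragment of a +2 precursor cannot exceed `m_p`.
* **n_bs** counts unordered peak pairs whose m/z difference matches a
  K, R or H residue mass within tolerance, directly or with one neutral
  loss on either member, each pair at most once, divided by the
  theoretical repeat number `nt`. `nt` defaults to 1 (raw pseudo-count);
  deriving a better repeat number from fragment-ion statistics is an open
  refinement deliberately left as a parameter.

For classification the features are divided by their sample standard
deviation (ddof = 1) so each retained column has unit variance; no
mean-centering by default (the mixture estimates means anyway, and
uncentered scaling keeps the raw feature signs interpretable; centering is
a flag). A constant column is an error, not a silent drop. The default
classifier uses {δ_cp, δ_Rcp, I_dc}; the basic-site count is the weakest
feature and is excluded from the default subset but available everywhere.

## Mixture model and EM

The model is a K = 2 component Gaussian mixture with a single scalar
variance per component (spherical covariance), mixing weights on the
simplex. The E-step computes responsibilities in the log domain
(log-sum-exp), so distant points never underflow to an error. The M-step
uses the closed-form stationary equations: responsibility-weighted means,
per-dimension weighted mean squared deviation for the variance, average
responsibility for the mixing weight. The softmax reparameterization that
enforces the mixing-simplex constraint during derivation reduces to this
closed form at the stationary point and is not carried at runtime.

Numerical guards: variances are floored at 1e-6 (scaled-feature units²)
to block component collapse; a component whose total responsibility falls
below 1e-10 is reseeded from a random data point. Initialization runs one
deterministic start (split at the median of the first feature column,
halves' statistics, equal mixing) plus 10 random hard-assignment restarts
drawn from the seed; the highest final log-likelihood wins. Convergence:
relative log-likelihood change below 1e-8 or 500 iterations. The EM
monotonicity guarantee is asserted in the tests with 1e-9 absolute slack
for float accumulation.

Components are unlabeled after an unsupervised fit. The label rule votes
per feature on which component's mean sits on the +2 side of that
feature's physical direction (pair features larger for +2, region
intensity and basic-site count larger for +3); majority wins, ties break
on δ_Rcp when present. The +3 posterior is the responsibility of the
+3-labeled component; the charge call is +3 strictly above the threshold
(default 0.5), so a posterior exactly at threshold is called +2.

## ROC/AUC

The positive class is +3. The threshold sweep groups tied scores, and the
trapezoidal area then equals the two-sample rank statistic (concordant
pairs plus half the ties over all +3/+2 pairs); this identity, the exact
antisymmetry `AUC(s) + AUC(−s) = 1`, and agreement with an external
implementation are all asserted in tests. Single-feature AUCs are
orientation-corrected (`max(a, 1−a)`, orientation reported) so a
discriminant feature scores above 0.5 whichever class it favors.

## Synthetic data generator

The generator emulates the statistical structure the features exploit,
with deterministic class allocation (`round(n·frac_plus3)` spectra are
+3) and full per-peak provenance. Defaults, frozen as the package's study
conditions:

| parameter | default | rationale |
|---|---|---|
| peptide length | 8–20 residues | typical tryptic range |
| fragmentation efficiency | 0.7 | mid-quality ion-trap bond coverage |
| (+1,+2) emission for +3 | 0.7 | strong but non-degenerate class signal |
| y/b intensity median ratio | 2.0 | y-series dominance in tryptic CID |
| m/z jitter SD | 0.15 Da | centroiding error well inside the 0.5 Da window |
| noise peaks | Poisson(10), uniform in (50, 2·m_p) | sparse chemical noise covering the I_dc region |
| intensity CV | 0.3 | lognormal spread of fragment abundances |

Charge placement: +2 peptides carry one basic site (C-terminal K/R), +3
peptides exactly one extra internal K/R/H. When a +3 precursor emits a
(+1, +2) pair, the **y ion takes the +2**: it contains the C-terminal K/R
and, for most bonds, the internal basic residue, so it retains both
protons. (An earlier design that gave the +2 to whichever fragment is
heavier makes the (+2)/(+1) intensity ratio average to 1 by symmetry under
a type-based intensity model, erasing δ_Rcp's signal — physically the
charge follows the basic sites, not the mass.)

What the generator does **not** model: mobile-proton fragmentation
chemistry, a/c/x/z series, isotope envelopes, correlated electronic
noise, intensity dependence on m/z position, and — most consequentially —
the peak richness of real ion-trap spectra, which carry hundreds of
fragment-related peaks rather than the ~30 produced here.

That last gap has a measurable consequence. On sparse synthetic spectra
the pair-count feature δ_cp is nearly noiseless (chance relations shift
both classes equally), while δ_Rcp's intensity sums run over only a
handful of pairs, so chance pairs with heavy-tailed lognormal intensity
ratios dominate its within-class variance: on generator defaults the
single-feature AUCs rank δ_cp ≈ 0.99 > I_dc ≈ 0.93 > δ_Rcp ≈ 0.67 >
n_bs ≈ 0.6. On real ion-trap data the intensity-ratio feature is reported
as the most discriminant, a ranking that dense spectra (whose set sums
average over many pairs) make plausible. Passing end-to-end tests here
therefore demonstrate the pipeline's correctness and the features'
direction structure, not the relative feature ranking expected on
instrument data.

## Problem sizes

End-to-end checks use 1000 spectra (the acceptance script's size) and
finish in seconds; oracle comparisons run 100 random spectra against
scalar brute-force enumerations; EM parameter recovery uses N = 2000
points in D = 3 at 6σ separation. These sizes give stable Monte-Carlo
behavior at interactive runtimes.

## Known limitations

* Charges +1 and ≥ +4 are out of scope (singly charged spectra are
  assumed filtered upstream; ≥4 is rare in ion-trap tryptic work).
* The precursor m/z is taken verbatim from PEPMASS — no monoisotopic
  correction of the isolation-window center.
* `n_bs` uses plain mass differences; ion-type co-occurrence and
  adjacent-basic-site effects are not modeled.
* The decision threshold (0.5) is not optimized; sweep it via the ROC
  export if a different precision trade-off is needed.
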