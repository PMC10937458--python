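# Methods

## Survival-curve models

All four models are expressed as ln S(d), the log surviving fraction after a
single acute dose d (Gy):

* **LQ**: ln S = −(αd + βd²).  Two parameters; known to over-curve at the
  large single doses used in SBRT and BNCT.
* **USC**: LQ for d ≤ D_T, multi-target line ln S = −(d − D_q)/D_0 for
  d ≥ D_T.  We impose continuity of both value and slope at D_T, which
  forces β = (1 − αD_0)²/(4·D_q·D_0) and D_T = 2·D_q/(1 − αD_0), leaving
  three free parameters (α, D_0, D_q).  The published SCC coefficients
  satisfy both relations to printed precision, so the smooth join is the
  parametrization actually used in practice.
* **LQL**: LQ for d ≤ D_T, straight line of slope γ = α + 2βD_T above —
  the LQ tangent continued linearly, so it is C¹ by construction with free
  (α, β, D_T).
* **PLQ**: ln S = −(αd + βd²)/(1 + γd), a rational (Padé) softening of LQ
  that is smooth everywhere and reduces to LQ at γ = 0.

**USC/LQL equivalence.** With the smooth-join constraint the USC family and
the LQL family are the *same* set of curves: (α, D_0, D_q) ↔ (α, β, D_T)
is a bijection on the valid domain (D_0 = 1/γ, D_q = βD_T²/γ, always
positive with αD_0 < 1).  Consequently no dataset can distinguish them by
goodness of fit.  `compare_models` therefore (a) cross-seeds each fit from
the other's optimum so both reliably reach the shared minimum, and (b)
breaks SEE ties (|ΔSEE| ≤ 1e-8, also the tolerance at which nested LQ/USC
fits tie on pure-LQ data) by fewer free parameters and then by the fixed
registry order LQ, USC, LQL, PLQ.  Ranking USC ahead of LQL in an exact tie
is a convention, reflecting the USC's standard role in single-high-dose
radiobiology.

**Fitting.** Least squares on ln S (unweighted by default; optional
per-point weights).  The objective matches the noise model of clonogenic
data, which is closer to lognormal in S.  Zero-dose points (S = 1) are kept;
they anchor the intercept.  LQ is a bounded linear least-squares problem and
is solved directly.  The nonlinear families use bounded trust-region least
squares (`scipy.optimize.least_squares`, ftol/xtol/gtol 1e-14) from seeded
Latin-hypercube restarts (default 10, seed 20240229) plus data-driven
heuristic starts (LQ fit for α, β; a straight-line fit to the upper-dose
half of ln S for D_0, D_q).  USC is optimized in the transformed coordinates
(α, u = αD_0, D_q) with u ∈ (0, 1), which makes the αD_0 < 1 constraint a
simple box bound.

**Model comparison.** The standard error of the estimate is
SEE = sqrt(Σ(ln S_obs − ln S_pred)²/(N − p)), p the number of free
parameters (2 for LQ, 3 otherwise).  The literature names this criterion
without writing it; residual standard error in ln S space with the N − p
denominator is the standard reading and penalizes the extra parameter of
the flexible models.

## Weighted dose and BED/EQD2 conversion

The weighted dose is D_w = CBE·D_boron + RBE·(D_thermal + D_fast) + D_gamma
with tumor factors CBE = 3.8, RBE = 3.2 (normal-tissue CBE 1.3 is provided
as a constant but no NTCP conversion is implemented).

Under the USC model the BED of n fractions of d Gy is piecewise:
n·d·(1 + d/(α/β)) on the LQ branch (d ≤ D_T) and n·(d − D_q)/(α·D_0) on the
multi-target branch.  A single BNCT delivery uses the multi-target form
unconditionally, BED = (D_w − D_q)/(α·D_0): doses in (D_q, D_T) are
converted on the extrapolated line with a warning rather than silently
switching branch, and doses below D_q (negative BED) are errors.

Equating with an LQ schedule at d = 2 Gy gives
EQD2 = BED/(1 + 2/(α/β)) whenever 2 Gy ≤ D_T — the case that applies to the
SCC coefficients (D_T = 4.66 Gy).  The opposite branch (2 Gy ≥ D_T) is
implemented as EQD2 = D_w + (n − 1)·D_q with n resolved as the smallest
fraction count covering EQD2 at 2 Gy/fraction by fixed-point iteration; it
is retained for completeness, flagged as rarely reachable, and not defined
for multi-fraction input.

DVHs are converted bin by bin (the map is strictly increasing, so bin order
and volumes are preserved).  Bin doses are interpreted as per-fraction
weighted doses; with `fractions > 1` the per-fraction BEDs are summed before
the isoeffect division.  The default is `fractions = 1`: treating the
reported weighted dose as a single delivery is the reading under which the
published per-target gEUD/TCP table is reproducible, although the trial
protocol delivered two fractions.  Whether reported minimum doses are
per-fraction or totals is not documented; both readings are supported via
the `fractions` parameter.

## DVH handling

Differential bins are point masses at their stated dose (the gEUD sum is
over discrete (v_i, D_i) pairs; no intra-bin spread is assumed).  Cumulative
input follows the volume-receiving-≥-dose convention.  Differential volumes
may sum to within 1% of unity and are renormalized (exported DVHs commonly
round); larger deviations are parse errors.  `volume_fraction_below` uses a
strict inequality, matching the "volume below threshold" phrasing of
clinical summaries.  `dose_at_volume` interpolates linearly between
cumulative points.

## gEUD and TCP

gEUD = (Σ v_i·D_i^a)^(1/a) is evaluated in log space
(logsumexp of ln v_i + a·ln D_i) so that a = −13, or the a = −200 used in
convergence checks, cannot underflow; agreement with the naive power sum is
property-tested at 1e-10 relative.  The volume-weighted form is implemented;
the equal-volume form is its special case v_i = 1/N.  For a < 0, any
contributing dose ≤ 1e-6 Gy is an error (diverging term), never clamped.

gEUD is computed on the **EQD2-converted** DVH, not on raw Gy-w: the TCP
parameters (TCD50 = 46.8 ± 6.4 Gy, γ50 = 2.0) are photon-derived and live on
the EQD2 scale, and this choice reproduces the published per-target TCP
values from the published gEUDs.  The logistic model is
TCP = 1/(1 + (TCD50/gEUD)^(4γ50)); its normalized slope at TCD50 equals γ50
exactly, which is property-tested by finite differences.  The TCD50
uncertainty is stored and exposed as a CLI sensitivity sweep
(`--sweep-tcd50`) but not propagated — matching how the parameters are used
in practice.

TCP bands map onto response levels: ≥ 60% CR-level, ≥ 25% PR-level, else
sub-PR, with inclusive boundaries.  TCP is held at full precision
internally; rounding (half-up, one decimal) happens only in the reporting
layer (`format_report`).

### Reproduction accuracy of published values

The published per-target table prints gEUD to 3 significant figures and TCP
to one decimal, but its TCPs were evidently computed from unrounded gEUDs:
recomputing TCP from the printed gEUD reproduces the printed TCP only to
about one unit in the last printed decimal (e.g. 56.5 Gy → 81.86% vs
printed 81.8%; mid-curve the sensitivity is ≈ 4 pp per Gy, so a ±0.05 Gy
printing error moves TCP by up to ≈ 0.2 pp).  Tests therefore assert
agreement at 0.1 pp for the well-conditioned pairs and 0.2 pp for pairs near
a rounding boundary, rather than exact decimal equality.

## Synthetic data

The generators define the conditions under which the package is tested:

* **Clonogenic data**: 24 doses on 0.5–12 Gy (spanning both USC branches)
  plus a zero-dose anchor, S = exp(ln S_USC + ε), ε ~ N(0, σ²) with
  σ = 0.1 — multiplicative lognormal noise on S, consistent with the ln S
  fitting objective and typical clonogenic scatter.  Under these conditions
  a noiseless fit recovers the SCC coefficients to ≪ 1%, and across 200
  noisy replicates the USC ranks first by SEE in ≈ 96% of cases (PLQ wins
  the remainder by chance).
* **DVHs**: an atom of volume `cold_spot_volume · min_atom_fraction`
  (default 1e-3) exactly at the requested minimum dose; the remaining
  cold-spot volume on (min, 18.5 Gy-w) shaped Beta(cold_skew, 1); the main
  mass Beta-shaped (or bimodal) between the threshold and the maximum dose.
  Volumes are jittered multiplicatively (seeded) and renormalized part by
  part, so the minimum dose and the volume below the threshold are *exact*
  construction targets.  The two shipped configs emulate the published
  cold-spot contrast — 15% vs 2% of volume below 18.5 Gy-w at ≈ 9 Gy-w
  minimum dose — and their `cold_skew` values (1.7 and 5.0) were calibrated
  once against the published gEUDs of that contrast (≈ 31 and ≈ 44.7 Gy);
  the package reproduces them at 31.2 and 44.9 Gy.
* **Cohorts**: minimum doses drawn on 6–26 Gy-w and cold-spot volumes on
  1–25%, spanning the full TCP range; ~25% of patients get a second target.
  All generators are deterministic per integer seed.

What the synthetic DVHs do **not** emulate: spatial correlation between
dose and tumor sub-regions, boron-uptake heterogeneity, inter-fraction
variation, or DVH export artifacts beyond mild volume rounding.  Passing
tests therefore demonstrate the correctness of the dose-conversion and
reduction chain and its phenomenology (minimum-dose dominance, cold-spot
volume sensitivity), not clinical predictive performance on real plans.

## Numerical choices

* lnS-space SSE minimized; ties and convergence as described above.
* gEUD in log space; TCP closed form; no iteration anywhere downstream of
  fitting except the (unreachable-by-default) second EQD2 branch.
* Degenerate inputs: empty DVHs, volumes summing outside 1 ± 0.01,
  non-monotone doses, doses below D_q, TCP inputs outside (0, ∞) and
  classification inputs outside [0, 100] all raise with context; cohort
  runs collect per-patient failures and continue.
* Problem sizes: default test suite and the replicate study (200 fits × 4
  models at 25 points each) run in well under a minute on one core.

## Known limitations

* No refit of the original FaDu clonogenic data (not redistributable); the
  fitting machinery is validated by parameter recovery on synthetic data.
* TCD50 uncertainty is not propagated into TCP intervals.
* Single-delivery EQD2 is the default; two-fraction handling assumes equal
  fractions.
* No NTCP/normal-tissue chain, no DICOM-RT input, no treatment-plan
  optimization.
* The subvolume-based alternative to EUD-based TCP is out of scope.
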