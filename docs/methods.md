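# Methods

This note documents the models, conventions and numerical choices behind
`lipid2h`, what the synthetic-study generator does and does not emulate,
and the limitations a user should know before pointing the pipeline at
real data.

## Delta arithmetic and reference frames

All δ²H values are stored in ‰ against a named reference (V-SMOW, the
co-injected reference ester, or media water). Every chained computation is
carried out on the fractional deviation δ/1000, where the α algebra is
exactly multiplicative:

* re-anchoring: δ_s/VSMOW = (1 + δ_s/ref)(1 + δ_ref/VSMOW) − 1;
* fractionation: ²ε = (1 + δ_lipid)/(1 + δ_water) − 1.

Values at or below −1000‰ are rejected (the isotope ratio would be
non-positive). The permil↔fraction conversions are exact inverses to
floating precision; unit tests hold round trips to 1e-12 and chained
orderings to 1e-9 on the ‰ scale.

## Hydrogen accounting

A mono-carboxylic fatty acid CnH(2n−2d)O₂ carries 2n−2d hydrogens; only
the carboxyl O–H is treated as exchangeable (standard CSIA practice), so
the free acid has 2n−2d−1 non-exchangeable H and its methyl ester that
plus three. Branching relocates hydrogen but never changes counts; each
double bond removes exactly two. Poly-carboxylic standards (phthalic acid)
lose one exchangeable H and gain three methyl H per acid group.

Branched-chain primers: odd anteiso chains start from 2-methylbutyryl-CoA
(isoleucine-derived, 9 H), odd iso chains from isovaleryl-CoA (leucine,
9 H), even iso chains from isobutyryl-CoA (valine, 7 H), straight chains
from acetyl-CoA (3 H). For chains too short or too unsaturated to retain
the full complement, the primer count is capped at the molecule's
non-exchangeable H. For anteiso-C17:0 the primer fraction is 9/33 ≈ 27.3%
of the free acid's non-exchangeable H and exactly 9/36 = 25% on the
methyl-ester basis; because the published "roughly 25%" figure matches the
ester basis while inference about the biosynthetic pool belongs on the
free-acid basis, the primer mass-balance operation defaults to
`basis="free_acid"` and reports both fractions.

## Methyl calibration and mass-balance correction

The methyl-hydrogen δ²H of the derivatization methanol is estimated from
each co-processed standard as δ_Me = (n_FAME·δ_meas − n_FA·δ_known)/3·k
(k acid groups) and combined across standards as the unweighted mean; a
spread above 20‰ raises a warning but does not abort, since the analyst
may legitimately proceed with a noisy session. Note the ×(n_FAME/3) error
leverage: with 5.5‰ instrument noise and six pseudoreplicates per
standard, per-standard δ_Me estimates scatter by ~20‰, so the spread
warning fires in roughly half of realistic sessions — it flags leverage,
not necessarily a bad calibration. The correction
δ_FA = (n_FAME·δ_FAME − 3·δ_Me)/n_FA is the exact inverse of the forward
mass balance (round-trip tested to 1e-12).

Because δ_Me is shared by every corrected value in a session, its
uncertainty is fully correlated across compounds. The pipeline therefore
carries it separately from the per-compound measurement SEM: in the pool
average it combines linearly under the pool weights (Σwᵢcᵢ) rather than in
quadrature, and per-compound SEMs add it back in quadrature for reporting.
Collapsing it into the independent part would understate the ε_total SEM
by roughly a factor of two at study scale.

## QC, replication and error model

* **Bracketing rule:** a sample injection is kept only when its nearest
  preceding and following standard-mix injections both have RMS ≤ 7‰
  (default) against the known 8-component mix; edge samples without both
  brackets are discarded. The passing set is monotone in the threshold.
* **Pseudoreplicates:** repeated injections of one extract are averaged;
  SEM = max(sd/√n, RMS_session/√n), where RMS_session is pooled over the
  sequence's standard-mix injections (falling back to the long-term 5.5‰
  figure). The floor stops a handful of coincidentally tight replicates
  from claiming better-than-instrument precision.
* **Biological replicates:** per-compound free-acid δ values are averaged
  across extracts with SEM = max(propagated, between-replicate scatter).
* **Methyl calibration** uses every standard injection in the sequence
  rather than only bracket-passing ones: it is a session-level constant
  estimated from many replicates, and the bracketing rule is a per-sample
  discard criterion.
* All propagation is first-order Taylor.

## Pool fractionation

δ²H_total is the weighted mean of per-lipid δ²H with weights
abundance × non-exchangeable H per molecule (default, `"hydrogen"`): this
is the mass-balance-exact pool value, equal to laying out every
non-exchangeable hydrogen atom and averaging (the unit tests check
precisely that enumeration). A `"abundance"` mode (weights = relative
abundance only) is provided because pool averages are sometimes quoted per
molecule rather than per hydrogen; at this study's chain-length range the
two differ by well under 1‰. Compounds without a measured δ are excluded
from the pool and logged. ²ε_total then follows from the α formula against
media water.

## Growth model

Phases are fit with the Zwietering reparameterization of the logistic
applied to OD directly,

    OD(t) = OD₀ + A / (1 + exp(4μ(λ − t)/A + 2)),

so A is the OD rise of the phase (dimensionless OD units), μ the maximum
slope (OD/h), and λ the lag time (h, tangent intercept). Initialization
takes A from the OD range, μ from the steepest discrete slope and λ from
that tangent's baseline intercept; five multi-starts jitter (μ, λ) by
×{0.5, 0.75, 1, 1.5, 2}, with bounds keeping A, μ positive. A flat curve
or all-start non-convergence raises an error carrying the best attempt.

**Diauxie detection.** The OD series is smoothed (centered 3-point median,
then 3-point mean) and differentiated. In this parameterization each
phase's derivative peaks at its μ, so a diauxie is a rise–dip–rise: a
second phase is declared when the derivative falls below 10% of its
running maximum and later re-exceeds 50% of that maximum; the split goes
at the intervening derivative minimum, and the two windows are disjoint.
The derivative of *log* OD was considered and rejected: because the second
phase grows on top of the first phase's biomass, its log-derivative peak
is only ~0.2–0.3 × (μ₂/μ₁) of the first phase's, so no fixed re-exceed
threshold can fire on realistic diauxic curves. A zero-length plateau
(phases abutting) is not detectable and collapses to one window — a stated
limitation. Curves need ≥8 points for two-phase detection.

**Weighted average rate.** μ_avg = Σ μ_k·ΔOD_k / Σ ΔOD_k, with ΔOD taken
as the fitted asymptote rise A of each phase (noise-robust, unlike raw
endpoint differences). "Biomass produced" is read as the OD increment, not
integrated OD. μ_avg is invariant to time shifts; uniform OD rescaling
rescales μ_avg proportionally (the weights are scale-free) — the natural
equivariance for a rate expressed in OD/h.

## Study-level statistics

The correlation screen is plain Pearson r over strain × condition cells,
excluding zero-variance columns; it is descriptive, with optional
Benjamini–Hochberg-adjusted p-values at 5% FDR. The growth-rate–
fractionation relationship is fit with three candidate shapes — linear
ε = a + bμ, exponential decay ε = ε∞ + c·e^(−kμ), hyperbolic
ε = ε∞ + c/(K + μ) — compared by AICc (small n); fits within ΔAICc < 2 are
reported as indistinguishable rather than declaring a winner. Kovats
retention indices use the linear temperature-programmed convention
(RI = 100n + 100·(rt − t_n)/(t_{n+1} − t_n)), appropriate for a ramped GC
program; the logarithmic isothermal form is not offered.

## Synthetic-study generator

The generator emulates the study's replication and measurement structure:
15 strain × condition cells, 2 biological × 3–6 pseudoreplicate
injections, bracketing standard-mix injections every ≤5 samples, an alkane
ladder, co-processed methyl standards (6 injections each), Gaussian
measurement noise of σ = 5.5‰ on δ (the session RMS), and 2% relative
lognormal noise on peak areas. Per-cell true fractionations are drawn
inside the study-scale envelope ε_total ∈ [−175, −55]‰ and rates inside
μ ∈ [0.007, 0.172] OD/h; with `ordering_flags` on, per-compound offsets
enforce the observed isotopic ordering (C16:1 below C16:0, saturated
anteiso below straight homologs, iso-C18:0 highest). Mutant cells on
malate or fumarate get two-phase OD curves (second-phase μ drawn at
0.65–0.95 of the first, separated by a plateau); OD curves are noise-free
by default (replicate OD scatter in such experiments is typically smaller
than plot symbols), with optional multiplicative noise. Media water δ²H
defaults to −45 ± 3‰, a typical mid-continental laboratory water; the
methanol methyl truth is −185‰ (strongly ²H-depleted, as petrochemical
methanol is); the reference ester is −179.3‰ — all arbitrary but
physically plausible session constants.

What it does **not** emulate: chromatographic peak shape and integration,
co-elution, H₃⁺-factor drift (input δ are taken as instrument-corrected;
the daily H₃ factor rides along as metadata only), memory/linearity
effects, between-day calibration drift beyond the bracketing structure,
or any coupling between growth rate and fractionation (per-cell truths are
independent draws). Passing recovery tests therefore demonstrate that the
reduction arithmetic, QC logic and error model are self-consistent — not
that instrument-side systematics are handled.

Determinism: each output file uses its own RNG stream spawned from the
master seed; the same seed reproduces every file byte-for-byte.

## Problem sizes used in the checks

Recovery checks run the full 15-cell study per seed: noise-free recovery
asserts per-lipid δ and ε_total to 1e-9 ‰; the statistical check runs 100
seeded studies (~1500 reduced cells) and requires |ε_total − truth| <
3×SEM in ≥99% of cells; growth recovery spans μ over the full study range
with 48–60 points per curve. The whole suite runs in about a minute on
one core.

## Known limitations

* The bracketing rule with σ = 5.5‰ noise sits close to its own 7‰ gate;
  occasionally a whole cell loses all its injections to failed brackets
  (the reduced table then has fewer than 15 cells) — the behavior of the
  discard rule, not a bug.
* The elongation-hydrogen proxy in the primer inference (the measured
  straight-chain homolog of matching chain class) is an approximation;
  desaturase and elongation isotope effects are not modeled.
* `GrowthFit` reports no per-phase parameter covariance; SEMs on μ_avg
  come from biological replication only.
* Fermentation cells are identified by sulfate_mM = 0; media chemistry is
  otherwise not represented.
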