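# Methods

This note documents the science and the engineering choices behind
`hcqpbpk`: what is modelled, which parameters matter, what the synthetic data
do and do not emulate, and where the design was genuinely open.

## Scope and strategy

The package re-implements, in open code, a whole-body PBPK analysis of
hydroxychloroquine (HCQ): healthy-adult IV and oral simulations qualified
against published NCA values via observed/predicted 2-fold ratios, then
extrapolated to liver cirrhosis (Child–Pugh A/B/C) and CKD (moderate/severe)
by physiology scaling. The original analysis was performed in a proprietary
simulator whose physiology database and partition algorithm are not public;
its engine-exact outputs are therefore not bit-reproducible. The package
splits its qualification accordingly:

* the **evaluation layer** (R ratios, 2-fold verdicts, column means, percent
  changes) is exact arithmetic on published tables and is reproduced to
  printed precision (modulo documented inconsistencies in the source table);
* the **simulation engine** is held to physics: mass balance, dose
  proportionality, closed-form limits, equilibrium partitioning, and
  direction/magnitude-class agreement of disease effects.

## Physiology

Reference adults (`data/reference_physiology.yaml`) are ICRP-style composites
(volumes in L, cardiac output 360/330 L/h for the 73 kg male / 60 kg female,
hematocrit 0.45/0.40, GFR 110 mL/min/1.73 m², gastric emptying 15 min, small
intestinal transit 210 min). Organ blood flows are fractions of cardiac
output summing to one; the hepatic artery carries 6.5% and the portal organs
(gut 15%, spleen 3%) drain through the liver, so total hepatic flow QH is
about 24.5% of cardiac output (≈ 86 L/h for the reference female used in the
study demographics).

Body size scales volumes and flows linearly with weight (allometric exponent
1.0, configurable); GFR and hematocrit are size-invariant. Virtual
populations perturb organ volumes, flows (CV 0.20) and hematocrit (CV 0.05)
with independent mean-one log-normal multipliers; weight is log-normal around
the mid study range. After perturbation cardiac output is *redefined* as the
sum of organ flows, keeping flow conservation exact by construction. The
female count is `round(n × female_fraction)`; all sampling is driven by one
`numpy` generator per population seed, so populations are bit-reproducible.

The study conditions follow the source demographics: 100 virtual adults,
60% female, ages 19–27, weights 55–68 kg, single doses of 155/310 mg base
(IV infusion over 30 min) and 155 mg base orally (200 mg sulfate = 155 mg
base, conversion factor 0.775).

## Drug model and partitioning

The drug record (`data/hcq.yaml`) mirrors the published parameter table:
MW 335.87 g/mol, logP 2.4 (an optimised value, treated as fixed), pKa
9.67/8.27 (diprotic base), fu 0.48 (α-1 acid glycoprotein), B:P 7.2,
solubility 5 mg/mL at pH 7.2 (treated as non-limiting — dissolution kinetics,
not solubility, rate-limit absorption at these doses), Peff 1.06×10⁻⁵ cm/min,
renal plasma clearance 12.7 L/h.

Partitioning uses the Rodgers–Rowland composition scheme for ionised bases.
For HCQ both pKas exceed intracellular pH, so the acidic-phospholipid (AP)
term dominates; its association constant is calibrated from the blood-cell
partition coefficient implied by the measured B:P at the reference hematocrit
(Kpu_BC ≈ 31), which makes the scheme reproduce B:P exactly and anchors the
large tissue Kp values (muscle ≈ 117, liver ≈ 345 tissue:plasma) that give
HCQ its very large distribution volume. Consequences worth knowing:

* lean, AP-rich organs out-partition adipose (Kp_adipose ≈ 30 < Kp_muscle),
  the expected pattern for a strongly ionised base;
* Kp is strictly increasing in logP only where neutral lipid actually drives
  partitioning (adipose, skin, brain); electrostatic organs track the fixed
  measured B:P and are insensitive to logP (the calibrated AP constant
  absorbs the change);
* the vegetable-oil correction for adipose is available but off by default,
  so the neutral-solute limit (logP 0, fu 1) gives water-like Kp ≈ 1
  everywhere.

Absolute Kp values will differ from the proprietary "standard" algorithm;
this is expected and is why engine acceptance is property-based.

In disease, fu rises as `fu/binding_protein_scalar` (AGP falls in cirrhosis)
and B:P is recomputed from the cell-partitioning identity
`B:P = (1−Hct) + Hct·Kpu_BC·fu` with the healthy-calibrated Kpu_BC, so
anemia (lower hematocrit) lowers whole-blood concentrations mechanistically.

## Clearance

Hepatic intrinsic clearance is back-calculated from hepatic blood clearance
CLH with the well-stirred model. CLH is not printed in the source material;
the default 4.0 L/h derives from total HCQ blood clearance ≈ 5.76 L/h
(96 mL/min, the primary IV literature) minus renal blood clearance
12.7/7.2 ≈ 1.76 L/h. Two algebraic forms of the inversion are exposed; the
default follows the published formula verbatim (`fuB·QH − CLH` denominator),
with the standard form (`fuB·(QH − CLH)`) behind a flag. Both are logged by
`hcq-pbpk clearance explain`; for this low-extraction drug they differ by
about 3-fold in CLint but by < 2% in the resulting CLH, which is what the
simulation consumes.

The back-calculation is anchored at the sex-matched reference physiology so
CLint is a drug-level constant; each individual's CLint then scales with
relative liver volume and (in cirrhosis) contribution-weighted CYP activity.
CYP contributions (2D6 0.45 / 3A4 0.35 / 2C8 0.20) and abundances
(137/24/8 pmol per mg microsomal protein, MPPGL 40 mg/g) are editable
defaults with provenance comments; the published per-enzyme in-vitro values
are carried in the drug record as reference outputs only, because they
depend on the unpublished abundances of the original software. What the
tests pin is the conservation property: apportionment re-aggregates to
CLint exactly.

Renal plasma clearance scales proportionally with GFR and converts to blood
clearance through B:P wherever it enters the ODE sink. All plasma↔blood
conversions use `CL_blood = CL_plasma/(B:P)`.

## ODE engine

Perfusion-limited mass balances per organ; lung in series; portal chain
gut/spleen → liver; elimination on the unbound emergent venous concentration
of liver (`CLint·fuB·C_out`) and kidney (`CLR_blood·C_out`), which reproduces
the well-stirred relation at steady state. IV dosing is a zero-order infusion
into venous blood; oral dosing tracks undissolved formulation (Lint80
release: 80% linearly over the dissolution time after the lag; by default the
same rate continues to 100%, with a config switch to truncate at 80% — the
two differ by up to ~20% in oral AUC), stomach (first-order emptying, 1/GET),
and a single absorbing small-intestine compartment (first-order absorption
ka = Peff × smooth-cylinder area 2200 cm² × mucosal amplification / lumen
volume 350 mL; distal transit loss 1/SITT). The amplification factor
(default 240, within the anatomical villi/microvilli range) was fixed once so
that oral bioavailability ≈ 0.75, the literature value for HCQ — the same
role the manual Peff optimisation played in the source analysis. Cumulative
metabolised, excreted and transit-lost amounts are states, so mass balance is
auditable to solver precision at any time.

Integration uses `scipy.integrate.solve_ivp` (LSODA), piecewise between
dosing discontinuities (infusion end, release lag/end), rtol 1e-8 / atol
1e-10 by default; population runs relax to 1e-6/1e-9 (profile AUCs agree to
< 0.01%). The default output grid is 0–72 h at 0.1 h (0.5 h in population
runs); a long horizon (1000 h+) is used for conservation checks.

## Disease extrapolation

Stage scalers (`data/disease_scalers.yaml`) are editable defaults in the
spirit of the staged hepatic-impairment physiologies in the clinical
pharmacology literature: Child–Pugh A/B/C reduce splanchnic (hence hepatic)
flow to 0.60/0.40/0.25, liver volume to 0.90/0.80/0.67, CYP3A4 activity to
0.60/0.40/0.25 (2C8, 2D6 less), AGP to 0.88/0.75/0.50, hematocrit and GFR
moderately, and peripheral perfusion mildly. CKD overrides GFR to 45/20
mL/min/1.73 m², lowers hematocrit (renal anemia) and prolongs gastric
emptying and intestinal transit. Only the *direction* of these tables is
load-bearing in the tests (monotone severity), as the magnitudes are
literature defaults, not printed model inputs.

Mechanistically, the cirrhosis exposure increase in this engine comes from
three reinforcing effects: reduced CYP activity and liver volume (lower
CLint), reduced hepatic and peripheral perfusion (slower tissue uptake, so
blood concentrations stay higher over the 72 h window), and AGP loss (higher
fu shifts drug into red cells, raising whole-blood levels). The simulated
100-subject medians increase monotonically (healthy→CP-C roughly +18/+32/+42%
IV) — the same direction and ordering as the published +33.5/+53.8/+73.1%,
with smaller magnitude since the scaler tables and partition scheme are not
the proprietary ones. CKD changes are small (within ±10%), matching the
published −2.4/−4.3% conclusions that renal impairment does not meaningfully
alter HCQ exposure.

## NCA and qualification

AUC0-t by linear trapezoid on the sampled grid; terminal rate by log-linear
regression on the last k ≥ 3 positive samples (k configurable); AUC0-inf =
AUC0-t + C_last/λz; CL = Dose/AUC0-inf (Dose/AUC0-t is inconsistent with the
published observed CL values for these truncated designs). A non-positive
terminal slope flags the result rather than raising. R = observed/predicted
at full precision, displayed at 2 d.p. (round half up); the 2-fold rule is
boundary-inclusive. VPC envelopes use pointwise mean/min/max and 5th–95th
percentiles with the linear-interpolation (type-7) percentile definition.
Population medians carry a seeded percentile-bootstrap 95% CI (1000
resamples) — the source analyses name no CI method; note that the percentile
bootstrap of a median needs large samples to reach nominal coverage (the
package's coverage test uses 10 000 draws, where empirical coverage is ~94%).

Three cells of the published evaluation table print R ratios inconsistent
with their own observed/predicted columns (two week-4 oral CL cells print
0.50 where the columns give 0.39–0.40, and the IV 310 mg CL cell prints 0.60
vs 0.589); the tests assert the frozen recomputed values for those cells and
printed-precision agreement for the other 33. Similarly, one published
summary mean (IV observed 1857.45) differs from its own column mean
(1857.845); the recomputed value is asserted. The published summary means
labelled as AUC0-t are numerically the Cmax-column means of the evaluation
table, and are implemented as such.

## Synthetic data

The pseudo-observed generator replaces the unavailable digitised clinical
curves. It emulates: the eight study designs (routes, doses incl. salt→base
conversion, 30 min infusions, demographics), sparse clinical sampling grids
(dense early, out to 72 h IV / 120 h oral), biological parameter variability
(log-normal multipliers on intrinsic and renal clearance and on logP), and
residual digitisation/assay noise (proportional, default CV 15%, plus
optional additive; unbiased on the concentration scale). It does **not**
emulate: the actual 1988–2012 concentration values, multiple-dose designs
(the week-4 oral profiles are approximated as independent single doses),
between-study assay differences, or model misspecification — so passing
recovery tests demonstrate pipeline self-consistency (simulate → corrupt →
NCA → ratio recovers truth within 2-fold in ≥ 95% of replicates), not
clinical predictive accuracy.

The development/verification split (1 IV + 2 oral vs 2 IV + 3 oral) is by
registry order and configurable, as the source does not identify the
development studies beyond route counts.

## Numerical choices and degenerate inputs

* Flow conservation is enforced to 1e-6 relative after every transformation.
* `fuB` and disease-adjusted fu are capped at 1.
* Back-calculation raises on a non-positive denominator ("hepatic clearance
  exceeds unbound hepatic flow capacity") rather than returning a negative
  CLint; the synthetic generator therefore perturbs a forward-direction
  CLint multiplier, which is admissible for any positive value.
* Tiny negative solver excursions (|c| < 1e-9 ng/mL) are clipped to zero.
* Ratio display rounds half-up to 2 d.p.; the source table mixes rounding
  and truncation, so exact-match tests use only rounding-robust cells.
* Problem sizes: population runs use 100 subjects per stage (the study
  condition); engine property checks use the grids stated above; the
  bootstrap coverage check uses 200 replicates of 10 000 draws × 1000
  resamples; synthetic recovery uses 200 seeded replicates.

## Known limitations

* Perfusion-limited distribution everywhere; no lysosomal trapping or
  permeability-limited deep compartments, although HCQ is known for both —
  the calibrated AP partitioning absorbs much of this phenomenologically.
* Single-dose regimens only; the published week-4 oral observations imply
  repeat dosing that the source analysis does not describe.
* No metabolite kinetics, enzyme ontogeny/polymorphism, or DDI scaling.
* Disease scalers are literature-style defaults, not fitted quantities;
  disease predictions inherit the source limitation that no clinical HCQ
  data exist in cirrhosis/CKD to verify against.
* A single reference population is used for all studies, including the
  Chinese cohort of the 2012 study.
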