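# Methods

`owlstrike` reimplements, as a tested pipeline, the chain of computations
that turns raw biologger output from a hunting barn owl — 50 Hz tri-axial
accelerometry plus 1 Hz GPS — into behavioural labels, landing
ground-reaction forces, hunting strategies and outcomes, and the
population-level statistics built on them. Because the field dataset is
not reproducible at a desk, the package ships a ground-truthed
synthetic-night generator; every downstream stage is validated against
the generator's known event schedule.

## Signal model

The accelerometer reports specific force in units of g along the heave
(dorsoventral), surge (anteroposterior) and sway (lateral) body axes. The
gravitational ("static") component per axis is estimated by a centred
moving average over 0.5 s (two wingbeat cycles at the ~4 Hz barn-owl
wingbeat frequency); the "dynamic" residual is raw − static, so
raw = static + dynamic holds exactly. Derived channels:

* **VeDBA** = √(Σ dynamic²) per sample, plus a 0.5 s smoothed copy;
* **pitch** = arcsin(static heave, clamped to ±1 g) in degrees, smoothed
  over 1 s. The arcsine argument is used directly in g, not normalised by
  the static vector norm;
* **raw vectorial sum** = √(Σ raw²); its event-window maximum is the
  landing peak. Note this includes gravity: a motionless logger reads
  1 g, so a "3 × body weight" perch landing is a vectorial-sum peak of
  3 g.

The moving average is centred rather than trailing so event times are not
phase-shifted; windows round to the nearest odd sample count and shrink
at the edges (mean over available samples only). Everything is then
summarized in 1 s intervals (mean pitch, max VeDBA, mean smoothed VeDBA,
max vectorial sum); Δ features are first differences between consecutive
1 s rows. g₀ = 9.81 m/s² throughout.

## Behavioural classification

Boolean rules on the per-second features, all thresholds in one
configuration block (`RuleThresholds`):

| event | rule (defaults) |
|---|---|
| take-off | Δpitch ≤ −10° (standing → horizontal) AND max VeDBA > 1 g |
| travelling flight | smoothed VeDBA > 0.1 g AND pitch < 30° |
| landing | Δpitch > +10° AND max VeDBA > 1 g AND the previous second is flight |
| strike vs perch | strike iff Δpitch > 6° AND ΔVeDBA > 1.3 g, else perch |
| self-feeding | ≥ 3 peaks in the heave–surge dynamic norm, each with VeDBA in (0.2, 0.9) g, inter-peak interval CV ≤ 0.5 |
| nest enter | Δpitch < −1.5° AND ΔVeDBA > +0.5 g, GPS within the nest radius |
| nest exit | Δpitch < +0.5° AND ΔVeDBA < −0.9 g, GPS within the nest radius |

The take-off pitch threshold is implemented as a *drop* of at least 10°:
the behaviour it encodes is the switch from an upright perch posture to a
horizontal flight posture. Labels partition time with precedence
landing > takeoff > travel > feeding/nest > stationary; events closer
than 1 s merge, keeping the strongest second. Feeding peaks are detected
on the heave–surge dynamic norm (the plane of the swallowing head-bob)
rather than full VeDBA: isotropic sensor noise spreads its energy over
three axes, so the two-axis norm keeps the noise floor below the 0.2 g
peak threshold while passing real feeding bumps essentially unchanged.
Nest-visit transients are additionally gated by the GPS fix lying within
`nest_radius` (default 30 m) of the declared nest position — the
automated stand-in for a manual check that the location matches the nest
site. The landing peak is the maximum raw vectorial sum within ±0.5 s of
the within-second spike.

## Analysis units

* **Landing force** F = peak (g) × g₀ × body mass (kg), in newtons;
  body-weight multiple = F / (m g₀). Both are linear in peak and mass.
* **Strategy**: sit-and-wait if the strike was preceded by ≤ 1.0 s of
  flight, on-the-wing if ≥ 5.0 s; anything between is excluded but
  counted, never silently dropped (closed bounds at both printed
  boundaries).
* **Outcome**: a strike succeeds iff the next hunting-relevant event is a
  self-feeding bout or a nest entry ("direct return"). Relevant events
  are another strike, feeding, nest entry, and any perch landing *away*
  from the nest. A perch landing within the nest radius does not break
  the chain: owls land on the box before slipping inside, so the arrival
  perch is part of the return. When several strikes precede one
  confirming event, the nearest preceding strike gets the credit.
* **Pre-hunt context**: the force of the most recent perch landing is
  attached to a strike only when the gap is < 90 s (the study's filter,
  corresponding to the lower tercile of perch-to-strike gaps).
* **Prey-load exclusion**: perch landings between a successful strike and
  its confirming event are flagged as loaded and excluded from all force
  analyses.
* **Flight speed**: median of per-second GPS step speeds over the 20 s
  before an on-the-wing strike (median, so single bad fixes do not
  matter). **Trips**: maximal intervals with distance(nest) > 30 m,
  durations in minutes, with attempt counts and sit-and-wait frequency
  attached.
* **Perch type**: coordinate-wise median of the GPS fixes while perched,
  then the nearest habitat feature within 2 m (point distance for poles
  and trees, boundary distance for buildings; ties break
  pole > tree > building and are logged; nothing within 2 m → unknown).

## Statistical estimators

The study-grade mixed models are replaced by fully implemented
fixed-effects analogues; repeated measures are respected through
owl-level cluster bootstraps where cluster labels are available.

* **Force ratios**: exp(mean log a − mean log b) with a percentile
  bootstrap CI (default 1000 resamples).
* **Success model**: logistic regression fitted by IRLS (deviance
  tolerance 1e-8, ≤ 100 iterations; Wald CIs from the inverse Fisher
  information). Design: z-scored pre-hunt force, strategy, sex, the
  sex × strategy interaction (sex terms only when both sexes are
  present), and force × strategy. The sex × strategy term is part of the
  final model structure; without it, pooled-sex fits are misspecified
  when baseline success differs non-additively by sex and strategy, and
  the force effect picks up the bias. Divergent coefficients (> 30 on
  the z scale) raise a `SeparationError` naming the offending predictor.
  `or_per_newton()` converts the z-scale force coefficients back to a
  per-newton odds ratio for either strategy branch.
* **Force–time trend**: penalized cubic B-spline (9 basis functions, the
  conservative basis size used for the study's smooths) of log force on
  time-to-next-hunt, second-difference penalty, penalty weight by GCV
  with a parsimony rule — the smoothest λ within 0.2% of the GCV minimum
  is chosen, so a flat signal is fitted flat instead of at a spuriously
  wiggly near-tie. The curve is mapped back to newtons, the first
  derivative taken by finite differences on a 100-point grid, and
  simultaneous 95% bands built by the max-deviation bootstrap (refit on
  resampled pairs at fixed λ; the band constant is the 95th percentile of
  the maximum standardized deviation over the grid). The decline mask
  marks grid points whose derivative band lies entirely on the
  "force falls as the hunt approaches" side — on a time-until-hunt axis
  that is a significantly *positive* slope. Groups with fewer than 50
  events warn and return no trend.

## The synthetic-night generator

The generator is first-class, tested code. A night is a sequence of
foraging trips: a commute leg to an arrival perch, then hunting attempts
drawn per trip (Poisson, mean `strike_rate` = 5, matching the nightly
effort of provisioning males at the default 8 trips), each sit-and-wait
(probability 0.2) with one or two perch hops and a ≤ 1 s pounce,
on-the-wing with 21–35 s of search flight, or "excluded" (2–4 s,
8% of attempts). Successful strikes end in ground feeding or a direct
provisioning return to the nest box (probability 0.5 each); provisioning
ends the trip. Every event writes its signature into the 50 Hz trace:

* wingbeat: 0.9 g dynamic heave sine at 4 Hz (1.5 g in the take-off
  second), chosen so travelling flight clears the 0.1 g smoothed-VeDBA
  threshold while staying under the 1 g landing spike threshold;
* landings: a 0.1 s half-sine along the instantaneous gravity direction
  whose vectorial-sum peak equals the injected peak exactly before
  noise. Strike peaks are drawn N(13, 0.5) g and perch peaks
  N(3, 0.2) g in body-weight multiples (per-sex overrides accepted).
  The perch spread is deliberately tight: with a 0.1 s spike, a perch
  peak beyond ~3.5 g would cross the fixed 1.3 g ΔVeDBA strike
  threshold, so the spread encodes the assumption that the two landing
  types are well separated in force, which is what the classifier's
  published thresholds presuppose;
* prey-loaded landings (carrying a ~25 g vole at ~300 g body mass)
  scale the perch peak by 1.08 — the mass-ratio value;
* feeding: 5–15 half-sine bumps in the heave–surge plane at a regular
  1–2 s spacing, amplitudes sized to keep per-peak VeDBA inside
  (0.2, 0.9) g;
* nest visits: a 1.1 g entry burst with a small pitch dip, 3 Hz sway
  activity inside the box, a pitch dip as the owl ducks out, and an
  abrupt return to quiet that realizes the negative ΔVeDBA exit
  signature;
* noise: additive Gaussian, 0.05 g per axis (a declared assumption —
  the logger's true noise floor is not documented); GPS jitter 1 m.

Sit-and-wait success is force-modulated: the odds fall by a factor 0.85
per newton of pre-hunt perching force above the sex-expected perch force;
on-the-wing success is force-independent. Baseline success rates are the
study's printed sex × strategy values. Sex-specific body masses are
drawn N(322, 22.6) g for females and N(281, 16.5) g for males, flight
speeds 5.47 (F) and 5.24 (M) m/s. GPS tracks are planar metres in a
local frame (an equirectangular projection handles real lon/lat);
flights move at the configured speed, so displacement/duration is exact
by construction. A schedule that cannot fit in `night_duration` raises
an error rather than truncating.

**What the generator does not emulate**: aerodynamic or biomechanical
realism beyond the signatures the classifier keys on (no glide phases,
no wind drift, no variable wingbeat frequency), terrain, weather,
prey behaviour, multi-owl interaction, or logger artefacts
(quantization, clipping, temperature drift). Passing tests therefore
demonstrate that the pipeline's rules and estimators are implemented
correctly and are mutually consistent with the published thresholds and
force levels — not that the classifier would achieve the same recall on
field data, where signatures are messier and the noise floor differs.

## Problem sizes and numerical choices

Tests run on nights of 1,500–4,500 s with 2–4 trips; the recovery suite
pools 40 dense nights of 4,000 s / 8 trips (~2,000 landings, ~1,200
attempts); the success-OR recovery refits on a 100,000-attempt
generator-level simulation, where the estimator's sampling error
(~3% on the odds-ratio scale) is small against the effect. A full
default night is 10 h — 1.8 M accelerometer samples — and runs through
generation plus the complete pipeline in a few seconds. Bootstrap sizes
default to 500–1000 for CIs and 100–200 for simultaneous bands.
Degenerate inputs are explicit: empty series, non-uniform sampling,
non-positive masses and forces, single-class outcomes, and zero-variance
predictors all raise typed errors.

## Known limitations

* Random effects (bird ID, night ID) are replaced by cluster bootstraps;
  exact replication of the study's lme4/mgcv output is out of scope.
* The trend band approximates posterior-simulation simultaneous
  intervals by a bootstrap max-deviation construction.
* Outcome inference is logical, not photographic: on real data the
  camera-validated provisioning record would correct direct-return
  mistakes; here agreement with ground truth is ~99% under default
  noise.
* The Δ-threshold sign and lag conventions come from the published
  in-text rule set; a differently-worded appendix table can be encoded
  by editing `RuleThresholds` without touching code.
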