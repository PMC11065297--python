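# Methods

## Measurement model

An oocyte held at a micropipette mouth under constant suction creeps
into the lumen. We model the aspirated depth with a modified Zener
circuit — a standard linear solid (spring k₀ in parallel with a
spring k₁ + dashpot η₀ arm) in series with a dashpot η₁ — whose creep
response under a step force F₀ is

d(t) = (F₀/k₁)(1 − k₀/(k₀+k₁)·e^(−t/τ)) + F₀·t/η₁,  τ = η₀(k₀+k₁)/(k₀k₁).

Assumptions: the suction force is constant over the 0.5 s analysis
window (the pressure step settles faster than one frame); the zona
pellucida dominates the response and is treated as a lumped element (no
zona/cytoplasm separation, no contact mechanics of the pipette mouth);
deformations stay in the linear-viscoelastic range. The form above is
the unique reading of the creep solution consistent with a positive
instantaneous jump d(0) = F₀/(k₀+k₁), monotone creep under constant
suction, and the stated τ. The force is F₀ = p·6894.757·π(D/2)², with p
the suction magnitude in p.s.i. and D the lumen diameter in meters.
Internally everything is SI; depths are reported in µm.

Identifiability: scaling F₀ together with all four parameters leaves
d(t) unchanged, so F₀ is computed from the configured suction (or the
mean logged suction during the clip, when a pressure trace is supplied)
and held fixed during fitting. η₁ enters only through the linear drift
F₀t/η₁ and is the weakest-identified parameter over a 0.5 s window.

## Fitting

`fit_zener` minimises Σ(dᵢ − d(tᵢ))² (µm²) over log-parameters with
scipy's BFGS (finite-difference gradients), which enforces positivity by
construction; a second BFGS pass from the first solution polishes
finite-difference stalls, and the result is clamped to the box
[1e−6, 1e3] on each SI parameter. Initialisation: k₀ = k₁ from the
observed jump (k₀+k₁ = F₀/d(0), split equally), η₀ from τ ≈ window/3,
η₁ from the terminal slope. Convergence is declared on the optimizer's
own success flag or a gradient norm ≤ 1e−3·(1+SSE) — BFGS routinely
exits with a "precision loss" status at the optimum when gradients are
finite-differenced. The returned SSE never exceeds the SSE at the
initialisation; a flat zero curve raises a degenerate-fit error rather
than returning arbitrary parameters.

## Synthetic data

The generator emulates the study conditions: 70 fps, 0.5 s window
(36 samples at t = k/70), −0.1 p.s.i. suction, 50 µm pipette, ~110 µm
oocyte with a 15 µm zona. Tracking noise is i.i.d. Gaussian on depth
with sd 0.2 µm (≈ sub-pixel tracking error; real tracking error is
likely correlated frame-to-frame, which this does not model).

Mechanical parameters are log-normal per oocyte with medians
k₀ = k₁ = 0.08 N/m, η₀ = 0.0024 N·s/m, η₁ = 0.25 N·s/m and log-sd 0.25
(~25% biological CV). These were chosen, before any downstream tuning,
to satisfy two a-priori constraints: simulated curves span roughly
5–20 µm over the window (pipette-scale plausibility: jump 8.5 µm,
d(0.5 s) ≈ 19.6 µm at the medians), and the parameters are identifiable
from 36 noisy samples — a Cramér–Rao analysis at sd 0.2 µm shows the
relative-error floor for η₀ rises steeply once τ approaches the window
length, so the medians put τ = 60 ms, well inside it. At these
conditions the noisy-fit medians are ~1–3% for k₀/k₁, ~3–4% for η₀ and
~5–10% for η₁ (the documented η₁ tolerance is 15%).

Cohorts are patient-structured: ages uniform on 21–45, ≥11 oocytes per
patient (the count doubles as the MII count), oocytes split ~50/50 into
measured/control arms within each patient, and two clinics (a day-3 and
a blastocyst-culture site, 46:22 patient ratio). A latent quality bit
Q ~ Bernoulli(usable_fraction = 0.40) drives both the mechanics (all
four parameter medians multiplied by `class_effect` when Q = 1; the
usable class is modelled as uniformly stiffer/more viscous) and the
outcome chain: fertilized ~ Bernoulli(0.77) independent of Q by default
(switchable), usable = fertilized ∧ Q, blastocyst = usable ∨
(fertilized ∧ Bernoulli(0.25)), day-3 grade A ~ Bernoulli(0.45) given
fertilization. The hierarchy usable ⇒ blastocyst ⇒ fertilized holds by
construction. About 2.8% of measured oocytes are flagged as
poor-video-quality exclusions. Because fertilization is independent of
mechanics, all-oocyte classification has an irreducible-error ceiling
(a usable-quality oocyte that happens not to fertilize is labelled
negative); the signal-recovery calibration is therefore run on the
fertilized-only dataset, where the label equals Q. What passing these
calibrations shows is that the pipeline recovers signal it is fed and
invents none under the null — not that real oocyte mechanics are this
cleanly log-normal or this strongly separated.

The renderer draws each frame from geometry (bright zona annulus,
cytoplasm disk, horizontal pipette walls, aspirated tongue) plus
Gaussian pixel noise, with the tongue tip at the resting zona thickness
plus the curve's depth, rounded to the nearest pixel at 0.5 µm/px. It
emulates contrast and geometry, not microscopy optics: no point-spread
blur, debris, illumination gradients or focus drift, so tracking
accuracy on renders is an upper bound on real-video performance.

## Tracking conventions

Pixel coordinates are 0-based; the pipette axis is horizontal with the
lumen opening rightward; tip positions are measured from the tip plane,
positive into the lumen. The resting tongue position approximates the
zona thickness (the "initial aspiration depth" convention), and the
curve handed to fitting is baseline-subtracted so its t = 0 value is
the elastic jump — this reconciles the initial-depth convention with
the model's d(0) = F₀/(k₀+k₁). The start frame is the one immediately
before the first frame whose tip displacement exceeds 1 px; onset
detection is done once there, and the moving clip is then taken
directly (late-creep steps fall below any per-frame threshold and must
not be re-filtered). The µm/px conversion factor is calibrated on the
known 50 µm lumen diameter, the only known-size object in frame, which
also makes µm depths independent of image resolution. Boundaries are
found automatically (adaptive intensity threshold at the frame's
mid-range; wall bands located in the far-right strip the tongue never
reaches); a manual-label CSV path (`io.read_curves`) exists for data
annotated by hand.

## Classifier

Features: {k₀, k₁, η₀, η₁, τ} (mechanical), {age, MII count}
(maternal), or both (mixed); all log2-transformed, then standardized
with mean/sd learned on training rows only. Splits assign whole
patients, greedily targeting round(0.70·n) training oocytes
(oocyte-count rounding); CV folds are patient-grouped and
count-balanced. Forward selection adds the feature whose addition
maximises mean 10-fold CV AUC of an RBF SVM, with C ∈ {0.1, 1, 10, 100}
and kernel width ∈ scale·{0.1, 1, 10} grid-searched inside the same
folds, stopping at the first non-improving addition (tolerance 1e−6);
within each fold, standardization is refit on that fold's training rows
so no artifact sees held-out labels. Decisions use the SVM's native
boundary; metrics (ACC/PPV/NPV/SEN/SPE) are kept at full precision and
rounded to whole percent only for display, with empty-denominator
ratios flagged NaN rather than zeroed. Zero-variance feature columns
are dropped with a warning (degenerate synthetic inputs would otherwise
break standardization). Fleiss' kappa comes from statsmodels, with the
all-unanimous single-category case (P̄ₑ = 1) rejected as degenerate.

## Safety statistics

2×2 tables (measured/control × outcome yes/no) are tested with
Pearson's chi-square (1 df), continuity correction off by default but
exposed and recorded. Denominators are not canonical, so reports show
both conventions: fertilization out of all injected oocytes; day-3 and
blastocyst outcomes out of fertilized oocytes (default) and out of all
oocytes. Type-I calibration uses 1000 null cohorts of 20 patients —
the test's size does not depend on cohort scale once expected counts
are adequate, and this keeps the calibration fast.

## Problem sizes and numerical choices

Default simulations run 68 patients (≈1250 oocytes) to mirror the
study's scale; calibration and test runs use 10–40-patient cohorts,
100-curve recovery batches, 50 rendered stacks and 100 label
permutations, which resolve the quantities of interest (medians,
rates within ±2–3 points) without waste. Ties in forward selection
break lexicographically on feature name; the greedy patient split
keeps at least one patient on each side; all RNG streams derive from a
single seed via numpy `SeedSequence`, making every stage reproducible
bit-for-bit.

## Known limitations

η₁ is weakly identified over 0.5 s and its tolerance is documented
separately. The renderer's idealised contrast means detection
thresholds are untested against low-SNR microscopy. The cohort
generator's outcome chain is deliberately simple (one latent quality
bit); phenomena like the mixed-feature-set accuracy drop can be
observed on synthetic data but their cause is not modelled. The CSV
schemas are this package's own; real clinical workbooks will need a
mapping step.
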