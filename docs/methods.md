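# Methods

This note documents the models behind `dosewise`: what is simulated, the
equations and defaults, the numerical choices, and what results on the
synthetic cohort do and do not show about real data.

## Glucose–insulin simulation model

The environment advances interstitial glucose on a 5-minute grid:

```
G_{t+1} = clip( G_t − p₁·Δt·(G_t − G_b) + k_c·C_t − S_I·A_t − k_e·x_t·Δt + ε_t , 40, 400 )
```

- `G_b` (basal glucose, default 120 mg/dL): the level glucose reverts to
  when nothing else acts; it absorbs the patient's (unmodelled) basal
  insulin, which is assumed balanced.
- `p₁` (reversion rate, 0.01 /min): first-order pull toward `G_b`, a
  ~100-minute relaxation time.
- `S_I` (insulin sensitivity, 40 mg/dL per U of activity): total glucose
  drop produced by one unit of insulin over its lifetime.
- `k_c` (carb gain, 3.5 mg/dL per g absorbed): rise per gram of
  carbohydrate appearing in plasma.
- `k_e` (exercise effect, 0.1 mg/dL per intensity-minute): linear drain
  during exercise at intensity 1–5.
- `ε_t ~ N(0, 2²)` mg/dL per step: process noise.

`A_t` (units of insulin activity expended in bin *t*) and `C_t` (grams
absorbed in bin *t*) come from triangular profiles. Insulin activity
rises to a peak at 0.4×DIA and returns to zero at DIA (240 min by
default), placing the peak at 96 min — inside the 90–120-minute
peak-action band of rapid-acting insulin analogues — and integrating
exactly to the delivered dose. Carbohydrate appears over 60 min with a
20-min peak. Per-bin amounts are exact integrals of these profiles over
the bin, so totals are conserved to float precision. A dose taken at the
start of a bin begins acting the following bin: there is no same-bin
instantaneous insulin effect.

This is deliberately a *minimal* mean-reverting model, not a
physiological ODE system (no Bergman minimal model, no UVA/Padova, no
glucagon). Every term is independently testable and carries a clinically
named parameter; that is the design goal, not fidelity to any individual
patient.

Two guard rails shape episodes: glucose is clipped to the sensor band
[40, 400] mg/dL, and an episode terminates early once glucose has sat at
the 40 mg/dL floor for 6 consecutive steps (30 min), so a policy cannot
exploit the clip as a safe harbor. Episodes default to 1500 steps
(~5.2 days), inside the 1000–2000-transition range used throughout.

## Reward family

With target range [L, H] = [70, 180] mg/dL:

- in range: +10;
- out of range: −(d/10)·1 per mg/dL distance d to the nearer boundary,
  doubled when beyond the extreme thresholds (<70 or >250 mg/dL), and
  floored at −20 so Q-value scales stay bounded;
- `asymmetric`: hypoglycemia penalties further multiplied by λ = 2
  (hypos are clinically more dangerous than equal-sized hypers);
- `stability`: −1·max(0, |ΔG/Δt| − 2) with the rate in mg/dL per minute
  over one 5-min step;
- `iob`: −1·max(0, IOB − 3 U), discouraging insulin stacking;
- `full`: all of the above.

The magnitudes beyond the +10 bonus are package choices: a linear
severity ramp of one point per 10 mg/dL realizes "penalty grows with
severity" with the fewest assumptions, and the −20 floor is twice the
bonus. The 3 U IOB cap is a plausible adult bolus ceiling; all values are
configuration.

The sensitivity grid sweeps threshold sets (70–180, 80–160, 70–140) ×
variants and reports TIR/TBR/TAR, one-step MAE/RMSE and mean episode
reward, as mean (SD) over rollout seeds shared across cells, so rows are
paired comparisons. The grid accepts either one fixed policy for every
cell or a mapping from variant to policy (e.g. policies trained under
each reward variant); with a single fixed policy the trajectories, and
hence TBR, are identical across variants by construction, so variant
comparisons are only informative with per-variant policies.

## DQN agent

Q(s, a) is approximated by a fully connected network with three ReLU
hidden layers (64, 64, 32) and a linear head over the 4 dose actions.
The state vector (length 100) concatenates the four 24-bin windows
(glucose/400, insulin/5 U, carbs/100 g, exercise/5), the two elapsed
times /720 min, hour/24 and IOB/10 U. Training regresses Q(s, a) toward
`r + γ·max_a′ Q(s′, a′)` (γ = 0.99) on uniform batches of 32 from a
5000-transition FIFO replay buffer, with Adam at 0.001 and ε-greedy
exploration decaying linearly 1.0 → 0.1 over 10 episodes. Ties at the
argmax break to the lowest action index for bit-reproducibility; all
randomness flows from one integer seed.

Two loop choices matter at this small training budget:

- **Replay ratio.** Early episodes explore near-uniformly, stack insulin,
  and hit the safety termination within ~25 steps, so the experience
  stream is short; each environment step therefore triggers 8 replay
  updates (`updates_per_step`), a standard data-efficiency lever, to
  extract enough gradient signal from the ~10-episode run.
- **Target network.** Off by default (the baseline algorithm bootstraps
  from the online network); soft updates with τ = 0.005 are available via
  `soft_target_tau` for longer runs.

The network, Adam optimizer and training loop are implemented directly
on numpy: the model is a few thousand parameters, and this keeps the
package dependency-light and exactly reproducible.

Evaluation rolls the greedy policy (ε = 0) over paired seeds and reports
TIR/TBR/TAR, mean per-episode cumulative reward, and MAE/RMSE. The
latter are computed between consecutive readings of the simulated
trajectory (one-step persistence error): the value-based agent does not
emit an explicit glucose forecast, so these quantify trajectory
smoothness under the policy rather than predictive skill. Forecast skill
proper lives in the forecaster module.

## Forecasting arm

The supervised arm predicts glucose 30 or 60 min ahead from the
engineered features (lags at 30/45/60 min, trailing rolling mean/SD over
30/60 min, hour of day, elapsed times, plus the current reading). Any
scikit-learn-style regressor plugs into the contract; ridge regression
is the default, and a persistence regressor (predict the current
reading) is always scored alongside as the floor. Fitting uses the
time-blocked split only and refuses shuffled splits. The recurrent
baseline this arm stands in for cannot be reproduced here — its training
data sits behind a data-use agreement — so no claim is made about its
printed error values; the comparison *methodology* (same splits, same
metrics, persistence floor) is what the module preserves.

## Metrics and small-sample summaries

MAE and RMSE are computed over pairwise non-missing readings (RMSE ≥ MAE
always, by Jensen). TIR/TBR/TAR use the closed interval [70, 180] and
exclude missing readings from numerator and denominator, so the three
always sum to exactly 100%. Cross-model summaries report mean, sample SD
(n−1), and a two-sided Student-t interval with df = n−1; at n = 2 the
quantile t₀.₉₇₅,₁ = 12.706 produces the very wide intervals
characteristic of two-model comparisons, and this is the only interval
convention that reproduces such printed CIs from their printed means and
SDs.

## Explainability

Shapley values are estimated by permutation sampling: for each sampled
feature order, features switch one at a time from background values to
the instance's values, and the change in the background-averaged
prediction accrues to the switched feature. The estimator satisfies
efficiency exactly (per permutation, the marginals telescope) and is
checked against an exhaustive 2^d subset enumeration — which itself
satisfies efficiency, symmetry and dummy — for d ≤ 10. The attribution
target is the Q-value of the greedy action for a policy and the
predicted glucose for a forecaster: two scalar targets, one mechanism.
The default background is a fixed-seed sample of training states.

The local surrogate follows the LIME recipe: Gaussian perturbations
around the instance (per-feature scale configurable), RBF kernel weights
with width 0.75·√d on the scaled distance, and a weighted least-squares
linear fit reported with its weighted R². Vignette reports are purely
descriptive of the explanation object (top driver, sign summary, and a
flagged carbohydrate-up/exercise-down pattern when present).

## Synthetic cohort

The generator emulates the *structure* of an 8-week, 12-patient T1D
pump/CGM dataset: 5-min CGM with sensor noise (SD 2 mg/dL), per-bin
dropout (p = 0.005) plus one long gap (25–120 min) per week, occasional
above-range spikes (p = 0.001, values 410–500 to exercise clipping);
~3 meals/day anchored at 08:00/13:00/19:00 with 45-min jitter and
lognormal carbs (mean 50 g, SD 20 g); boluses from a noisy 1:10 carb
ratio (multiplicative SD 0.15, 5% omissions, 5% square boluses);
4 exercise bouts/week (20–60 min, intensity 1–5); a held basal rate with
small daily drift; heart rate as resting 62 bpm plus exercise elevation.
Patients are jittered ±25% in insulin sensitivity and ±15 mg/dL in basal
glucose, split 6/6 across the two cohort labels. Glucose itself is
produced by the simulator dynamics driven by this behavior, so meal,
insulin and exercise channels carry realistic correlations.

Deliberate divergences from real data: no near-zero erroneous CGM
readings are emitted (they would be artifacts of a specific sensor
failure mode, and the clipping stage already exercises the <40 path);
physiology channels (heart rate, GSR) are passthrough, not drivers; and
no circadian insulin-sensitivity cycle is modelled. Consequently,
passing tests demonstrate that the pipeline, agent and explanations are
*correct and internally consistent* under controlled conditions — not
that the trained policy would dose safely for a real patient. Results on
the restricted real dataset are out of scope by design.

## Numerical and degenerate-input choices

- Grid bins are half-open [t, t+5): boundary events belong to the bin
  starting there.
- Interior CGM gaps forward-fill (no future information); a leading gap
  with no past backward-fills; both are flagged `imputed`. Gaps over
  15 min are flagged `gap_excluded` and stay missing.
- Rate spikes (|ΔG| > 50 mg/dL per bin, ~3× the physiological maximum)
  are replaced by the last trusted reading; bound-clipped and replaced
  readings never become the trust reference, so an isolated spike cannot
  cascade.
- IOB decays linearly over DIA = 240 min (a common pump "active insulin"
  default, analytically checkable); square/dual boluses deliver
  uniformly over their stated duration; basal contributes rate × 5/60 U
  per bin to the same decay.
- Timelines shorter than 8 weeks split proportionally 6:1:1 with a
  logged warning; shorter than 3 bins refuse to split.
- Timestamps are timezone-naive local clock time, in the dataset's
  `dd-mm-yyyy HH:MM:SS` XML format.
- Elapsed-time features cap at 720 min for bounded network inputs.
- Problem sizes in the test suite (1–2-week patients, 10-episode
  trainings, 3 rollout seeds) are chosen as the smallest scales at which
  every check is meaningful; all are configuration, not limits of the
  implementation.

## Known limitations

- The simulator is a single-compartment linear model; it cannot exhibit
  dawn phenomenon, biphasic meal absorption, or insulin-sensitivity
  circadian rhythm.
- The 10-episode default training is an early-stopping regime: learning
  curves plateau but do not converge in the deep-RL sense; `episodes`,
  buffer capacity and `soft_target_tau` are exposed for longer runs.
- Basal insulin is carried through preprocessing and the IOB trace but
  is not an action of the agent, and the environment assumes it balanced
  into `G_b`.
- MAE/RMSE for the dosing agent are trajectory-smoothness measures, not
  forecast errors (see above); the two uses are kept in separate modules
  to avoid conflation.
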