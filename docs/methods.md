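# Methods

`cardionet` simulates closed-loop autonomic control of heart rate by a
three-level networked hierarchy — central nervous system, intrathoracic
extracardiac ganglia, and the intrinsic cardiac nervous system — and the
response of that hierarchy to recurrent myocardial infarction or unstable
angina, with or without autonomic derangement. This note records the model,
its assumptions, the parameters that matter, and the reasoning behind the
design choices that were genuinely open.

## The model

### Network

Each level holds a population of local circuit neurons (LCN, pure
interneurons) plus transducer neurons that receive one of two globally
broadcast signals: blood-flow demand `D` (the central controller output,
received by 'D' receivers) or heart rate `H` ('H' receivers). The
demand:heart-rate receiver mix is level-centric — 5:1 centrally, 1:1 at the
intrathoracic level, 1:5 at the cardiac level — and the transducer share of
each layer defines *neural diversity*: 10 % at low diversity, 50 % at high.
With 600 LCN per level (1800 total), low diversity adds ≈67 transducers per
level and high diversity 600. Integer splits use largest-remainder rounding,
ties resolved toward the demand role at the upper levels and the heart-rate
role at the cardiac level.

A separate networked parasympathetic pool (800 neurons by default) sits at
the cardiac level beside the sympathetic population. Its transducer share
follows the diversity setting, all of its transducers sense heart rate, and
its non-transducing cells (`parasym_efferent`) are the vagal postganglionic
output. Pool neurons receive peer and descending synapses but emit none:
postganglionic motor output goes to the heart, not back into the network.
This choice is also what keeps the wiring ratios exact — cardiac neurons may
emit at most one ascending synapse, so a large emitting cardiac pool would
make the 1:1 top-down peer:adjacent ratio unattainable.

Every networked (sympathetic-branch) neuron emits `out_degree = 20` synapses
split between peer (same level) and adjacent-layer connections. The split is
set in expectation so that the *global* peer:adjacent count ratio equals
10:1 for stratified networks and 1:1 for top-down networks, with the
cardiac level's ascending cap compensated by larger descending quotas at the
two upper levels. Peer targets are uniform over the whole level (either
branch); descending targets are uniform over the level below; ascending
targets over the level above, at most one per neuron. Weights start uniform
on [0, 0.15]. All randomness flows through one seeded PCG64 generator, so a
configuration plus seed reproduces a network bitwise.

### Neuron dynamics

Neurons are leaky logistic rate units advanced by explicit Euler steps
(`dt = 0.5 s`, activity time constant `tau_a = 2 s`):

    a_i <- a_i + (dt/tau_a) * ( sigma(g_i * u_i + b_i) - a_i ),
    u_i  = sum_j w_ij a_j + s_i^D D + s_i^H H + ischemic drive.

`g_i` is a slowly adapting intrinsic gain, `b_i` a fixed role bias. The
logistic squashing keeps every activity in (0, 1) for any input, which is the
global boundedness the stability claims rest on. Within one composite step
the activity, Hebbian and homeostatic updates all read the pre-step state
(synchronous, Jacobi-style), so results do not depend on neuron enumeration
order.

Three plasticity channels operate on slow time scales:

* **Hebbian** (soft-bounded): `w += dt * eta * a_pre * a_post * (w_max − w)`,
  `eta = 2e-4 /s`, `w_max = 0.15`. Growth-only, bounded, and the carrier of
  episode memory: populations that are jointly hyperactive during a pathology
  episode keep strengthened synapses afterwards.
* **Synaptic downscaling**: incoming weights of a neuron whose running-mean
  activity exceeds the target (0.45) shrink multiplicatively at
  `1.8e-3 /s` per unit of excess. This one-sided normalization balances the
  one-way Hebbian growth at the operating point, and produces the gradual
  decline of sympathetic tone across angina episodes. It is deliberately
  one-sided so it cannot erase populations that sit below target *by design*
  (the sensory transducers).
* **Intrinsic gain homeostasis**: `g += dt * 1e-4 * (target − abar)`,
  clipped to [0.6, 1.6]; a slow, bounded trim of excitability.

The running mean `abar` is an exponential moving average with a 100-s time
constant. Frozen neurons hold their activity exactly (and keep transmitting
it); dead neurons are silent forever and their synapses are inert.

### Closed loop

The heart is a first-order responder with constant ejection fraction, so
cardiac output is proportional to heart rate and heart rate is the
controlled variable:

    H <- H + (dt/tau_H) * ( −H + H0 + c_s*S − c_p*(alpha*P_net + (1−alpha)*P_dir) )

with `tau_H = 10 s`, intrinsic rate `H0 = 0.5695` (the intrinsic sinus rate sits
above the setpoint and resting vagal tone restrains it), sympathetic coupling
`c_s = 1`, parasympathetic coupling `c_p = 4` and a mix `alpha = 0.25`
weighted toward the direct vagal pathway. `S` and `P_net` are the mean
activities of the surviving cardiac sympathetic population and of the
surviving parasympathetic pool.

The central controller is the standard PI rule on the delayed tracking error
(`K = 2`, reset time `Ti = 1 s`, delay `L = 2` steps = 1 s):

    D(n) = K * ( e(n) + (1/Ti) * sum_{j<=n} e(j)*dt ),  e(j) = H*(j) − H(j−L).

`D` is broadcast identically to every demand transducer and recorded as the
central-drive channel. Two numerical guards matter. First, the integral is
conditionally clamped so the demand signal stays in [−1, 1.5] (anti-windup):
during the 0.25-setpoint initialization the low-diversity network has almost
no downward demand authority, and an unclamped integral winds up so far that
it poisons the 500–2500 s benchmark window. Second, before the delay buffer
fills, the earliest available heart-rate sample stands in.

The direct (non-networked) vagal pathway is a first-order unit
(`tau_p = 5 s`) relaxing toward a logistic function of the *signed* delayed
error with gain 17 and a baseline bias placing its quiescent tone at 0.1. The
signed form (rather than a rectified overshoot-only form) is essential: the
demand receptors saturate above `D ≈ 0.5`, so raising the setpoint from 0.3
to 0.35 during a demand challenge is physically realized mostly by vagal
withdrawal, exactly as in the textbook picture of rapid heart-rate control.

### Pathology

Three episodes follow the canonical timeline (onsets 2500/6000/9500 s,
recoveries +1000 s, 500-s demand challenges +1000 s after recovery, aftermath
re-initialization at 13 000 s, end at 18 000 s; setpoint 0.25 during 0–500 s,
0.35 during challenges, 0.3 otherwise). At each onset, a fresh sample of
approximately 15 % of the cardiac, 4 % of the intrathoracic and 2.5 % of the
central population is drawn without replacement from the survivors —
`floor(fraction × alive pool)` per level per included population, where the
local-circuit switch covers LCN plus the non-transducing pool cells, and the
transducer switch covers both receiver types. Under infarction the affected
neurons die; under unstable angina they freeze at their pre-onset activity
(outside central control and network influence, but still transmitting) and
thaw at recovery. Either fate can be overridden per population to express
the mixed scenarios (for example LCN stressed while the sensory transducers
die). An ischemic excess drive (amplitude 2.0) is added to the input of every
alive unfrozen cardiac neuron for the duration of each ischemic interval.

Autonomic derangement, when enabled, multiplies every surviving heart-rate
transducer's feedback sensitivity by 0.75 and every demand transducer's
demand sensitivity by 1.25 per episode, ramped linearly across the ischemic
interval and compounding across episodes (a step-at-onset variant and an
affected-only variant are configurable). At the aftermath, every surviving
transducer's sensitivity is reset to the pre-pathology population mean of its
role (deterministic reset; a redraw would add nothing at these population
sizes), dead neurons stay dead, and weights and gains keep their acquired
state — the "new normal" is carried entirely by the network.

## Calibration and what the balance means

The closed loop pins a combination of the efferent tones: at tracking
equilibrium `c_s·S − c_p·(alpha·P_net + (1−alpha)·P_dir) = H* − H0`, so with
the default couplings `S ≈ (H*−H0) + P_net + P_dir`. The sympathetic tone is
therefore *not* free — it floats with the parasympathetic pool, which is why
the pool's composition matters so much. The benchmark balance
(S, P, D) ≈ (0.5, 0.1, 0.35) over 500–2500 s emerges from:

* role biases (`b_LCN = −0.25`, `b_pe = −0.35`, `b_H = −2.4`, `b_D = −7`)
  placing LCN/pool activity near 0.5 and heart-rate receivers near 0.15;
* demand sensitivity ≈ 20 (spread ±10 %) so that demand receptors are
  centered at `D = 0.35` — this makes the demand pathway's slope large enough
  that the equilibrium drive is reproducible across seeds (with weak
  coupling the equilibrium `D` is noise-dominated);
* `H0` chosen to center the equilibrium drive at the reference value 0.35;
* the vagal baseline bias fixing `P_dir = 0.1` whenever tracking is good.

High diversity replaces 40 % of each population with low-activity heart-rate
receivers, which drags both the cardiac sympathetic mean and the pool mean
down together; through the pinning relation the sympathetic tone drops by
≈ 28–30 % while heart-rate tracking is unaffected — the headline diversity
effect. The same arithmetic makes the top-down/stratified contrast in
diversity sensitivity small in this implementation (see Limitations).

The sympatho-excitation contrast between LCN-unaffected and LCN-affected
derangement scenarios is measured over the three ischemic windows. Its
mechanism here is the frozen population: frozen cells neither receive the
ischemic drive nor follow the deranged transducers, so when LCN are affected
the cardiac populations (and particularly the parasympathetic pool, through
the pinning relation) run measurably cooler than when all local circuits are
free to respond. The calibrated contrast is ≈ +4.6 % (sign stable in every
seed pair and window), smaller than the ≈ 10 % reference contrast; the loop's
equilibrium structure bounds it (see Limitations).

## Scaling choices

A default run is ≈ 2 400–4 400 neurons and 4.8×10⁴–7.2×10⁴ synapses,
36 000 steps for the full 18 000-s timeline (≈ 20–40 s on one CPU). The
acceptance script runs prelude-only and episodes-only segments where the
measured window permits it. The test suite's cross-scenario ordering checks
use reduced populations (120 LCN/level, 160-neuron pool) that preserve every
structural fraction; they behave like the full model with more sampling
noise, which the majority votes absorb. What passes on synthetic runs shows
internal consistency of the model under its stated conditions — not fidelity
to any particular animal's autonomic physiology.

## Numerical choices

Explicit Euler throughout with `dt = 0.5 s` against time constants ≥ 2 s;
activities are clipped only by the logistic itself, the heart rate at zero,
weights to [0, w_max], gains to their bounds. Non-finite activities or heart
rates abort with a diagnostic rather than propagate. Episode events fire at
the first step whose time reaches the scheduled event time (all canonical
event times are multiples of `dt`). Ties in largest-remainder rounding are deterministic.
The event log records every onset (with affected ids), recovery, and the
aftermath re-initialization.

## Known limitations

* **The derangement LCN contrast is ≈ 4.6 %, not ≈ 10 %.** At closed-loop
  equilibrium the plant pins the sympathetic tone to the parasympathetic
  tones plus a constant, so the between-scenario difference reduces to the
  frozen share of the parasympathetic pool times its activity gap; the
  frozen *sympathetic* deficit is compensated by the controller in both
  scenarios. Larger contrasts would require a controller too sluggish to
  re-equilibrate within a 1000-s episode, which would degrade the tracking
  behaviour the rest of the results depend on.
* **Top-down rigidity is marginal.** The diversity effect is dominated by
  population composition, which is wiring-independent; the peer-mediated
  amplification that should make stratified networks more diversity-sensitive
  is real but small at these weight scales, so the stratified/top-down
  contrast in diversity sensitivity is within noise.
* The exact neuron and plasticity equations of the antecedent open-loop
  model are not public; the rate unit, soft-bounded Hebbian rule and
  homeostatic channels used here are canonical substitutes calibrated to
  reproduce the reference benchmark quantities, not the original equations.
* No spiking, synaptic delays, transmitter kinetics, spatial ganglion
  geometry, arrhythmia substrate, or mortality; the heart is a first-order
  plant with constant ejection fraction and the setpoint schedule stands in
  for all baroreflex resetting.
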