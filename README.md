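# cardionet

Closed-loop simulation of **networked autonomic cardiac control** under
recurrent ischemic pathology.

Investigative neurocardiology has shown that the heart is not regulated by a
central command pipeline alone: local circuit neurons (LCN) in the
intrathoracic and intrinsic cardiac nervous systems form a genuine networked
control layer. `cardionet` is a research simulator for exploring what such a
hierarchy does when myocardial infarction or unstable angina strikes it
repeatedly — which neurons die or fall silent, how sensory transduction
becomes deranged, and what "new normal" balance of sympathetic tone, vagal
tone and central drive the network settles into afterwards. It is intended
for computational physiologists and control-minded neuroscientists who want a
reproducible, configurable desk-scale model rather than a clinical tool.

## The model in brief

A three-level hierarchy (central / intrathoracic / cardiac) of bounded
firing-rate neurons: each level holds local circuit neurons plus transducers
of the two global signals, blood-flow demand *D* and heart rate *H*
(demand:heart-rate receiver mix 5:1, 1:1, 1:5 down the hierarchy; transducer
share 10 % or 50 % per the *neural diversity* setting). Wiring is seeded and
random with a 10:1 (stratified) or 1:1 (top-down) peer-to-adjacent synapse
ratio and at most one ascending synapse per neuron. Neurons follow

    a ← a + (Δt/τ_a) · ( σ(g·u + b) − a ),   u = Σ w·a_pre + s_D·D + s_H·H + ischemic drive

with Hebbian growth, homeostatic synaptic downscaling and slow intrinsic-gain
adaptation. The heart is a first-order plant,

    H ← H + (Δt/τ_H) · ( −H + H0 + c_s·S − c_p·(α·P_net + (1−α)·P_dir) ),

driven by the mean cardiac sympathetic tone *S*, the networked
parasympathetic pool tone *P_net*, and a direct vagal pathway *P_dir*. The
central controller is the standard PI rule on the delayed tracking error,

    D(n) = K·( e(n) + (1/Ti)·Σ_{j≤n} e(j)·Δt ),   e(j) = H*(j) − H(j−L),

whose output *D* is the recorded central-drive channel. Scenarios follow the
canonical 18 000-s timeline: initialization, a pre-pathology steady state,
three episodes of infarction or angina (onset with ischemic drive and
optional accumulating autonomic derangement of transducer sensitivities,
recovery, and a mild demand challenge), then an aftermath in which transducer
sensitivities are re-initialized and the network seeks its new normal.

See `docs/methods.md` for the full model description, parameter rationale and
known limitations.

## Worked example

Run the canonical low-diversity stratified unstable-angina scenario (the
default configuration) and summarize its benchmark balance:

```python
from cardionet import (ScenarioConfig, run_timeline,
                       benchmark_balance, prelude_aftermath_summary)

record = run_timeline(ScenarioConfig(master_seed=0, record_stride=4))
prelude = benchmark_balance(record, (500, 2500))
print(f"prelude S={prelude.sympathetic:.3f}  P={prelude.parasym_direct:.3f} "
      f"D={prelude.central_drive:.3f}")
summary = prelude_aftermath_summary(record)
print(f"aftermath S={summary.aftermath.sympathetic:.3f}  "
      f"delta S={summary.deltas['sympathetic']:+.4f}  flags={summary.flags}")
```

which prints

```
prelude S=0.486  P=0.100 D=0.318
aftermath S=0.465  delta S=-0.0207  flags={'ans_derangement': 'N', 'lcn': 'S', 'sensory': 'S'}
```

— the calibrated pre-pathology benchmark balance (sympathetic tone ≈ 0.5,
direct vagal tone ≈ 0.1, central drive ≈ 0.35), and an aftermath in which the
network has *improved*: repeated angina without derangement ends with
slightly **lower** sympathetic tone, the plasticity-driven adaptation the
model is built to exhibit. Heart-rate tracking stays within 0.02 of the
setpoint throughout, which is exactly why heart rate alone is a poor monitor
of the underlying autonomic pathology.

The same interface drives the published scenario matrix
(`cardionet.scenario_matrix()`, labels `fig04`–`fig14`) covering stratified
vs top-down wiring, low vs high diversity, angina vs infarction, LCN
involvement and autonomic derangement.

## Command line

```sh
cardionet run --config src/cardionet/examples/fig08.yaml --seed 1 --out out/fig08
cardionet sweep --seeds 3 --out out/sweep
cardionet summarize out/sweep
```

`run` writes `timeseries.csv` (time, setpoint, central drive, heart rate,
sympathetic and parasympathetic tones, phase label), `summary.json`
(prelude/aftermath balances, deltas, scenario flags) and `events.jsonl` (the
pathology event log). An empty or missing config file means the default
scenario; every parameter of the model can be overridden from the YAML/JSON
document, and unknown keys are rejected.

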