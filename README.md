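# avpvk

Conductance-based single-compartment models of AVPV kisspeptin neurons
across the estrous cycle (diestrus / proestrus), together with the full
in-silico experimental workflow around them:

- **gating / neuron** — Boltzmann gating curves, sigmoid/bell time
  constants, Ohmic and GHK driving forces, a 3-state Markov transient
  Na⁺ channel, and YAML-shipped stage presets (seven voltage-gated
  conductances + leak). Leak/holding-current calibration to a −70 mV,
  1 GΩ operating point; conductance-swap construction of hybrid models.
- **protocols / simulator** — the published voltage-step families
  (total/slow/fast K⁺ activation, inactivation, rate and recovery
  protocols) and current-step (F–I) families; an ideal voltage clamp with
  exact per-segment analytic propagation and a fast fixed-step current
  clamp (Rush–Larsen gates, implicit-Euler Markov states, numba-
  accelerated with a numpy reference path). Traces serialize to
  CSV + JSON sidecars.
- **vc_analysis / cc_analysis** — scaled-template and P/N leak
  subtraction, voltage-subtraction component isolation, windowed peak
  extraction, GHK permeability conversion (analysis reversal −94 mV),
  Boltzmann and single-exponential fitting; spike detection (−10 mV peak
  criterion), F–I curves, rheobase, AP threshold (2 V/s) and amplitude,
  rebound-spike counting.
- **fitting** — seeded particle-swarm optimization of maximal
  conductances against target clamp traces (kinetics are never touched).
- **synthetic_data** — an in-silico rig: lognormal cell-to-cell
  conductance scatter, passive-property sampling within the recording
  inclusion criteria, leak and capacitive-transient artifacts, Gaussian
  noise, and calibrated TEA / 4-AP suppression conditions.
- **experiments** — orchestration: per-component clamp-panel
  reproduction, the hybrid swap suite (F–I + rebound for ten models),
  and rheobase-AP comparison, with tidy CSV/JSON outputs.

## CLI

```sh
avpv-kneuron model-show --stage diestrus
avpv-kneuron protocol list
avpv-kneuron protocol dump --name total-activation
avpv-kneuron simulate-vc --stage diestrus --protocol total-activation --out traces.csv
avpv-kneuron analyze-vc --traces traces.csv
avpv-kneuron simulate-cc --stage proestrus --out cc.csv
avpv-kneuron analyze-cc --traces cc.csv
avpv-kneuron fit-gbar --stage diestrus --target traces.csv --seed 1
avpv-kneuron synth --stage diestrus --n-cells 10 --noise 5 --seed 1 --out synth/
avpv-kneuron vc-panels --stage diestrus
avpv-kneuron swap-suite --out swap.csv
avpv-kneuron rheobase-ap
avpv-kneuron run-all --out results/
```

## Conventions

mV / ms / nS / pA / pF throughout; outward current positive. The GHK
driving force follows the printed current equation (thermal-voltage-
scaled prefactor) times the bath K⁺ concentration, with its zero pinned
at the model reversal of −92 mV; the analysis pipeline deliberately uses
the separate −94 mV constant.
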