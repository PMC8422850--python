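# Markov transient-sodium channel, shared between cycle-stage models.
gbar_nS: 68.12
E_mV: 50.0
open_exponent: 3
rates:
  alpha: {s: 65.24, k: -6.05, r: 38.40}
  beta: {s: 48.59, k: 5.09, r: 391.84}
  r1: {s: 9.52, k: -4.66, r: 1.36}
  r3: {s: 12.68, k: 3.08, r: 0.014}
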