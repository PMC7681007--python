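# Epitope-depletion simulation: target + two off-targets + inert pool,
# with a small high-affinity spike-in calibrant.
antibody_total: 6.0        # uM
species:
  - {name: target,     total: 10.7, binding_constant: 11.0}
  - {name: offtarget2, total: 0.3,  binding_constant: 0.1}
  - {name: offtarget3, total: 0.3,  binding_constant: 0.5}
  - {name: inert,      total: 0.0,  inert: true}
  - {name: calibrant,  total: 0.01, binding_constant: 80.0, spike: true}
scenario: case1            # or case2 (target converted to offtarget2)
grid: {start: 0.5, stop: 10.7, num: 41}
total_constant: 11.0       # case2: S2t = total_constant - S1t
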