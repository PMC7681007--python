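# Synthetic ground-truth experiment on a 2 x 1 Mb toy genome.
antibody_total: 6.0
species:
  - {name: target,     total: 10.7, binding_constant: 11.0}
  - {name: offtarget3, total: 0.3,  binding_constant: 0.5}
genome:
  interval_width: 10000
  sizes: {chr1: 1000000, chr2: 1000000}
distributions:
  target:     {kind: blocks, blocks: [[chr1, 0, 40], [chr2, 50, 90]]}
  offtarget3: {kind: uniform}
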