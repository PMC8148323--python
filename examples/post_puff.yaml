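# Worst-case secondhand scenario: forceful post-puff exhalation toward a
# bystander standing 1 m away in a ventilated 27 m^3 room.
puff:
  kind: post_puff

room:
  declared_ach_per_h: 0.6   # intentionally inconsistent with the 0.018 m^3/s
                            # flow (2.4 h^-1); the run manifest records the
                            # warning

dose:
  rounding: full_precision
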