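# Soft-exhalation scenario (short puff): the exhaled plume rises with the
# thermal plume and never reaches the bystander's breathing zone, so the
# secondhand doses are zero over the short exposure window.
puff:
  kind: short_puff
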