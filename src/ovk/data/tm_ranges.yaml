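# Transmembrane helix ranges of bovine rhodopsin (1-based, inclusive),
# from the crystal structure. Editable: users may substitute their own
# boundaries; in_transmembrane() reads whatever is configured here.
tm_ranges:
  - [34, 64]    # TM1
  - [71, 100]   # TM2
  - [106, 140]  # TM3
  - [150, 172]  # TM4
  - [200, 225]  # TM5
  - [246, 277]  # TM6
  - [285, 309]  # TM7
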