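spins:
- 19F
- 19F
- 1H
- 1H
- 1H
- 1H
- 1H
- 1H
shifts_ppm:
- -219.8
- -219.8
- 4.52
- 4.52
- 1.98
- 1.98
- 4.52
- 4.52
base_frequency_mhz: 500.0
j_hz:
- - 0.0
  - 4.5
  - 47.3
  - 47.3
  - 25.6
  - 25.6
  - 0.0
  - 0.0
- - 4.5
  - 0.0
  - 0.0
  - 0.0
  - 25.6
  - 25.6
  - 47.3
  - 47.3
- - 47.3
  - 0.0
  - 0.0
  - -10.1
  - 5.9
  - 5.9
  - 0.0
  - 0.0
- - 47.3
  - 0.0
  - -10.1
  - 0.0
  - 5.9
  - 5.9
  - 0.0
  - 0.0
- - 25.6
  - 25.6
  - 5.9
  - 5.9
  - 0.0
  - -14.6
  - 5.9
  - 5.9
- - 25.6
  - 25.6
  - 5.9
  - 5.9
  - -14.6
  - 0.0
  - 5.9
  - 5.9
- - 0.0
  - 47.3
  - 0.0
  - 0.0
  - 5.9
  - 5.9
  - 0.0
  - -10.1
- - 0.0
  - 47.3
  - 0.0
  - 0.0
  - 5.9
  - 5.9
  - -10.1
  - 0.0
molecule_permutations:
- - 2
  - 1
  - 7
  - 8
  - 5
  - 6
  - 3
  - 4
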