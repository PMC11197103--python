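spins:
- 19F
- 19F
- 1H
- 1H
- 1H
- 1H
- 1H
- 1H
- 1H
- 1H
- 1H
- 1H
shifts_ppm:
- -169.8
- -169.8
- 1.36
- 1.36
- 1.36
- 4.78
- 1.82
- 1.95
- 4.78
- 1.36
- 1.36
- 1.36
base_frequency_mhz: 500.0
j_hz:
- - 0.0
  - 3.2
  - 23.6
  - 23.6
  - 23.6
  - 48.6
  - 16.5
  - 28.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 3.2
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 16.5
  - 28.0
  - 48.6
  - 23.6
  - 23.6
  - 23.6
- - 23.6
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 6.2
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 23.6
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 6.2
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 23.6
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 6.2
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 48.6
  - 0.0
  - 6.2
  - 6.2
  - 6.2
  - 0.0
  - 6.8
  - 4.2
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 16.5
  - 16.5
  - 0.0
  - 0.0
  - 0.0
  - 6.8
  - 0.0
  - -14.7
  - 6.8
  - 0.0
  - 0.0
  - 0.0
- - 28.0
  - 28.0
  - 0.0
  - 0.0
  - 0.0
  - 4.2
  - -14.7
  - 0.0
  - 4.2
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 48.6
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 6.8
  - 4.2
  - 0.0
  - 6.2
  - 6.2
  - 6.2
- - 0.0
  - 23.6
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 6.2
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 23.6
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 6.2
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 23.6
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 6.2
  - 0.0
  - 0.0
  - 0.0
symmetry_groups:
- spins:
  - 3
  - 4
  - 5
  group: S3
- spins:
  - 10
  - 11
  - 12
  group: S3
molecule_permutations:
- - 2
  - 1
  - 10
  - 11
  - 12
  - 9
  - 7
  - 8
  - 6
  - 3
  - 4
  - 5
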