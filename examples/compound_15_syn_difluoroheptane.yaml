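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
- 1H
- 1H
- 1H
- 1H
shifts_ppm:
- -181.9
- -181.9
- 0.97
- 0.97
- 0.97
- 1.56
- 1.69
- 4.43
- 1.74
- 1.86
- 4.43
- 1.56
- 1.69
- 0.97
- 0.97
- 0.97
base_frequency_mhz: 500.0
j_hz:
- - 0.0
  - 2.8
  - 0.0
  - 0.0
  - 0.0
  - 17.0
  - 27.5
  - 48.9
  - 15.2
  - 31.8
  - 2.1
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 2.8
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 2.1
  - 15.2
  - 31.8
  - 48.9
  - 17.0
  - 27.5
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 7.4
  - 7.4
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 7.4
  - 7.4
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 7.4
  - 7.4
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 17.0
  - 0.0
  - 7.4
  - 7.4
  - 7.4
  - 0.0
  - -14.2
  - 6.3
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 27.5
  - 0.0
  - 7.4
  - 7.4
  - 7.4
  - -14.2
  - 0.0
  - 4.1
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 48.9
  - 2.1
  - 0.0
  - 0.0
  - 0.0
  - 6.3
  - 4.1
  - 0.0
  - 7.1
  - 3.6
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 15.2
  - 15.2
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 7.1
  - 0.0
  - -14.8
  - 7.1
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 31.8
  - 31.8
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 3.6
  - -14.8
  - 0.0
  - 3.6
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 2.1
  - 48.9
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 7.1
  - 3.6
  - 0.0
  - 6.3
  - 4.1
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 17.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 6.3
  - 0.0
  - -14.2
  - 7.4
  - 7.4
  - 7.4
- - 0.0
  - 27.5
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 4.1
  - -14.2
  - 0.0
  - 7.4
  - 7.4
  - 7.4
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 7.4
  - 7.4
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 7.4
  - 7.4
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 7.4
  - 7.4
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
  - 14
  - 15
  - 16
  group: S3
molecule_permutations:
- - 2
  - 1
  - 14
  - 15
  - 16
  - 12
  - 13
  - 11
  - 9
  - 10
  - 8
  - 6
  - 7
  - 3
  - 4
  - 5
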