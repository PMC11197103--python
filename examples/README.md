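# Spin-system file schema

Structured-text (YAML) files with 1-based spin indices:

- `spins`: ordered isotope labels (`1H`, `19F`); file order is authoritative.
- `shifts_ppm`: one chemical shift per spin, on each isotope's own ppm scale.
- `base_frequency_mhz`: the magnet's ¹H Larmor frequency.
- `j_hz`: symmetric scalar-coupling matrix with zero diagonal, either a full
  matrix (list of rows) or sparse `{entries: [[i, j, value], ...]}`.
- `symmetry_groups` (optional): sets of equivalent spins with a permutation
  group label, e.g. `{spins: [3, 4, 5], group: S3}` for a methyl rotor.
- `molecule_permutations` (optional): whole-molecule symmetry operations as
  permutation image lists, used to tie fit parameters.

The files here describe the 1,3-difluoroalkane family (1,3-difluoropropane,
the 2,4-difluoropentanes, and the 3,5-difluoroheptanes) with representative
shifts and couplings authored from the molecular topology — synthetic
stand-ins for worked examples and tests, not measured values.
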