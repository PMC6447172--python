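# Per-element van der Waals parameters (Tripos-5.2-style): R = half r_min in
# angstrom, epsilon = well depth in kcal/mol.  Combined with the probe by
# r_min_ij = R_i + R_probe and eps_ij = sqrt(eps_i * eps_probe), giving
# A_i = eps_ij * r_min_ij**12 and B_i = 2 * eps_ij * r_min_ij**6.
# Edit or replace this table to drop in an alternative force field.
probe:
  name: sp3_carbon
  R: 1.70
  epsilon: 0.107
  charge: 1.0
elements:
  H:  {R: 1.50, epsilon: 0.042}
  C:  {R: 1.70, epsilon: 0.107}
  N:  {R: 1.55, epsilon: 0.095}
  O:  {R: 1.52, epsilon: 0.116}
  F:  {R: 1.47, epsilon: 0.109}
  P:  {R: 1.80, epsilon: 0.314}
  S:  {R: 1.80, epsilon: 0.314}
  Cl: {R: 1.75, epsilon: 0.266}
  Br: {R: 1.85, epsilon: 0.434}
  I:  {R: 1.98, epsilon: 0.623}
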