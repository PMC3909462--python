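# Substituent-adjusted Karplus parameterisation for vicinal 3J(H,H)
# couplings across H-C-C-H fragments, in the generalised form
#
#   J = P1 cos^2(t) + P2 cos(t) + P3
#       + sum_i dchi_i * [P4 + P5 cos^2(xi_i t + P6 |dchi_i|)]
#
# with t the H-H dihedral in degrees, dchi_i the relative group
# electronegativity of substituent i and xi_i = +/-1 its orientation
# factor.  Coefficient sets are keyed by the number of non-hydrogen
# substituents on the coupling fragment; values are the standard
# empirical parameterisation for this equation family.  The evaluation
# engine is value-agnostic: edit or replace this file to use another
# calibration.
version: 1
coefficients:
  two_substituents:   {P1: 13.89, P2: -0.98, P3: 0.0, P4: 1.02, P5: -3.40, P6: 14.9}
  three_substituents: {P1: 13.22, P2: -0.99, P3: 0.0, P4: 0.87, P5: -2.46, P6: 19.9}
  four_substituents:  {P1: 13.24, P2: -0.91, P3: 0.0, P4: 0.53, P5: -2.41, P6: 15.5}
# relative group electronegativities (Huggins scale, H = 0)
electronegativities:
  C: 0.40
  N: 0.85
  OH: 1.26
  OR: 1.27
  O: 1.27
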