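# Compact nearest-neighbor free-energy parameters for RNA secondary
# structure at 37 C, kcal/mol.  Version 1.
#
# Stacks: key "P1.P2" where P1 = (base i, base j) of the outer pair and
# P2 = (base i+1, base j-1) of the inner pair, both written 5'-side base
# first.  Only one member of each symmetry class (P1.P2 == rev(P2).rev(P1))
# needs to be listed; the loader fills in the symmetric partner and checks
# that all 36 combinations of the six allowed pairs (WC + G:U) are covered.
#
# Loop penalties are tabulated by the number of unpaired nucleotides in the
# loop; beyond the last tabulated size they are extrapolated as
# dG(n) = dG(n_max) + 1.75 * RT * ln(n / n_max) with RT = 0.616 kcal/mol.
#
# Multiloops are affine: a (closing) + b per branch (closing pair included)
# + c per unpaired nucleotide.  Exterior bases are free.  No dangling ends,
# no coaxial stacking, no terminal-AU penalties; lonely pairs allowed.
version: 1
rt_kcal: 0.616
lxc: 1.75            # log-extrapolation prefactor (times RT)
min_hairpin: 3       # minimum unpaired nucleotides in a hairpin loop
max_interior: 30     # DP search cap on unpaired nucleotides in interior loops
duplex_init: 4.09    # bimolecular duplex initiation penalty

stacks:
  AU.AU: -0.93
  AU.UA: -1.10
  UA.AU: -1.33
  AU.CG: -2.24
  AU.GC: -2.08
  UA.CG: -2.35
  UA.GC: -2.11
  CG.CG: -3.26
  CG.GC: -3.42
  GC.CG: -2.36
  AU.GU: -0.55
  AU.UG: -1.36
  UA.GU: -1.00
  UA.UG: -1.27
  CG.GU: -1.41
  CG.UG: -2.11
  GC.GU: -1.53
  GC.UG: -2.51
  GU.GU: -0.50
  GU.UG: 0.47
  UG.GU: -0.57

hairpin:   # indexed by loop size (unpaired nt), minimum 3
  3: 5.40
  4: 5.60
  5: 5.70
  6: 5.40
  7: 6.00
  8: 5.50
  9: 6.40
  10: 6.50
  12: 6.70
  14: 6.90
  16: 7.10
  18: 7.30
  20: 7.50
  25: 7.70
  30: 7.90

bulge:     # indexed by loop size, minimum 1
  1: 3.80
  2: 2.80
  3: 3.20
  4: 3.60
  5: 4.00
  6: 4.40
  7: 4.60
  8: 4.70
  9: 4.80
  10: 4.90
  12: 5.20
  14: 5.40
  16: 5.40
  18: 5.50
  20: 5.70
  25: 6.10
  30: 6.30

interior:  # indexed by total unpaired nt on both sides, minimum 2 (1x1)
  2: 4.10
  3: 5.10
  4: 4.90
  5: 5.30
  6: 5.70
  7: 5.90
  8: 6.00
  9: 6.10
  10: 6.30
  12: 6.40
  14: 6.60
  16: 6.80
  18: 6.90
  20: 7.00
  25: 7.30
  30: 7.60

multiloop:
  a: 3.40    # closing penalty
  b: 0.40    # per branch (closing pair counts as one branch)
  c: 0.00    # per unpaired nucleotide
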