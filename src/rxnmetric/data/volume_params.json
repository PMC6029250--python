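{
  "comment": "Additive atom-contribution van der Waals volumes (A^3) with bond and ring corrections: V = sum(atom contributions) - 5.92*B - 14.7*RA - 3.8*RNA, where B = bonds counting hydrogens = N_atoms - 1 + N_rings, RA = aromatic rings, RNA = non-aromatic rings.",
  "bond_correction": 5.92,
  "aromatic_ring_correction": 14.7,
  "nonaromatic_ring_correction": 3.8,
  "atom_contributions": {
    "H": 7.24,
    "B": 40.48,
    "C": 20.58,
    "N": 15.6,
    "O": 14.71,
    "F": 13.31,
    "Si": 38.79,
    "P": 24.43,
    "S": 24.43,
    "Cl": 22.45,
    "As": 26.52,
    "Se": 28.73,
    "Br": 26.52,
    "Te": 36.62,
    "I": 32.52
  }
}
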