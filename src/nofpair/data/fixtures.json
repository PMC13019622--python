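{
  "h2_sto3g": {
    "source": "pyscf 2.14.0, RHF molecular orbitals",
    "atom": "H 0 0 0; H 0 0 0.7414",
    "basis": "sto-3g",
    "n_basis": 2,
    "n_electrons": 2,
    "e_nuc": 0.7137539936876182,
    "e_rhf": -1.1166843870853405,
    "e_fci": -1.137270174660903
  },
  "he_631g": {
    "source": "pyscf 2.14.0, RHF molecular orbitals",
    "atom": "He 0 0 0",
    "basis": "6-31g",
    "n_basis": 2,
    "n_electrons": 2,
    "e_nuc": 0.0,
    "e_rhf": -2.8551604261544448,
    "e_fci": -2.8701621389008207
  },
  "lih_sto3g": {
    "source": "pyscf 2.14.0, RHF molecular orbitals",
    "atom": "Li 0 0 0; H 0 0 1.5949",
    "basis": "sto-3g",
    "n_basis": 6,
    "n_electrons": 4,
    "e_nuc": 0.995380044366418,
    "e_rhf": -7.8620269593941385,
    "e_fci": -7.882403410335491
  }
}
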