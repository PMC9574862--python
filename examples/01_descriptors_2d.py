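"""Compute the three chemical-space descriptors (nC, TPSA, PHI) for a few
small molecules.

nC measures size, TPSA polarity (Ertl fragment sum over N/O environments)
and PHI conformational flexibility (Kier's alpha-modified kappa indices).
Degraders live at the large/polar/flexible corner of this space
(nC 34-58, TPSA 166-335 Å², PHI 9-27)."""

from protacsol import compute_descriptors

MOLECULES = {
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "morpholine": "C1COCCN1",
    "n-decane": "C" * 10,
}

for name, smiles in MOLECULES.items():
    d = compute_descriptors(smiles)
    print(f"{name:12s} nC = {d.nc:2d}   TPSA = {d.tpsa:6.2f} Å²   PHI = {d.phi:5.2f}")
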