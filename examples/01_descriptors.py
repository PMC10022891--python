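"""Sequence descriptors of two classic curvature-sensing helices.

Computes net charge z, mean hydrophobicity <H> and the per-residue
hydrophobic moment mu_H (Eisenberg scale, 100 deg/residue) for the
N-terminal helix of alpha-synuclein and a synthetic ALPS-like sequence
(serine/glycine-rich polar face, bulky hydrophobics, nearly uncharged).
Both compositions are typical curvature sensors, yet their descriptors
differ sharply, which is why descriptors alone cannot separate sensors
from binders.
"""

import curvsense as cv

PEPTIDES = {
    "ALPS-like (synthetic)": "GSSLFDWLSSTVSGLSSFGWSLSG",
    "alpha-synuclein 1-24": "MDVFMKGLSKAKEGVVAAAEKTKQ",
}

print(f"{'peptide':24s} {'L':>3s} {'z':>3s} {'<H>':>7s} {'mu_H':>7s}")
for name, seq in PEPTIDES.items():
    p = cv.Peptide(seq)
    print(
        f"{name:24s} {len(p):3d} {cv.net_charge(p):+3d} "
        f"{cv.mean_hydrophobicity(p):7.3f} {cv.hydrophobic_moment(p):7.3f}"
    )
print(
    "\nz is side-chain charge at neutral pH; <H> and mu_H are dimensionless\n"
    "Eisenberg-scale values (mu_H ~ 0.3+ marks a clearly amphipathic helix)."
)
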