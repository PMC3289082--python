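"""Complementary-pair mass relations on a hand-built peptide spectrum.

Builds the noiseless +2 spectrum of the tryptic peptide GASPVLK from its
theoretical b/y ion m/z values and shows that every backbone bond yields a
(+1, +1) pair whose masses sum to twice the precursor m/z.
"""

from cidcharge import (
    DEFAULT_CONSTANTS as C,
    Spectrum,
    by_ion_mz,
    enumerate_pair_relations,
)

peptide = "GASPVLK"
mass = C.peptide_mass(peptide)
mp = (mass + 2 * C.proton) / 2  # +2 precursor

mz = []
for bond in range(1, len(peptide)):
    mz.append(by_ion_mz(peptide[:bond], "N", 1))   # b ion
    mz.append(by_ion_mz(peptide[bond:], "C", 1))   # y ion
spectrum = Spectrum("GASPVLK/2", mp, mz=mz, intensity=[1.0] * len(mz))

relations = enumerate_pair_relations(spectrum, losses_enabled=False)
cp11_z2 = [r for r in relations if r.kind == "CP11" and r.charge_hypothesis == 2]

print(f"peptide {peptide}: neutral mass {mass:.4f} Da, +2 precursor {mp:.4f} Th")
print(f"{len(spectrum)} fragment peaks, {len(cp11_z2)} (+1,+1) complementary pairs under z=2")
for r in cp11_z2:
    m1, m2 = spectrum.mz[r.i], spectrum.mz[r.j]
    print(f"  {m1:9.4f} + {m2:9.4f} = {m1 + m2:9.4f}  (2*mp = {2 * mp:.4f})")
# Each printed sum reproduces 2*mp to within float precision: the b and y
# ions of one bond jointly carry the whole peptide plus two protons.
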