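"""Convert a single BNCT weighted dose to BED and EQD2 under the USC model.

A BNCT delivery is characterized by its weighted dose (physical components
times RBE/CBE factors).  Because it is a single high dose, the multi-target
branch of the USC model gives its biologically effective dose, which is then
expressed as the equivalent total dose in standard 2-Gy photon fractions
(EQD2) — the scale on which photon-derived TCP parameters live.
"""

from bnct_tcp import (
    DoseComponents,
    SCC_USC_PARAMS,
    TUMOR_WEIGHTS,
    bed_bnct,
    eqd2_from_bnct,
    weighted_dose,
)

components = DoseComponents(
    boron_dose=4.2, thermal_neutron_dose=0.6, fast_neutron_dose=0.4, gamma_dose=1.04
)
d_w = weighted_dose(components, TUMOR_WEIGHTS)
print(f"physical components {components}")
print(f"weighted dose: {d_w:.2f} Gy-w  "
      f"(CBE {TUMOR_WEIGHTS.cbe_boron} x boron + RBE {TUMOR_WEIGHTS.rbe_neutron} x neutrons + gamma)")

bed = bed_bnct(d_w, SCC_USC_PARAMS)
eqd2 = eqd2_from_bnct(d_w, SCC_USC_PARAMS)
print(f"BED  = (D - Dq)/(alpha*D0) = {bed.bed:.2f} Gy")
print(f"EQD2 = BED/(1 + 2*beta/alpha) = {eqd2:.2f} Gy")
print("\nreading: this single BNCT fraction is biologically equivalent to "
      f"~{eqd2 / 2:.0f} photon fractions of 2 Gy.")
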