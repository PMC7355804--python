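"""Ideal solubility of piperine from its fusion properties, and the
activity coefficients that measure how far each solvent blend falls short
of (or exceeds) that ideal."""

from cosolvency import activity_coefficient, ideal_solubility, ppn_fixture
from cosolvency.piperine import PIPERINE_FUSION

ds = ppn_fixture()

print("T (K)    x_idl      gamma in water   gamma in THP")
for T in ds.temperatures:
    x_idl = ideal_solubility(T, PIPERINE_FUSION)
    g_water = activity_coefficient(x_idl, ds.x(0.0, T))
    g_thp = activity_coefficient(x_idl, ds.x(1.0, T))
    print(f"{T:5.1f}  {x_idl:.3e}   {g_water:12.1f}   {g_thp:10.2f}")

# gamma >> 1 in water: piperine dissolves orders of magnitude below the
# ideal limit there; gamma near (and below) 1 in pure Transcutol-HP means
# near-ideal to slightly favourable solute-solvent interactions.
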