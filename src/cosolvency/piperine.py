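"""Study constants for piperine in Transcutol-HP (THP) + water.

Molar masses from the materials table of the study; fusion properties of
piperine from differential scanning calorimetry reported there; total Hansen
solubility parameters as computed by the study for the three pure
substances.  The water molar mass is kept exactly as tabulated (18.07 g/mol)
for fixture fidelity; callers may substitute 18.015 g/mol.
"""

from .dataset import MolarMasses
from .hsp import HSPComponents
from .thermo import FusionProperties

__all__ = [
    "PIPERINE_MASSES",
    "PIPERINE_FUSION",
    "PIPERINE_HSP",
    "THP_HSP",
    "WATER_HSP",
    "HSP_TOTALS",
]

#: Molar masses (g/mol): piperine 285.34, Transcutol-HP 134.17, water 18.07.
PIPERINE_MASSES = MolarMasses(solute=285.34, cosolvent=134.17, water=18.07)

#: Fusion temperature 404.88 K, enthalpy 32.69 kJ/mol, heat-capacity
#: difference 80.74 J/(mol K).
PIPERINE_FUSION = FusionProperties(T_fus=404.88, dH_fus=32690.0, dC_p=80.74)

#: Total Hansen solubility parameters, MPa^1/2 (components not published).
PIPERINE_HSP = HSPComponents(delta_total=22.30)
THP_HSP = HSPComponents(delta_total=21.40)
WATER_HSP = HSPComponents(delta_total=47.80)

HSP_TOTALS = {
    "piperine": PIPERINE_HSP.total,
    "Transcutol-HP": THP_HSP.total,
    "water": WATER_HSP.total,
}
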