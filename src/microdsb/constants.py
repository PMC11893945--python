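"""Physical constants and unit conversions.

Internal unit conventions: lengths in micrometres (macroscopic geometry) or
nanometres (nucleus-frame damage coordinates), energies in MeV (transport) or
eV (deposition events), masses in kg, doses in Gy.
"""

MEV_TO_J = 1.602176634e-13
EV_TO_J = 1.602176634e-19

#: nuclear transformations per MBq·h — converts Gy/decay to Gy·h⁻¹·MBq⁻¹
DECAYS_PER_MBQ_H = 3.6e9

#: water density, kg/µm³ (1.0 g/cm³)
WATER_DENSITY_KG_PER_UM3 = 1.0e-15

#: default 15-day decay-chain truncation cutoff, seconds
DEFAULT_CHAIN_CUTOFF_S = 15.0 * 86400.0

SECONDS_PER_DAY = 86400.0
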