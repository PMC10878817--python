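"""Unit conventions and conversion constants.

All internal computation is SI (m, s, kg, Pa). Clinical reporting units
(mmHg, cm^2, ml/beat) appear only at the package boundary, converted with
the helpers here.
"""

from __future__ import annotations

#: Conversion factor from millimetres of mercury to pascal.
MMHG_TO_PA: float = 133.322

#: Conversion factor from square metres to square centimetres.
M2_TO_CM2: float = 1.0e4

#: Conversion factor from cubic metres to millilitres.
M3_TO_ML: float = 1.0e6


def mmhg_to_pa(p_mmhg: float) -> float:
    """Convert a pressure from mmHg to Pa."""
    return p_mmhg * MMHG_TO_PA


def pa_to_mmhg(p_pa: float) -> float:
    """Convert a pressure from Pa to mmHg."""
    return p_pa / MMHG_TO_PA
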