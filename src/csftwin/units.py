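"""Unit conventions and axial landmarks shared across the package.

Internal unit system is mm-s-mL (1 mL = 1000 mm^3). Flowrates are carried in
mL/min because that is how CSF flow is reported clinically; they are converted
to mm^3/s at the numerical core. SI conversions happen only inside the
Reynolds-number computation.
"""

from __future__ import annotations

#: mm^3 per mL
MM3_PER_ML = 1000.0

#: convert a flowrate in mL/min to mm^3/s
ML_MIN_TO_MM3_S = MM3_PER_ML / 60.0

#: convert a flowrate in mL/min to mL/day
ML_MIN_TO_ML_DAY = 60.0 * 24.0

#: minutes per day, for net-production bookkeeping
MIN_PER_DAY = 1440.0


def ml_min_to_mm3_s(q_ml_min):
    return q_ml_min * ML_MIN_TO_MM3_S


def mm3_s_to_ml_min(q_mm3_s):
    return q_mm3_s / ML_MIN_TO_MM3_S


# Axial landmarks (mm caudal of the foramen magnum, negative = cranial).
# Region cut planes follow the rootlet-table attachment positions: the
# cervicothoracic boundary at the T1 attachment and the thoracolumbar
# boundary at the L1 attachment; the spinal canal terminates at ~231 mm.
FORAMEN_MAGNUM_MM = 0.0
CERVICOTHORACIC_MM = 50.7
THORACOLUMBAR_MM = 181.3
SPINAL_TERMINATION_MM = 231.0
CRANIAL_VERTEX_MM = -28.0

REGION_ORDER = ("cranial", "cervical", "thoracic", "lumbar")


def region_of(z_mm: float) -> str:
    """Anatomical region label for an axial position."""
    if z_mm < FORAMEN_MAGNUM_MM:
        return "cranial"
    if z_mm < CERVICOTHORACIC_MM:
        return "cervical"
    if z_mm < THORACOLUMBAR_MM:
        return "thoracic"
    return "lumbar"
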