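"""AHA 17-segment model: angular sectors, levels, and named segment groups.

Conventions used throughout the package:

* Short-axis slices are ordered apex (slice 0) to base.
* The in-plane angle is 0 degrees at the anterior-wall centre and increases
  counter-clockwise when the stack is viewed from the apex, so the septum is
  centred near 90 degrees and the lateral wall near 270 degrees.
* Levels are indexed 0 = basal, 1 = mid, 2 = apical, 3 = apical cap.
"""

from __future__ import annotations

import numpy as np

SEGMENT_NAMES = {
    1: "basal anterior",
    2: "basal anteroseptal",
    3: "basal inferoseptal",
    4: "basal inferior",
    5: "basal inferolateral",
    6: "basal anterolateral",
    7: "mid anterior",
    8: "mid anteroseptal",
    9: "mid inferoseptal",
    10: "mid inferior",
    11: "mid inferolateral",
    12: "mid anterolateral",
    13: "apical anterior",
    14: "apical septal",
    15: "apical inferior",
    16: "apical lateral",
    17: "apex",
}

#: Segments averaged for the lateral wall in the lateral-minus-septal
#: time-to-end-systole difference (basal + mid inferolateral/anterolateral).
LATERAL_SEGMENTS = (5, 6, 11, 12)
#: Segments averaged for the septum (basal + mid anteroseptal/inferoseptal).
SEPTAL_SEGMENTS = (2, 3, 8, 9)

BASAL, MID, APICAL, APEX = 0, 1, 2, 3


def sector6(angle_deg):
    """Six 60-degree sectors, index 0 anterior, counter-clockwise."""
    a = np.asarray(angle_deg, dtype=float)
    return np.floor(((a + 30.0) % 360.0) / 60.0).astype(int)


def sector4(angle_deg):
    """Four 90-degree apical sectors, index 0 anterior."""
    a = np.asarray(angle_deg, dtype=float)
    return np.floor(((a + 45.0) % 360.0) / 90.0).astype(int)


def segment_of(level, angle_deg):
    """AHA segment id (1-17) from level index and in-plane angle.

    Broadcasts over array inputs.  Level 3 (apical cap) maps to segment 17
    regardless of angle.
    """
    level = np.asarray(level, dtype=int)
    angle = np.asarray(angle_deg, dtype=float)
    level, angle = np.broadcast_arrays(level, angle)
    seg = np.full(level.shape, 17, dtype=int)
    seg = np.where(level == BASAL, 1 + sector6(angle), seg)
    seg = np.where(level == MID, 7 + sector6(angle), seg)
    seg = np.where(level == APICAL, 13 + sector4(angle), seg)
    if seg.ndim == 0:
        return int(seg)
    return seg
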