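"""Report rounding convention.

Printed report tables use integer percentages rounded half away from zero
(so 45.45 -> 45, 81.82 -> 82, 17.5 -> 18, -17.5 -> -18). Python's built-in
round() rounds half to even and would disagree on .5 ties.
"""

import math


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero."""
    if x >= 0:
        return int(math.floor(x + 0.5))
    return -int(math.floor(-x + 0.5))
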