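"""Pixel-class and growth-event codes shared across the pipeline.

The trinarized representation assigns every in-arena pixel to one of three
classes: the plasmodium itself (SLIME), the extracellular slime trace it
leaves behind when it withdraws (MUCUS), and substrate it has never touched
(UNEXPLORED).  Pixels outside the arena are stored as UNEXPLORED (code 0)
but are excluded from every metric.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np


class Label(IntEnum):
    """Per-pixel class of a trinarized frame."""

    UNEXPLORED = 0
    SLIME = 1
    MUCUS = 2


class Event(IntEnum):
    """Per-pixel growth event between two consecutive trinarized frames.

    PRIMARY    : unexplored -> slime (first visit)
    SECONDARY  : mucus -> slime (revisit of previously explored substrate)
    REFINEMENT : slime -> mucus (withdrawal)
    """

    NONE = 0
    PRIMARY = 1
    SECONDARY = 2
    REFINEMENT = 3


#: RGB palette used when label grids are written as indexed PNG.
LABEL_PALETTE = {
    Label.UNEXPLORED: (0, 0, 0),
    Label.SLIME: (255, 210, 40),
    Label.MUCUS: (170, 170, 190),
}

# Legal label transitions between consecutive frames.  Once a pixel has been
# visited it can never return to UNEXPLORED.
LEGAL_TRANSITIONS = {
    Label.UNEXPLORED: {Label.UNEXPLORED, Label.SLIME},
    Label.SLIME: {Label.SLIME, Label.MUCUS},
    Label.MUCUS: {Label.MUCUS, Label.SLIME},
}


def check_transition_legality(prev: np.ndarray, curr: np.ndarray) -> bool:
    """Return True iff every pixel transition between two label grids is legal."""
    ok = np.ones(prev.shape, dtype=bool)
    for src, allowed in LEGAL_TRANSITIONS.items():
        allowed_codes = np.array(sorted(int(a) for a in allowed))
        ok &= ~(prev == src) | np.isin(curr, allowed_codes)
    return bool(ok.all())
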