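"""Rule-based hypnogram smoothing.

Predicted hypnograms occasionally contain short REM bouts embedded in
long wake runs — physiologically atypical, since REM is entered from
NREM. The shipped rule relabels every maximal REM run of length <=
``max_bout`` whose immediate left AND right neighbours are both WAKE.
Runs touching a sequence boundary have no flank on that side and are
left untouched. The rule only helps when the classifier is already
accurate; on poorly labeled data it can be counterproductive, so it is
a separate, optional post-processing step.

Additional user rules can be composed via :func:`apply_rules`.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .stages import Hypnogram, Stage

__all__ = ["smooth_rem_in_wake", "apply_rules"]


def smooth_rem_in_wake(h: Hypnogram, max_bout: int = 1) -> Hypnogram:
    """Relabel wake-flanked REM runs of length <= max_bout as WAKE.

    Single left-to-right pass over maximal REM runs; output length
    equals input length. Idempotent: the relabeling never creates a new
    wake-flanked REM run.
    """
    if max_bout < 1:
        raise ValueError("max_bout must be >= 1")
    s = h.stages.copy()
    n = len(s)
    i = 0
    while i < n:
        if s[i] != Stage.REM:
            i += 1
            continue
        j = i
        while j < n and s[j] == Stage.REM:
            j += 1
        run_len = j - i
        has_flanks = i > 0 and j < n
        if (run_len <= max_bout and has_flanks
                and s[i - 1] == Stage.WAKE and s[j] == Stage.WAKE):
            s[i:j] = Stage.WAKE
        i = j
    return Hypnogram(s, h.epoch_length_s)


def apply_rules(
    h: Hypnogram,
    rules: Sequence[Callable[[Hypnogram], Hypnogram]],
) -> Hypnogram:
    """Apply smoothing rules in order; each maps Hypnogram -> Hypnogram."""
    for rule in rules:
        out = rule(h)
        if len(out) != len(h):
            raise ValueError("smoothing rules must preserve hypnogram length")
        h = out
    return h
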