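"""Convenience builders tying the synthetic generator to the imaging stack.

These helpers produce the multi-subject labeled image collections used
by the benchmarks, the pipeline runner and the test-suite: each
synthetic "subject" (animal) gets its own Markov hypnogram and signal
record, rendered into labeled epoch images.
"""

from __future__ import annotations

import numpy as np

from .dataset import ImageDataset
from .imaging import build_window_images
from .stages import Hypnogram
from .synth import (
    StageParams,
    TransitionConfig,
    simulate_hypnogram,
    synthesize_signals,
)

__all__ = ["derive_seed", "make_subject_images"]


def derive_seed(*parts: int) -> int:
    """Deterministic child seed (< 2^31) from a tuple of integers."""
    ss = np.random.SeedSequence([int(p) for p in parts])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def make_subject_images(
    n_subjects: int,
    epochs_per_subject: int,
    seed: int,
    out_px: int = 64,
    epochs_per_image: int = 1,
    window_s_override: float | None = None,
    subject_prefix: str = "m",
    transitions: TransitionConfig | None = None,
    params: StageParams | None = None,
) -> tuple[ImageDataset, dict[str, Hypnogram]]:
    """Simulate, synthesize and render images for several subjects.

    Returns the pooled ImageDataset and the per-subject ground-truth
    hypnograms. All randomness derives from ``seed``.
    """
    params = params or StageParams()
    images = []
    hypnograms: dict[str, Hypnogram] = {}
    for s in range(n_subjects):
        sid = f"{subject_prefix}{s}"
        hyp = simulate_hypnogram(
            epochs_per_subject,
            config=transitions,
            seed=derive_seed(seed, s, 0),
            epoch_length_s=params.epoch_length_s,
        )
        record = synthesize_signals(hyp, params, seed=derive_seed(seed, s, 1))
        images += build_window_images(
            record, hyp,
            epochs_per_image=epochs_per_image,
            window_s_override=window_s_override,
            out_px=out_px,
            subject_id=sid,
        )
        hypnograms[sid] = hyp
    return ImageDataset(images), hypnograms
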