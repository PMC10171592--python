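"""Intensity windowing and reproducible train/validation/test splitting.

CT slices arrive in Hounsfield units (HU).  For training they are mapped to
[0, 1] by a VOI-LUT window: intensities inside ``center +/- width/2`` are
scaled linearly and everything outside is clamped.  The default soft-tissue
window (center 0 HU, width 200 HU) puts orbital fat (~ -80 HU), muscle
(~ +50 HU) and the vitreous (~ +5 HU) on well-separated normalized levels
while saturating bone and air.

Dataset splitting shuffles the ordered id list with a seed derived from
``(seed, repetition)`` so that each of the repeated experiments uses a
distinct but reproducible partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WindowSpec", "SplitSpec", "apply_window", "split_ids"]


@dataclass(frozen=True)
class WindowSpec:
    """A linear intensity window in Hounsfield units.

    ``ps33`` selects the DICOM PS3.3 convention, which maps the interval
    ``[center - 0.5 - (width-1)/2, center - 0.5 + (width-1)/2]``; the default
    is the plain ``center +/- width/2`` clamp (sub-1% difference at width
    200).
    """

    center: float = 0.0
    width: float = 200.0
    ps33: bool = False

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"window width must be positive, got {self.width}")


def apply_window(image: np.ndarray, window: WindowSpec = WindowSpec()) -> np.ndarray:
    """Normalize an HU image to [0, 1] through a VOI-LUT window.

    y = clip((x - (center - width/2)) / width, 0, 1), elementwise.
    """
    x = np.asarray(image, dtype=np.float32)
    if not np.all(np.isfinite(x)):
        raise ValueError("image contains non-finite values")
    if window.ps33:
        lo = window.center - 0.5 - (window.width - 1.0) / 2.0
        span = window.width - 1.0
    else:
        lo = window.center - window.width / 2.0
        span = window.width
    y = (x - lo) / span
    return np.clip(y, 0.0, 1.0, out=y)


@dataclass(frozen=True)
class SplitSpec:
    """Repeated random train/validation/test split specification."""

    ratios: tuple[float, float, float] = (0.7, 0.15, 0.15)
    seed: int = 0
    repetitions: int = 10

    def __post_init__(self) -> None:
        if len(self.ratios) != 3 or any(r <= 0 for r in self.ratios):
            raise ValueError("ratios must be three positive fractions")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError(f"ratios must sum to 1, got {sum(self.ratios)}")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


def split_ids(
    ids: list, spec: SplitSpec = SplitSpec(), repetition: int = 0
) -> tuple[list, list, list]:
    """Partition ``ids`` into (train, val, test) for one repetition.

    Sizes are ``floor(r_train*n)`` and ``floor(r_val*n)`` with the remainder
    assigned to test.  Shuffling is driven by ``spec.seed + repetition`` so
    each repetition yields a distinct, reproducible permutation.
    """
    if len(ids) == 0:
        raise ValueError("cannot split an empty id list")
    if len(set(ids)) != len(ids):
        raise ValueError("ids must be unique")
    if not 0 <= repetition < spec.repetitions:
        raise ValueError(
            f"repetition {repetition} outside [0, {spec.repetitions})"
        )
    n = len(ids)
    n_train = int(np.floor(spec.ratios[0] * n))
    n_val = int(np.floor(spec.ratios[1] * n))
    rng = np.random.default_rng(spec.seed + repetition)
    order = rng.permutation(n)
    shuffled = [ids[i] for i in order]
    return (
        shuffled[:n_train],
        shuffled[n_train : n_train + n_val],
        shuffled[n_train + n_val :],
    )
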