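"""Threshold overlap score (TOS) colocalization.

TOS compares the sets of brightest pixels in two images of the same field of
view against the overlap expected if the two intensity patterns were
independent.  For each image the top ``t`` percent of pixels (by rank, not by
value threshold) is selected; with ``n1``, ``n2`` selected pixels out of ``N``
total, the expected co-selected count under independence is ``E = n1*n2/N``,
the maximum possible is ``M = min(n1, n2)`` and the minimum possible is
``m = max(0, n1 + n2 - N)``.  The observed co-selected count ``n12`` is then
rescaled logarithmically so that the score is -1 at the minimum possible
overlap (complete anticolocalization), 0 at the independence expectation, and
1 at the maximum possible overlap (complete colocalization).

Because selection is rank-based, the score is invariant under any strictly
monotone transform of either image's intensities — important when one image
is a network output in arbitrary units.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["TOSConfig", "TOSResult", "top_percentile_mask", "tos", "tos_batch"]


@dataclass(frozen=True)
class TOSConfig:
    """Selection settings: ``percentile_t`` is the top-intensity percentage."""

    percentile_t: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.percentile_t <= 100.0):
            raise ValueError(f"percentile_t must be in (0, 100], got {self.percentile_t}")


@dataclass(frozen=True)
class TOSResult:
    """Pixel-selection counts and the rescaled overlap scores for one pair."""

    N: int
    n1: int
    n2: int
    n12: int
    E: float
    M: int
    m: int
    tos_linear: float
    tos_log: float
    floored: bool = False  # half-pixel floor engaged (tiny images / zero overlap)

    def __post_init__(self) -> None:
        assert self.m <= self.n12 <= self.M


def _selection_order(image: np.ndarray) -> np.ndarray:
    """Flat pixel indices sorted by intensity descending, row-major index ascending.

    The fixed total order makes the selected count exact and deterministic even
    with ties at the cut.
    """
    flat = np.asarray(image).ravel()
    # stable sort on -value keeps row-major order within ties
    return np.argsort(-flat, kind="stable")


def top_percentile_mask(image: np.ndarray, t: float = 1.0) -> np.ndarray:
    """Boolean mask selecting exactly ``ceil(t/100 * N)`` brightest pixels."""
    img = np.asarray(image)
    if not (0.0 < t <= 100.0):
        raise ValueError(f"percentile t must be in (0, 100], got {t}")
    n_sel = int(math.ceil(t / 100.0 * img.size))
    n_sel = max(n_sel, 1)
    if img.size and np.ptp(img) == 0:
        warnings.warn("constant image: top-percentile selection is arbitrary (deterministic tie rule)",
                      stacklevel=2)
    order = _selection_order(img)
    mask = np.zeros(img.size, dtype=bool)
    mask[order[:n_sel]] = True
    return mask.reshape(img.shape)


def tos(image_a: np.ndarray, image_b: np.ndarray, config: TOSConfig = TOSConfig()) -> TOSResult:
    """Threshold overlap score with logarithmic rescaling between two images."""
    a = np.asarray(image_a)
    b = np.asarray(image_b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    t = config.percentile_t
    sel_a = top_percentile_mask(a, t)
    sel_b = top_percentile_mask(b, t)

    N = a.size
    n1 = int(sel_a.sum())
    n2 = int(sel_b.sum())
    n12 = int(np.count_nonzero(sel_a & sel_b))
    E = n1 * n2 / N
    M = min(n1, n2)
    m = max(0, n1 + n2 - N)
    if M <= E:
        raise ValueError(
            f"degenerate selection: M = {M} <= E = {E} (a selection covers the whole image)")

    floored = False
    if n12 >= E:
        tos_log = math.log(n12 / E) / math.log(M / E)
        tos_linear = (n12 - E) / (M - E)
    else:
        num = n12
        if num < 0.5:
            num, floored = 0.5, True
        lo = m
        if lo < 0.5:
            lo, floored = 0.5, True
        if E <= lo:  # tiny image: expected overlap below the floor
            floored = True
            tos_log = 0.0
        else:
            tos_log = math.log(num / E) / math.log(E / lo)
        tos_linear = (n12 - E) / (E - m) if E > m else 0.0
    tos_log = float(np.clip(tos_log, -1.0, 1.0))
    tos_linear = float(np.clip(tos_linear, -1.0, 1.0))
    return TOSResult(N=N, n1=n1, n2=n2, n12=n12, E=E, M=M, m=m,
                     tos_linear=tos_linear, tos_log=tos_log, floored=floored)


@dataclass(frozen=True)
class TOSBatchSummary:
    mean: float
    sd: float
    n: int
    scores: tuple = field(repr=False, default=())


def tos_batch(pairs, config: TOSConfig = TOSConfig()) -> TOSBatchSummary:
    """Mean +/- SD of the log-rescaled TOS across image pairs."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("need at least one image pair")
    scores = []
    for i, (a, b) in enumerate(pairs):
        try:
            scores.append(tos(a, b, config).tos_log)
        except ValueError as exc:
            raise ValueError(f"pair {i}: {exc}") from exc
    arr = np.asarray(scores, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return TOSBatchSummary(mean=float(arr.mean()), sd=sd, n=len(arr), scores=tuple(scores))
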