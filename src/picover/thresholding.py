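"""Histograms, automatic threshold selection and HSB colour-band masks.

Segmentation of pigment from background is a cut on the 256-bin histogram of
one channel (usually brightness), chosen automatically.  Three selectors are
provided:

* :func:`threshold_isodata` — iterative intermeans: the fixed point of
  ``t ← round((mean of values ≤ t) + (mean of values > t)) / 2``.
* :func:`threshold_ij_default` — the common "default" variant of the same
  iteration, differing only in its initialisation (mean of the occupied
  extremes); on most histograms the two coincide.
* :func:`threshold_max_entropy` — Kapur–Sahoo–Wong: maximises the summed
  Shannon entropies of the two class-conditional histograms.

All three return a byte value ``t`` with the fixed convention that the
foreground is ``value > t``; selecting *dark* pigment on a white background is
expressed as a brightness PASS band ``[0, t]`` rather than by redefining the
threshold.

A full colour threshold is three bands (hue, saturation, brightness) applied
to an HSB image; hue is circular, so a hue band with ``lo > hi`` wraps
through 255→0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class ThresholdMethod(Enum):
    DEFAULT = "default"
    ISODATA = "isodata"
    MAXENTROPY = "maxentropy"
    MANUAL = "manual"


class BandPolarity(Enum):
    PASS = "pass"
    STOP = "stop"


@dataclass(frozen=True)
class Histogram:
    """256-bin histogram of a byte plane."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (256,):
            raise ValueError("histogram needs exactly 256 bins")
        if (counts < 0).any():
            raise ValueError("histogram counts must be non-negative")
        if counts.sum() < 1:
            raise ValueError("histogram is empty")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def occupied(self) -> np.ndarray:
        return np.nonzero(self.counts)[0]


def histogram_of(channel: np.ndarray, mask: np.ndarray | None = None) -> Histogram:
    """Histogram of a byte plane, optionally restricted to ``mask``."""
    plane = np.asarray(channel)
    if plane.dtype != np.uint8:
        raise ValueError("channel must be a uint8 plane")
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        if m.shape != plane.shape:
            raise ValueError("mask shape must match channel shape")
        if not m.any():
            raise ValueError("no pixels to histogram (empty mask)")
        plane = plane[m]
    return Histogram(np.bincount(plane.ravel(), minlength=256))


def _round_half_down(x: float) -> int:
    """Round to nearest integer, halves toward zero (arguments are ≥ 0).

    Half-down at the intermeans update prevents oscillation between 127/128
    on histograms symmetric about 127.5.
    """
    return int(np.ceil(x - 0.5))

def _check_nondegenerate(h: Histogram) -> np.ndarray:
    occ = h.occupied
    if occ.size < 2:
        raise ValueError("degenerate histogram: fewer than 2 occupied bins")
    return occ


def _intermeans(h: Histogram, t0: int, max_iter: int = 256) -> int:
    counts = h.counts.astype(np.float64)
    values = np.arange(256, dtype=np.float64)
    csum = np.cumsum(counts)
    cvsum = np.cumsum(counts * values)
    occ = h.occupied
    lo_cap, hi_cap = int(occ[0]), int(occ[-1]) - 1  # both classes non-empty
    t = min(max(t0, lo_cap), hi_cap)
    for _ in range(max_iter):
        mean_below = cvsum[t] / csum[t]
        mean_above = (cvsum[255] - cvsum[t]) / (csum[255] - csum[t])
        t_next = _round_half_down((mean_below + mean_above) / 2.0)
        t_next = min(max(t_next, lo_cap), hi_cap)
        if t_next == t:
            return t
        t = t_next
    raise RuntimeError("intermeans iteration did not converge in 256 steps")


def threshold_isodata(h: Histogram) -> int:
    """IsoData / iterative-intermeans threshold (foreground = values > t)."""
    occ = _check_nondegenerate(h)
    t0 = int(occ[0] + occ[-1]) // 2  # midpoint of the occupied range
    return _intermeans(h, t0)


def threshold_ij_default(h: Histogram) -> int:
    """"Default" intermeans variant: initialised at the mean of the occupied
    extremes, then the same fixed-point update as :func:`threshold_isodata`."""
    occ = _check_nondegenerate(h)
    t0 = _round_half_down((int(occ[0]) + int(occ[-1])) / 2.0)
    return _intermeans(h, t0)


def threshold_max_entropy(h: Histogram) -> int:
    """Kapur–Sahoo–Wong maximum-entropy threshold.

    Maximises ``H_below(t) + H_above(t)`` over t, where each term is the
    Shannon entropy (natural log) of the normalized class-conditional
    histogram; empty bins contribute 0 (0·log 0 := 0).  Ties break toward the
    smallest t; the result equals exhaustive search by construction.
    """
    occ = _check_nondegenerate(h)
    p = h.counts.astype(np.float64) / h.total
    P = np.cumsum(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    S = np.cumsum(plogp)
    best_t, best_val = None, -np.inf
    for t in range(int(occ[0]), int(occ[-1])):  # both classes non-empty
        p0, p1 = P[t], 1.0 - P[t]
        if p0 <= 0 or p1 <= 0:
            continue
        h0 = np.log(p0) - S[t] / p0
        h1 = np.log(p1) - (S[255] - S[t]) / p1
        val = h0 + h1
        if val > best_val:  # strict: first (smallest) t wins ties
            best_t, best_val = t, val
    assert best_t is not None
    return best_t


_SELECTORS = {
    ThresholdMethod.DEFAULT: threshold_ij_default,
    ThresholdMethod.ISODATA: threshold_isodata,
    ThresholdMethod.MAXENTROPY: threshold_max_entropy,
}


def select_threshold(h: Histogram, method: ThresholdMethod) -> int:
    if method is ThresholdMethod.MANUAL:
        raise ValueError("MANUAL method has no automatic selector; supply bands")
    return _SELECTORS[method](h)


@dataclass(frozen=True)
class ThresholdBand:
    """One channel band.  PASS keeps values inside [lo, hi]; STOP keeps the
    complement.  Circular bands (hue only) permit lo > hi, wrapping through
    255→0."""

    lo: int
    hi: int
    polarity: BandPolarity = BandPolarity.PASS
    circular: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.lo <= 255 and 0 <= self.hi <= 255):
            raise ValueError("band limits must be byte values")
        if not self.circular and self.lo > self.hi:
            raise ValueError("non-circular band requires lo <= hi")

    def contains(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values)
        if self.circular and self.lo > self.hi:
            inside = (v >= self.lo) | (v <= self.hi)
        else:
            inside = (v >= self.lo) & (v <= self.hi)
        return inside if self.polarity is BandPolarity.PASS else ~inside

    @property
    def covers_full_circle(self) -> bool:
        if not self.circular:
            return False
        if self.lo > self.hi:
            return self.hi >= self.lo - 1  # wrap leaves no gap
        return self.lo == 0 and self.hi == 255

    def complement(self) -> "ThresholdBand":
        pol = (
            BandPolarity.STOP
            if self.polarity is BandPolarity.PASS
            else BandPolarity.PASS
        )
        return ThresholdBand(self.lo, self.hi, pol, self.circular)


def full_band(circular: bool = False) -> ThresholdBand:
    return ThresholdBand(0, 255, BandPolarity.PASS, circular)


@dataclass(frozen=True)
class ColorThresholdSpec:
    """Hue + saturation + brightness bands, as in an HSB colour threshold."""

    hue: ThresholdBand = field(default_factory=lambda: full_band(circular=True))
    saturation: ThresholdBand = field(default_factory=full_band)
    brightness: ThresholdBand = field(default_factory=full_band)
    method_used: ThresholdMethod = ThresholdMethod.MANUAL

    def __post_init__(self) -> None:
        if not self.hue.circular:
            raise ValueError("hue band must be circular")
        if self.saturation.circular or self.brightness.circular:
            raise ValueError("saturation/brightness bands must not be circular")


def apply_color_threshold(img, spec: ColorThresholdSpec) -> np.ndarray:
    """Binary mask of the HSB pixels satisfying all three bands."""
    from .imaging import ColorSpace  # local import avoids a cycle

    if img.space is not ColorSpace.HSB:
        raise ValueError(
            f"colour threshold requires an HSB image, got {img.space.name}"
        )
    return (
        spec.hue.contains(img.channel(0))
        & spec.saturation.contains(img.channel(1))
        & spec.brightness.contains(img.channel(2))
    )
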