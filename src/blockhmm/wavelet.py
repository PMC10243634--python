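"""Haar lifting transform, universal-threshold shrinkage and block building.

A piecewise-constant signal plus homoscedastic Gaussian noise has a
sparse orthonormal Haar representation: detail coefficients away from
jumps are N(0, σ²), while jumps produce large coefficients.  Zeroing
every detail below the universal threshold λ_u = sqrt(2 ln T)·σ removes
the noise; the positions where the surviving coefficients' wavelets
change sign are candidate segment boundaries (breakpoints).  The runs
between breakpoints become *blocks*, each summarized by its length n_w
and the sufficient statistics Σ1_w = Σ y_t and Σ2_w = Σ y_t² — all a
Gaussian-emission HMM needs to score the block.

The transform is computed with the lifting scheme: in place, one level
at a time, in O(T) total.  The orthonormal convention (a±b)/√2 is used
so that white noise of variance σ² stays white with variance σ² at
every level and λ_u applies to the coefficients directly.  Sequences of
arbitrary length are handled by carrying the odd trailing element of a
level up to the next level unchanged (no padding, hence no phantom
breakpoints at the end of the sequence).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HaarCoefficients",
    "Block",
    "BlockSequence",
    "haar_lift",
    "haar_inverse",
    "estimate_noise_sd",
    "universal_threshold",
    "detect_breakpoints",
    "build_blocks",
    "compress",
]

logger = logging.getLogger(__name__)

_SQRT2 = np.sqrt(2.0)
#: Φ^{-1}(3/4): MAD / this constant is a consistent estimator of a
#: Gaussian standard deviation.
MAD_GAUSS = 0.6745


@dataclass
class HaarCoefficients:
    """Multi-level orthonormal Haar decomposition of a sequence.

    ``details[l]`` holds the detail coefficients of level ``l`` (level 0
    is finest); ``centers[l]`` holds, for each detail, the 0-based
    position in the original sequence where the corresponding Haar
    wavelet changes sign (the boundary between its left and right
    support halves); ``starts[l]``/``ends[l]`` bound its half-open
    support.  ``smooth`` is the final single approximation coefficient.
    Total coefficient count is ``length`` (T-1 details plus one smooth).
    """

    details: list[np.ndarray]
    centers: list[np.ndarray]
    starts: list[np.ndarray]
    ends: list[np.ndarray]
    smooth: float
    length: int
    level_lengths: list[int] = field(default_factory=list)


def haar_lift(obs) -> HaarCoefficients:
    """Orthonormal Haar analysis by lifting; O(T), no padding.

    Each working element carries the *sum* of its original span.  A pair
    of elements with sums (S_a, S_b) over spans of lengths (n_a, n_b)
    yields the unbalanced-Haar detail

        d = (S_a/n_a − S_b/n_b) · sqrt(n_a n_b / (n_a + n_b)),

    which equals the classical (a−b)/√2 when n_a = n_b and — for any
    spans — is exactly zero on constant input and has variance σ² under
    i.i.d. N(0, σ²) noise.  The trailing element of an odd-length level
    is carried up unchanged, so arbitrary lengths need no padding and a
    constant sequence never produces phantom details.
    """
    y = np.asarray(obs, dtype=float).ravel()
    if y.size < 1:
        raise ValueError("cannot transform an empty sequence")
    T = y.size
    details: list[np.ndarray] = []
    centers: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    lends: list[np.ndarray] = []
    level_lengths: list[int] = []
    cur = y.copy()  # per-element span sums
    # original-sequence span covered by each current-level element; the
    # detail of pair (2k, 2k+1) changes sign at ends[2k]
    span_s = np.arange(T, dtype=np.intp)
    span_e = np.arange(1, T + 1, dtype=np.intp)
    while cur.size > 1:
        m = cur.size
        level_lengths.append(m)
        half = m // 2
        a, b = cur[0 : 2 * half : 2], cur[1 : 2 * half : 2]
        s = span_s[0 : 2 * half : 2]
        c = span_e[0 : 2 * half : 2]
        e = span_e[1 : 2 * half : 2]
        na = (c - s).astype(float)
        nb = (e - c).astype(float)
        details.append((a / na - b / nb) * np.sqrt(na * nb / (na + nb)))
        starts.append(s.copy())
        centers.append(c.copy())
        lends.append(e.copy())
        smooth = a + b
        new_s = span_s[0 : 2 * half : 2]
        new_e = span_e[1 : 2 * half : 2]
        if m % 2:  # odd element carried up unchanged
            smooth = np.append(smooth, cur[-1])
            new_s = np.append(new_s, span_s[-1])
            new_e = np.append(new_e, span_e[-1])
        cur, span_s, span_e = smooth, new_s, new_e
    return HaarCoefficients(
        details=details,
        centers=centers,
        starts=starts,
        ends=lends,
        smooth=float(cur[0] / np.sqrt(T)),
        length=T,
        level_lengths=level_lengths,
    )


def haar_inverse(coeffs: HaarCoefficients) -> np.ndarray:
    """Exact inverse of :func:`haar_lift` (the shrinkage estimate f̂
    when details have been thresholded)."""
    cur = np.array([coeffs.smooth * np.sqrt(coeffs.length)], dtype=float)
    for lvl in range(len(coeffs.level_lengths) - 1, -1, -1):
        m = coeffs.level_lengths[lvl]
        det = coeffs.details[lvl]
        half = m // 2
        if det.size != half:
            raise ValueError(f"level of length {m} expects {half} details, got {det.size}")
        if m % 2:
            carried, smooth = cur[-1], cur[:-1]
        else:
            smooth = cur
        if smooth.size != half:
            raise ValueError("coefficient levels are inconsistent with the stored lengths")
        na = (coeffs.centers[lvl] - coeffs.starts[lvl]).astype(float)
        nb = (coeffs.ends[lvl] - coeffs.centers[lvl]).astype(float)
        # invert d = (Sa/na - Sb/nb)·sqrt(na·nb/(na+nb)) given S = Sa+Sb
        r = det / np.sqrt(na * nb / (na + nb))
        sa = (r + smooth / nb) * na * nb / (na + nb)
        out = np.empty(m)
        out[0 : 2 * half : 2] = sa
        out[1 : 2 * half : 2] = smooth - sa
        if m % 2:
            out[-1] = carried
        cur = out
    if cur.size != coeffs.length:
        raise ValueError("coefficient structure does not reconstruct the original length")
    return cur


def estimate_noise_sd(coeffs: HaarCoefficients) -> float:
    """Noise standard deviation from the finest-level details.

    Under the orthonormal convention each finest detail away from a jump
    is N(0, σ²); the median absolute deviation is robust to the few
    jump-crossing coefficients, so σ̂ = median(|d|) / 0.6745.
    """
    if coeffs.length < 2 or not coeffs.details:
        raise ValueError("need at least two observations to estimate noise")
    return float(np.median(np.abs(coeffs.details[0])) / MAD_GAUSS)


def universal_threshold(T: int, sigma: float) -> float:
    """λ_u = sqrt(2 ln T) · σ, the universal shrinkage threshold."""
    if T < 1:
        raise ValueError("sequence length must be at least 1")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return float(np.sqrt(2.0 * np.log(T)) * sigma)


def _descend(coeffs: HaarCoefficients, level: int, index: int) -> list[int]:
    """Localize the jump seen by one coefficient by walking the wavelet tree.

    A coarse coefficient detects a jump anywhere in its support but its
    own sign change may be far from it.  Descending to the child wavelet
    (left or right support half) with the larger |detail| homes in on
    the jump; the centers visited on the way down are candidate
    boundaries at every scale.
    """
    s = int(coeffs.starts[level][index])
    c = int(coeffs.centers[level][index])
    e = int(coeffs.ends[level][index])
    out = []
    for lvl in range(level - 1, -1, -1):
        st = coeffs.starts[lvl]
        # children are the wavelets spanning [s, c) and [c, e)
        cand = []
        for lo, hi in ((s, c), (c, e)):
            k = int(np.searchsorted(st, lo))
            if k < st.size and st[k] == lo and coeffs.ends[lvl][k] == hi:
                cand.append(k)
        if not cand:
            break
        k = max(cand, key=lambda k: abs(coeffs.details[lvl][k]))
        s = int(st[k])
        c = int(coeffs.centers[lvl][k])
        e = int(coeffs.ends[lvl][k])
        out.append(c)
    return out


def detect_breakpoints(coeffs: HaarCoefficients, threshold: float) -> np.ndarray:
    """Candidate block boundaries from super-threshold details.

    Every detail with |d| > threshold contributes the center of its
    support (where its wavelet changes sign) plus the centers visited by
    a tree-descent localization of the jump inside its support (see
    :func:`_descend`).  The deduplicated sorted positions b ∈ (0, T) are
    returned; a breakpoint b means "a block ends at b (exclusive)".
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    hits: set[int] = set()
    for level, (det, cen) in enumerate(zip(coeffs.details, coeffs.centers)):
        for k in np.flatnonzero(np.abs(det) > threshold):
            hits.add(int(cen[k]))
            hits.update(_descend(coeffs, level, int(k)))
    hits.discard(0)
    hits.discard(coeffs.length)
    return np.array(sorted(hits), dtype=np.intp)


@dataclass(frozen=True)
class Block:
    """One block: half-open span [start, end) with sufficient statistics."""

    start: int
    end: int
    s1: float  # Σ1_w = sum of y_t
    s2: float  # Σ2_w = sum of y_t²

    @property
    def n(self) -> int:
        return self.end - self.start


@dataclass
class BlockSequence:
    """Contiguous, non-overlapping blocks covering [0, T) (struct-of-arrays)."""

    starts: np.ndarray
    ends: np.ndarray
    s1: np.ndarray
    s2: np.ndarray

    @property
    def n(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def W(self) -> int:
        return len(self.starts)

    @property
    def T(self) -> int:
        return int(self.ends[-1]) if self.W else 0

    def __len__(self) -> int:
        return self.W

    def __getitem__(self, w: int) -> Block:
        return Block(int(self.starts[w]), int(self.ends[w]), float(self.s1[w]), float(self.s2[w]))

    def __iter__(self):
        return (self[w] for w in range(self.W))

    def expand_states(self, block_states: np.ndarray) -> np.ndarray:
        """Per-observation state path from one state per block."""
        return np.repeat(np.asarray(block_states), self.n)


def build_blocks(obs, breakpoints) -> BlockSequence:
    """Cut the sequence at the breakpoints and accumulate Σ1, Σ2 per block."""
    y = np.asarray(obs, dtype=float).ravel()
    T = y.size
    bp = np.asarray(breakpoints, dtype=np.intp)
    if bp.size and (bp.min() < 1 or bp.max() > T - 1):
        raise ValueError("breakpoints must lie strictly inside (0, T)")
    bounds = np.concatenate(([0], bp, [T]))
    c1 = np.concatenate(([0.0], np.cumsum(y)))
    c2 = np.concatenate(([0.0], np.cumsum(y * y)))
    starts, ends = bounds[:-1], bounds[1:]
    return BlockSequence(
        starts=starts,
        ends=ends,
        s1=c1[ends] - c1[starts],
        s2=c2[ends] - c2[starts],
    )


def compress(obs, sigma: float | None = None, threshold: float | None = None) -> BlockSequence:
    """Full pipeline: lift → (estimate σ) → threshold → breakpoints → blocks.

    ``sigma`` overrides the MAD noise estimate (e.g. the smallest
    emission standard deviation of a known model); ``threshold``
    overrides the universal threshold entirely.
    """
    y = np.asarray(obs, dtype=float).ravel()
    coeffs = haar_lift(y)
    if threshold is None:
        if sigma is None:
            sigma = estimate_noise_sd(coeffs) if y.size > 1 else 0.0
        threshold = universal_threshold(y.size, sigma)
    blocks = build_blocks(y, detect_breakpoints(coeffs, threshold))
    logger.info(
        "compressed T=%d into W=%d blocks (ratio %.1f)",
        y.size,
        blocks.W,
        y.size / blocks.W,
    )
    return blocks
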