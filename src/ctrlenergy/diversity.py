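"""Lempel-Ziv signal diversity from epoched multichannel recordings.

Signal diversity is an entropy proxy for neural dynamics: each 2-s epoch
of each channel is binarized around its own mean, parsed with the
Lempel-Ziv 1976 exhaustive-history algorithm, and the per-channel
dictionary sizes are averaged.  The resulting 0.5 Hz series is convolved
with a canonical haemodynamic response function so it can be correlated
against BOLD-derived control energy on the fMRI volume grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal
import scipy.stats

__all__ = [
    "EpochedSignal",
    "DiversitySeries",
    "binarize_epoch",
    "lz76",
    "diversity_series",
    "hrf_align",
    "double_gamma_hrf",
]


@dataclass(frozen=True)
class EpochedSignal:
    """Channels x epochs x samples array of epoched signal (a.u.)."""

    data: np.ndarray
    sample_rate_hz: float = 250.0
    epoch_seconds: float = 2.0

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3:
            raise ValueError("data must be channels x epochs x samples")
        if d.shape[0] < 1:
            raise ValueError("need at least one channel")
        expected = int(round(self.sample_rate_hz * self.epoch_seconds))
        if d.shape[2] != expected:
            raise ValueError(
                f"samples per epoch {d.shape[2]} != sample_rate * epoch_seconds = {expected}"
            )
        object.__setattr__(self, "data", d)


@dataclass(frozen=True)
class DiversitySeries:
    """Per-epoch channel-mean LZ76 counts, optionally HRF-aligned."""

    values: np.ndarray
    epoch_seconds: float = 2.0
    aligned: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("values must be 1-D")
        if np.any(v < 1):
            raise ValueError("LZ76 counts are at least 1")
        object.__setattr__(self, "values", v)


def binarize_epoch(x: np.ndarray) -> np.ndarray:
    """Binarize one epoch around its mean: 1 where the sample exceeds it.

    Ties (including constant epochs) map to 0, keeping the rule
    deterministic.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty epoch")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples")
    return (x > x.mean()).astype(np.uint8)


def lz76(b: np.ndarray) -> int:
    """Lempel-Ziv 1976 exhaustive-history parse count of a binary sequence.

    The sequence is partitioned left to right into words: each word is
    the shortest extension that is no longer reproducible from the text
    preceding its last symbol (occurrences may overlap the word itself).
    The returned count is the number of words in the parse - the
    dictionary size used as the raw, unnormalized diversity.
    """
    arr = np.asarray(b)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError("need a 1-D sequence of length >= 1")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("sequence must be binary")
    s = arr.astype(np.uint8).tobytes()
    n = len(s)
    c = 0
    start = 0
    while start < n:
        k = 1
        # word grows while its prefix can be copied from s[: start+k-1]
        while start + k <= n and s[start:start + k] in s[: start + k - 1]:
            k += 1
        c += 1
        start += k
    return c


def diversity_series(sig: EpochedSignal) -> DiversitySeries:
    """Channel-mean LZ76 count per epoch."""
    d = sig.data
    counts = np.empty((d.shape[0], d.shape[1]))
    for ch in range(d.shape[0]):
        for ep in range(d.shape[1]):
            counts[ch, ep] = lz76(binarize_epoch(d[ch, ep]))
    return DiversitySeries(counts.mean(axis=0), epoch_seconds=sig.epoch_seconds)


def double_gamma_hrf(
    dt: float,
    duration: float = 32.0,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    ratio: float = 1.0 / 6.0,
    dispersion: float = 1.0,
) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled every ``dt`` s.

    Peak at ~6 s, undershoot at ~16 s with 1/6 relative amplitude, 32 s
    support; normalized to unit sum so convolution preserves the scale of
    a constant input.
    """
    t = np.arange(0, duration + dt / 2, dt)
    peak = scipy.stats.gamma.pdf(t, peak_delay / dispersion, scale=dispersion)
    under = scipy.stats.gamma.pdf(t, undershoot_delay / dispersion, scale=dispersion)
    h = peak - ratio * under
    return h / h.sum()


def hrf_align(
    ds: DiversitySeries,
    tr_seconds: float = 2.0,
    n_volumes: int | None = None,
    hrf: np.ndarray | None = None,
) -> np.ndarray:
    """Convolve a diversity series with an HRF and resample to the volume grid.

    The convolution runs at the epoch rate (mode ``full``, truncated to
    the series length).  Epochs map onto volumes by block-averaging when
    the epoch rate is an integer multiple of the volume rate; with 2-s
    epochs at TR = 2 s the mapping is one-to-one (epoch k -> volume k).
    """
    v = np.asarray(ds.values, float)
    if hrf is None:
        hrf = double_gamma_hrf(ds.epoch_seconds)
    if v.size < hrf.size:
        raise ValueError("series shorter than the HRF kernel")
    conv = scipy.signal.convolve(v, hrf, mode="full")[: v.size]

    per = tr_seconds / ds.epoch_seconds
    if abs(per - round(per)) > 1e-9 or per < 1:
        raise ValueError(
            "epoch rate must be an integer multiple of the volume rate"
        )
    per = int(round(per))
    out = conv[: (conv.size // per) * per].reshape(-1, per).mean(axis=1)
    if n_volumes is not None:
        if out.size < n_volumes:
            raise ValueError(
                f"only {out.size} aligned points for {n_volumes} volumes"
            )
        out = out[:n_volumes]
    return out


def lz76_bruteforce(b: np.ndarray) -> int:
    """Exhaustive-history parse by explicit occurrence enumeration, O(n^3).

    For a word starting at position ``l``, its reproducible length is the
    longest match between the suffix at ``l`` and a copy starting at any
    earlier position (copies may run into the word itself); the word is
    that prefix plus one fresh symbol.  Written with explicit character
    comparisons - no substring machinery - so it is an independent oracle
    for :func:`lz76`.
    """
    s = [int(x) for x in np.asarray(b).ravel()]
    if not s or any(x not in (0, 1) for x in s):
        raise ValueError("sequence must be binary and non-empty")
    n = len(s)
    c = 0
    l = 0
    while l < n:
        k_max = 0
        for i in range(l):
            m = 0
            while l + m < n and s[i + m] == s[l + m]:
                m += 1
            k_max = max(k_max, m)
        c += 1
        l += min(k_max + 1, n - l)
    return c
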