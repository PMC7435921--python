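"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the code paths they check: the Welch oracle loops
over segments and evaluates the discrete Fourier sum directly, the entropy
oracle tallies samples one by one in a dictionary, and the paired-t null is
simulated by resampling.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


def direct_welch_unit_area(
    x: np.ndarray, fs: float, nperseg: int = 256, nfft: int = 4096
) -> tuple[np.ndarray, np.ndarray]:
    """Averaged one-sided periodogram by explicit segment loop + DFT sum."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    hop = nperseg // 2
    n_seg = (len(x) - nperseg) // hop + 1
    freqs = np.arange(nfft // 2 + 1) * fs / nfft
    n = np.arange(nperseg)
    k = np.arange(nfft // 2 + 1)
    # explicit discrete-transform sum: X[k] = sum_n x[n] e^{-2pi i k n / nfft}
    basis = np.exp(-2j * np.pi * np.outer(k, n) / nfft)
    acc = np.zeros(freqs.size)
    for s in range(n_seg):
        seg = x[s * hop : s * hop + nperseg]
        spectrum = basis @ seg
        p = np.abs(spectrum) ** 2
        p[1:-1] *= 2.0  # one-sided doubling (DC and Nyquist excluded)
        acc += p
    acc /= n_seg
    df = fs / nfft
    return freqs, acc / (acc.sum() * df)


def tally_entropy_bits(x: np.ndarray, bin_width: float) -> float:
    """Plug-in differential entropy by per-sample dictionary tally."""
    counts: Counter = Counter()
    for value in np.asarray(x, dtype=float):
        counts[math.floor(value / bin_width)] += 1
    n = sum(counts.values())
    h = -sum((c / n) * math.log2(c / n) for c in counts.values())
    return h + math.log2(bin_width)


def tally_joint_entropy_bits(x: np.ndarray, y: np.ndarray, bin_width: float) -> float:
    counts: Counter = Counter()
    for a, b in zip(np.asarray(x, dtype=float), np.asarray(y, dtype=float)):
        counts[(math.floor(a / bin_width), math.floor(b / bin_width))] += 1
    n = sum(counts.values())
    h = -sum((c / n) * math.log2(c / n) for c in counts.values())
    return h + 2.0 * math.log2(bin_width)


def resampled_t_pvalue(t_obs: float, n: int, n_draws: int = 100_000, seed: int = 0) -> float:
    """Two-sided p-value of the paired t statistic under a simulated null."""
    rng = np.random.default_rng(seed)
    d = rng.standard_normal((n_draws, n))
    t = d.mean(axis=1) / (d.std(axis=1, ddof=1) / np.sqrt(n))
    return float(np.mean(np.abs(t) >= abs(t_obs)))
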