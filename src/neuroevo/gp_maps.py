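"""Deterministic genotype-phenotype maps from sampled trace amplitudes.

A trace is read out at regular bin-edge times (see
:func:`neuroevo.signals.sample_at_intervals`); the resulting amplitude
vector is decoded either into a binary string (thresholding) or into a
permutation (ordering by magnitude).  Both maps are many-to-one: the
statistics of that degeneracy are measured in :mod:`neuroevo.analysis`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["signal_to_binary", "signal_to_permutation",
           "pack_bits", "pack_permutation"]


def signal_to_binary(amplitudes: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Bit k is 1 iff ``amplitudes[k] > threshold`` (strict).

    The default threshold 0 is the symmetry point of the zero-mean Fourier
    seed signals.
    """
    amplitudes = np.asarray(amplitudes)
    return (amplitudes > threshold).astype(np.int8)


def signal_to_permutation(amplitudes: np.ndarray) -> np.ndarray:
    """The permutation sorting amplitudes ascending, stable in time index.

    ``order[k]`` is the index of the k-th smallest amplitude; ties go to the
    earlier sampling time.
    """
    amplitudes = np.asarray(amplitudes)
    return np.argsort(amplitudes, kind="stable")


def pack_bits(bits: np.ndarray) -> int:
    """Encode a binary string as an integer (first bit most significant)."""
    out = 0
    for b in np.asarray(bits).astype(int):
        out = (out << 1) | int(b)
    return out


def pack_permutation(order: np.ndarray) -> int:
    """Encode a permutation of 0..N-1 as a mixed-radix integer."""
    order = np.asarray(order).astype(int)
    n = order.size
    out = 0
    for v in order:
        out = out * n + int(v)
    return out
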