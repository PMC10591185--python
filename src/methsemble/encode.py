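"""Feature encodings of 41-bp windows.

A window is vectorized into five named feature groups, concatenated in a
fixed, column-stable order (344 features total):

==========  ====  ================================================================
group       size  meaning
==========  ====  ================================================================
DNF           16  dinucleotide frequencies over the 40 overlapping pairs
NCP          123  nucleotide chemical properties, 3 bits per position:
                  ring structure, hydrogen bonding, amino/keto class —
                  A=(1,1,1), C=(0,0,1), G=(1,0,0), T=(0,1,0)
AMIP          40  average mutual information profile: MI (bits) between bases
                  k positions apart, k = 1..40
GC             1  log-transformed GC content, log(1 + GC fraction)
MBED         164  mono-nucleotide binary encoding, 4 bits per position with the
                  bit assignment A=(1,0,0,0), G=(0,1,0,0), C=(0,0,1,0),
                  T=(0,0,0,1)
==========  ====  ================================================================

All encoders are pure functions of the window sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqio import WINDOW_WIDTH, SequenceWindow, validate_window

BASES = "ACGT"
DINUCLEOTIDES = tuple(a + b for a in BASES for b in BASES)

# chemical-property triples: (ring structure, hydrogen bond, amino/keto)
NCP_CODE = {"A": (1, 1, 1), "C": (0, 0, 1), "G": (1, 0, 0), "T": (0, 1, 0)}
NCP_CHANNELS = ("ring", "hbond", "amino")

# one-hot bit assignment; channel i is set by MBED_CHANNELS[i]
MBED_CODE = {"A": (1, 0, 0, 0), "G": (0, 1, 0, 0),
             "C": (0, 0, 1, 0), "T": (0, 0, 0, 1)}
MBED_CHANNELS = ("A", "G", "C", "T")

AMIP_KMAX = WINDOW_WIDTH - 1

_BASE_INDEX = np.full(128, -1, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _BASE_INDEX[ord(_b)] = _i


def _feature_names() -> tuple[list[str], list[str]]:
    names, groups = [], []
    for d in DINUCLEOTIDES:
        names.append(f"DNF:{d}")
        groups.append("DNF")
    for p in range(1, WINDOW_WIDTH + 1):
        for ch in NCP_CHANNELS:
            names.append(f"NCP:pos{p:02d}:{ch}")
            groups.append("NCP")
    for k in range(1, AMIP_KMAX + 1):
        names.append(f"AMIP:k{k:02d}")
        groups.append("AMIP")
    names.append("GC:log")
    groups.append("GC")
    for p in range(1, WINDOW_WIDTH + 1):
        for ch in MBED_CHANNELS:
            names.append(f"MBED:pos{p:02d}:{ch}")
            groups.append("MBED")
    return names, groups

#: fixed column order of the full encoding; stable across runs
FEATURE_NAMES, FEATURE_GROUPS = _feature_names()
N_FEATURES = len(FEATURE_NAMES)
GROUP_SIZES = {"DNF": 16, "NCP": 123, "AMIP": 40, "GC": 1, "MBED": 164}


@dataclass(frozen=True)
class FeatureVector:
    """Named, group-tagged encoding of one window."""

    names: tuple[str, ...]
    groups: tuple[str, ...]
    values: np.ndarray

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))

    def census(self) -> dict[str, int]:
        return group_census(self.names)


def group_census(names: Iterable[str]) -> dict[str, int]:
    """Count features per encoding group from their name prefixes."""
    census: dict[str, int] = {}
    for n in names:
        g = n.split(":", 1)[0]
        census[g] = census.get(g, 0) + 1
    return census


def _codes(window: SequenceWindow | str) -> np.ndarray:
    seq = validate_window(window).sequence
    return _BASE_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_dnf(window: SequenceWindow | str) -> np.ndarray:
    """Dinucleotide frequencies: counts of the 16 ordered pairs / 40."""
    c = _codes(window)
    pair = c[:-1] * 4 + c[1:]
    return np.bincount(pair, minlength=16) / (len(c) - 1)


def encode_ncp(window: SequenceWindow | str) -> np.ndarray:
    """Per-position chemical-property triples, position-major (123 values)."""
    c = _codes(window)
    table = np.array([NCP_CODE[b] for b in BASES], dtype=float)
    return table[c].ravel()


def encode_mbed(window: SequenceWindow | str) -> np.ndarray:
    """Per-position one-hot code with the A,G,C,T bit order (164 values)."""
    c = _codes(window)
    table = np.array([MBED_CODE[b] for b in BASES], dtype=float)
    return table[c].ravel()


def decode_mbed(values: Sequence[float]) -> str:
    """Invert :func:`encode_mbed` back to the window sequence."""
    arr = np.asarray(values, dtype=float).reshape(WINDOW_WIDTH, 4)
    if not np.array_equal(arr.sum(axis=1), np.ones(WINDOW_WIDTH)):
        raise ValueError("not a one-hot MBED block structure")
    return "".join(MBED_CHANNELS[i] for i in arr.argmax(axis=1))


def encode_gc(window: SequenceWindow | str) -> float:
    """Log-transformed GC content, log(1 + (G+C)/41), natural log.

    The log transform damps the weight of GC content relative to the
    larger feature groups; the value is 0 for a GC-free window and grows
    monotonically to log 2 for a pure-GC window.
    """
    c = _codes(window)
    gc = np.count_nonzero((c == 1) | (c == 2)) / len(c)
    return float(np.log1p(gc))


def encode_amip(window: SequenceWindow | str, k_max: int = AMIP_KMAX) -> np.ndarray:
    """Average mutual information profile, MI_k in bits for k = 1..k_max.

    For each lag k the joint distribution p_k(X,Y) is estimated over the
    41-k ordered base pairs (s_i, s_{i+k}); the marginals are the row and
    column sums of that joint, so MI_k >= 0 with equality iff the lag-k
    joint factorizes.  Empty cells follow the 0*log(0) = 0 convention.
    """
    if not 1 <= k_max <= AMIP_KMAX:
        raise ValueError(f"k_max must be in 1..{AMIP_KMAX}, got {k_max}")
    c = _codes(window)
    n = len(c)
    out = np.empty(k_max)
    for k in range(1, k_max + 1):
        joint = np.bincount(c[:-k] * 4 + c[k:], minlength=16).reshape(4, 4)
        joint = joint / (n - k)
        px = joint.sum(axis=1)
        py = joint.sum(axis=0)
        nz = joint > 0
        denom = np.outer(px, py)
        mi = float(np.sum(joint[nz] * np.log2(joint[nz] / denom[nz])))
        out[k - 1] = max(mi, 0.0)  # guard float round-off on factorizing joints
    return out


def encode_all(window: SequenceWindow | str) -> FeatureVector:
    """Full 344-feature encoding in the fixed group order DNF+NCP+AMIP+GC+MBED."""
    values = np.concatenate([
        encode_dnf(window),
        encode_ncp(window),
        encode_amip(window),
        [encode_gc(window)],
        encode_mbed(window),
    ])
    return FeatureVector(tuple(FEATURE_NAMES), tuple(FEATURE_GROUPS), values)


def encode_matrix(windows: Sequence[SequenceWindow | str]) -> pd.DataFrame:
    """Encode many windows into a column-stable (n, 344) feature matrix."""
    mat = np.empty((len(windows), N_FEATURES))
    index = []
    for i, w in enumerate(windows):
        mat[i] = encode_all(w).values
        index.append(w.accession if isinstance(w, SequenceWindow) else str(i))
    return pd.DataFrame(mat, columns=FEATURE_NAMES, index=index)
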