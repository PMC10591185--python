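"""Synthetic benchmarks: labeled 41-bp windows and motif-planted promoters.

Real 6mA benchmarks are balanced sets of 41-bp adenine-centred windows
(positives carry the methylated adenine at position 21).  The generator
emulates that structure at desk scale with a tunable, fully known signal: a
short motif written immediately downstream of the central adenine in positive
windows with probability ``separation``.  Both classes are centred on A —
negatives model *unmethylated* adenine sites — so at separation 0 the classes
are statistically exchangeable and any classifier is reduced to coin-flipping.

Promoter simulation plants complete positive-style windows at window-aligned
offsets of an otherwise random sequence, recording their coordinates in a
truth table so end-to-end scans can be scored for recall and precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import encode
from .seqio import WINDOW_WIDTH, SequenceRecord, SequenceWindow

BASES = "ACGT"
CENTER = WINDOW_WIDTH // 2  # 0-based index 20 == 1-based position 21
DEFAULT_MOTIF = "GAGG"


@dataclass(frozen=True)
class SyntheticBenchmark:
    """Balanced labeled window set with a planted class-discriminating motif."""

    windows: tuple[SequenceWindow, ...]
    labels: np.ndarray  # 1 = 6mA-positive window
    separation: float
    motif: str
    base_composition: tuple[float, float, float, float]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "accession": [w.accession for w in self.windows],
            "sequence": [w.sequence for w in self.windows],
            "label": self.labels,
        })

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for w, y in zip(self.windows, self.labels):
                fh.write(f">{w.accession} label={int(y)}\n{w.sequence}\n")


def _draw_window(rng: np.random.Generator, comp: np.ndarray,
                 motif: str, with_motif: bool) -> str:
    """One adenine-centred window; the motif slot is forced present/absent."""
    chars = rng.choice(4, size=WINDOW_WIDTH, p=comp)
    seq = list("".join(BASES[i] for i in chars))
    seq[CENTER] = "A"
    lo, hi = CENTER + 1, CENTER + 1 + len(motif)
    if with_motif:
        seq[lo:hi] = motif
    else:
        # scrub chance occurrences so `separation` is the exact signal rate
        while "".join(seq[lo:hi]) == motif:
            redraw = rng.choice(4, size=len(motif), p=comp)
            seq[lo:hi] = [BASES[i] for i in redraw]
    return "".join(seq)


def generate_benchmark(n_pos: int, n_neg: int, separation: float = 1.0,
                       seed: int = 0, motif: str = DEFAULT_MOTIF,
                       base_composition: Sequence[float] | None = None,
                       ) -> SyntheticBenchmark:
    """Generate a labeled benchmark of adenine-centred 41-bp windows.

    Positives carry ``motif`` directly downstream of the central A with
    probability ``separation``; negatives (and non-motif positives) never
    do.  Backgrounds are i.i.d. from ``base_composition`` (default uniform).
    Identical seeds give byte-identical output.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    if not 0.0 <= separation <= 1.0:
        raise ValueError(f"separation must be in [0,1], got {separation}")
    if CENTER + 1 + len(motif) > WINDOW_WIDTH:
        raise ValueError("motif too long to fit downstream of the central A")
    comp = (np.full(4, 0.25) if base_composition is None
            else np.asarray(base_composition, dtype=float))
    if len(comp) != 4 or not np.isclose(comp.sum(), 1.0):
        raise ValueError("base_composition must be 4 probabilities summing to 1")
    comp = comp / comp.sum()

    rng = np.random.default_rng(seed)
    windows: list[SequenceWindow] = []
    labels = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
    for i in range(n_pos):
        has_motif = rng.random() < separation
        seq = _draw_window(rng, comp, motif, has_motif)
        windows.append(SequenceWindow(f"pos_{i + 1:05d}", 1, 1, WINDOW_WIDTH, seq))
    for i in range(n_neg):
        seq = _draw_window(rng, comp, motif, False)
        windows.append(SequenceWindow(f"neg_{i + 1:05d}", 1, 1, WINDOW_WIDTH, seq))
    return SyntheticBenchmark(tuple(windows), labels, separation, motif,
                              tuple(comp), seed)


def generate_promoters(n: int, length: int = 1500, sites_per_promoter: int = 3,
                       seed: int = 0, motif: str = DEFAULT_MOTIF,
                       base_composition: Sequence[float] | None = None,
                       species: str | Sequence[str] = "synthetic",
                       ) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Simulate promoters with known planted 6mA windows.

    Each promoter is an i.i.d. background sequence in which
    ``sites_per_promoter`` distinct window-aligned 41-bp slots are rewritten
    as positive-style windows (central A + motif).  All remaining
    window-aligned slots are scrubbed of chance positive look-alikes so the
    returned truth table (accession, window_index, start, end; 1-based
    inclusive) is exact.  ``species`` may be a single tag or one tag per
    promoter, written as a ``species=`` token in the FASTA description.
    """
    if length < WINDOW_WIDTH:
        raise ValueError(f"length must be >= {WINDOW_WIDTH}")
    n_slots = length // WINDOW_WIDTH
    if sites_per_promoter > n_slots:
        raise ValueError(
            f"sites_per_promoter {sites_per_promoter} exceeds the "
            f"{n_slots} windows of a {length}-bp promoter"
        )
    comp = (np.full(4, 0.25) if base_composition is None
            else np.asarray(base_composition, dtype=float))
    comp = comp / comp.sum()
    if isinstance(species, str):
        tags = [species] * n
    else:
        tags = list(species)
        if len(tags) != n:
            raise ValueError("species must be a single tag or one per promoter")

    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    truth_rows = []
    for i in range(n):
        chars = rng.choice(4, size=length, p=comp)
        seq = list("".join(BASES[j] for j in chars))
        site_slots = sorted(rng.choice(n_slots, size=sites_per_promoter,
                                       replace=False))
        acc = f"prom_{i + 1:04d}"
        for w in range(n_slots):
            lo = w * WINDOW_WIDTH
            planted = w in site_slots
            seq[lo:lo + WINDOW_WIDTH] = _draw_window(rng, comp, motif, planted)
            if planted:
                truth_rows.append({
                    "species": tags[i], "accession": acc,
                    "window_index": w + 1, "start": lo + 1,
                    "end": lo + WINDOW_WIDTH,
                })
        records.append(SequenceRecord(acc, "".join(seq),
                                      f"species={tags[i]}"))
    truth = pd.DataFrame(
        truth_rows,
        columns=["species", "accession", "window_index", "start", "end"],
    )
    return records, truth


def planted_feature_matrix(n_samples: int,
                           planted: Sequence[str] | None = None,
                           effect: float = 1.5, seed: int = 0,
                           ) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature-space benchmark for validating the hybrid selector.

    Produces a balanced (n_samples, 344) matrix with the encoder's column
    names; all columns are N(0,1) noise except the ``planted`` ones, whose
    mean is shifted by ``effect`` in the positive class.  The default planted
    set spans all five encoding groups so group-census assertions are
    meaningful.  Returns ``(features, labels)``.
    """
    if planted is None:
        planted = DEFAULT_PLANTED_FEATURES
    missing = set(planted) - set(encode.FEATURE_NAMES)
    if missing:
        raise ValueError(f"unknown feature names: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    labels = np.concatenate([np.ones(n_samples // 2, int),
                             np.zeros(n_samples - n_samples // 2, int)])
    X = rng.standard_normal((n_samples, encode.N_FEATURES))
    df = pd.DataFrame(X, columns=encode.FEATURE_NAMES)
    for name in planted:
        df[name] += effect * labels
    return df, labels


#: ten planted columns spread over the five groups (3 DNF-like spread kept
#: small so recovery genuinely exercises both selection arms)
DEFAULT_PLANTED_FEATURES = (
    "DNF:AC", "DNF:GA",
    "NCP:pos21:ring", "NCP:pos22:hbond",
    "AMIP:k03", "AMIP:k10",
    "GC:log",
    "MBED:pos20:A", "MBED:pos22:G", "MBED:pos23:C",
)
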