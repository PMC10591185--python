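"""Promoter scanning: fragment, predict with two species models, intersect.

The application pipeline tiles each promoter into 41-bp windows, predicts
every unambiguous window with two independently trained ensembles (one per
model species), keeps only windows both models call 6mA-positive, and maps
the surviving windows back to promoter coordinates.  Summaries follow the
shapes used in promoter methylation surveys: per-species site totals, a
per-promoter site-count histogram, and mean sites per gene.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import learn, seqio
from .learn import EnsembleModel
from .seqio import SequenceRecord, split_windows

_SPECIES_RE = re.compile(r"species=(\S+)")


@dataclass(frozen=True)
class SiteEntry:
    """One predicted 6mA window in promoter coordinates (1-based inclusive)."""

    species: str
    accession: str
    window_index: int
    start: int
    end: int
    score: float


@dataclass
class SiteMap:
    """Predicted 6mA windows plus the census of all scanned promoters.

    ``promoters`` lists every (species, accession) scanned — including
    promoters with zero sites — so per-gene rates have the right denominator.
    """

    entries: list[SiteEntry] = field(default_factory=list)
    promoters: list[tuple[str, str]] = field(default_factory=list)

    @property
    def per_species_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {sp: 0 for sp, _ in self.promoters}
        for e in self.entries:
            counts[e.species] = counts.get(e.species, 0) + 1
        return counts

    @property
    def per_promoter_counts(self) -> dict[str, int]:
        counts = {acc: 0 for _, acc in self.promoters}
        for e in self.entries:
            counts[e.accession] = counts.get(e.accession, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "species": e.species, "accession": e.accession,
                    "window_index": e.window_index, "start": e.start,
                    "end": e.end, "score": e.score,
                }
                for e in self.entries
            ],
            columns=["species", "accession", "window_index",
                     "start", "end", "score"],
        )


def species_of(record: SequenceRecord) -> str:
    """Species tag from a ``species=`` token in the description, else 'unknown'."""
    m = _SPECIES_RE.search(record.description)
    return m.group(1) if m else "unknown"


def scan_promoters(promoters: Sequence[SequenceRecord],
                   model_a: EnsembleModel, model_b: EnsembleModel,
                   drop_ambiguous: bool = True) -> SiteMap:
    """Scan promoters for 6mA windows supported by both species models.

    Each promoter is tiled into 41-bp windows (N-containing windows dropped,
    coordinates preserved), both ensembles predict every window, and the
    intersection rule keeps a window only when both call it positive.
    """
    sites = SiteMap()
    for rec in promoters:
        sp = species_of(rec)
        sites.promoters.append((sp, rec.accession))
        windows = split_windows(rec, drop_ambiguous=drop_ambiguous)
        if not windows:
            continue
        pred_a = learn.predict(model_a, windows)
        pred_b = learn.predict(model_b, windows)
        for p in learn.intersect_calls(pred_a, pred_b):
            if p.call:
                w = p.window
                sites.entries.append(SiteEntry(
                    sp, w.accession, w.window_index, w.start, w.end, p.score,
                ))
    return sites


def summarize(sites: SiteMap) -> dict[str, pd.DataFrame]:
    """Species totals, per-promoter site-count histogram, mean sites/gene.

    The mean sites/gene divides total predicted windows by the number of
    scanned promoters of that species, counting zero-site promoters.
    Returns ``{"species": ..., "histogram": ...}`` DataFrames.
    """
    prom_counts = sites.per_promoter_counts
    prom_species = {acc: sp for sp, acc in sites.promoters}
    species = sorted({sp for sp, _ in sites.promoters})

    species_rows = []
    hist_rows = []
    for sp in species:
        accs = [acc for _, acc in sites.promoters if prom_species[acc] == sp]
        counts = [prom_counts[acc] for acc in accs]
        total = sum(counts)
        species_rows.append({
            "species": sp,
            "n_promoters": len(accs),
            "n_sites": total,
            "mean_sites_per_gene": total / len(accs) if accs else 0.0,
        })
        for k in sorted(set(counts)):
            hist_rows.append({
                "species": sp,
                "sites_per_promoter": k,
                "n_promoters": counts.count(k),
            })
    return {
        "species": pd.DataFrame(
            species_rows,
            columns=["species", "n_promoters", "n_sites",
                     "mean_sites_per_gene"],
        ),
        "histogram": pd.DataFrame(
            hist_rows,
            columns=["species", "sites_per_promoter", "n_promoters"],
        ),
    }


def top_promoters(sites: SiteMap, k: int,
                  ) -> list[tuple[str, int, list[SiteEntry]]]:
    """The k promoters with the most predicted sites (ties by accession).

    Returns ``(accession, site_count, site_entries)`` triples, sorted by
    descending count then accession; asking for more promoters than exist
    returns the full list.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    prom_counts = sites.per_promoter_counts
    by_prom: dict[str, list[SiteEntry]] = {acc: [] for acc in prom_counts}
    for e in sites.entries:
        by_prom[e.accession].append(e)
    ranked = sorted(prom_counts, key=lambda a: (-prom_counts[a], a))
    return [(acc, prom_counts[acc], sorted(by_prom[acc], key=lambda e: e.start))
            for acc in ranked[:k]]


def plot_histogram(sites: SiteMap, path) -> None:
    """Bar plot of the per-promoter site-count histogram, one panel set."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hist = summarize(sites)["histogram"]
    fig, ax = plt.subplots(figsize=(6, 4))
    for sp, sub in hist.groupby("species"):
        ax.bar(sub["sites_per_promoter"], sub["n_promoters"],
               alpha=0.6, label=str(sp))
    ax.set_xlabel("6mA sites per promoter")
    ax.set_ylabel("number of promoters")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
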