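"""Hypermutated-region flagging and mutational-spectrum summaries.

Selection on activating events tends to produce *mutually exclusive*
recurrence — each tumour mutated at most once in a region — whereas a
focal mutational process (e.g. AID-driven somatic hypermutation in
lymphoma) repeatedly hits the same region within one tumour.  The
discriminating statistic is the mean number of mutations per *mutated*
sample, T / n_samples: a region is flagged hypermutated when this ratio
strictly exceeds a threshold (default 1.2).  A threshold-sensitivity
analysis reports, over regions with more than ``min_T`` mutations, the
percentage classified identically under alternative thresholds.

Spectra summarize the base-substitution landscape in the standard
96-channel trinucleotide classification (pyrimidine-reference strand
collapse: a G>A call in an AGG context counts as C>T in C_T) and its
6-channel base-change marginal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals_io import GenomeIndex, GenomicInterval

__all__ = [
    "MultiplicityStats",
    "SpectrumCounts",
    "classify_hypermutated",
    "threshold_concordance",
    "trinucleotide_spectrum",
    "category_mutation_shares",
    "SPECTRUM_CLASSES_96",
    "SPECTRUM_CLASSES_6",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
PYRIMIDINES = ("C", "T")

SPECTRUM_CLASSES_6: list[str] = [
    f"{ref}>{alt}" for ref in PYRIMIDINES for alt in "ACGT" if alt != ref
]
SPECTRUM_CLASSES_96: list[str] = [
    f"{five}[{change}]{three}"
    for change in SPECTRUM_CLASSES_6
    for five in "ACGT"
    for three in "ACGT"
]


@dataclass(frozen=True)
class MultiplicityStats:
    """Per-region multiplicity: T mutations across n_samples mutated samples."""

    window: GenomicInterval
    T: int
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.T < self.n_samples:
            raise ValueError("need T >= n_samples >= 1")

    @property
    def mutations_per_mutated_sample(self) -> float:
        return self.T / self.n_samples


def classify_hypermutated(stats: MultiplicityStats, threshold: float = 1.2) -> bool:
    """True iff the region has strictly more than ``threshold`` mutations
    per mutated sample."""
    return stats.mutations_per_mutated_sample > threshold


def threshold_concordance(
    stats: list[MultiplicityStats],
    reference_threshold: float = 1.2,
    alt_thresholds: tuple[float, ...] = (1.1, 1.3, 1.4, 1.5),
    min_T: int = 2,
) -> dict[float, float]:
    """Percent of regions classified identically under alternative thresholds.

    Restricted to regions with T > ``min_T`` (regions with very few
    mutations are trivially non-hypermutated at every threshold and
    would inflate concordance).
    """
    eligible = [s for s in stats if s.T > min_T]
    if not eligible:
        raise ValueError("no regions with T > min_T")
    ratios = np.array([s.mutations_per_mutated_sample for s in eligible])
    ref_labels = ratios > reference_threshold
    return {
        float(t): float(100.0 * np.mean((ratios > t) == ref_labels))
        for t in alt_thresholds
    }


@dataclass
class SpectrumCounts:
    """96-channel trinucleotide and 6-channel base-change mutation counts.

    ``counts_96``/``counts_6`` are integer Series indexed by class label;
    ``n_excluded_edge`` counts mutations lacking a flanking base at a
    chromosome end, ``n_ref_mismatch`` counts mutations whose stated ref
    allele disagrees with the genome (or whose context contains N).
    Classified + excluded = input.
    """

    counts_96: pd.Series
    counts_6: pd.Series
    n_excluded_edge: int = 0
    n_ref_mismatch: int = 0

    @property
    def n_classified(self) -> int:
        return int(self.counts_96.sum())

    def fractions_96(self) -> pd.Series:
        return self.counts_96 / max(self.n_classified, 1)

    def fractions_6(self) -> pd.Series:
        return self.counts_6 / max(self.n_classified, 1)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def trinucleotide_spectrum(mutations: pd.DataFrame, genome: GenomeIndex) -> SpectrumCounts:
    """Classify SNVs into the 96 trinucleotide channels.

    The context comes from the reference genome; purine-reference calls
    are mapped to their reverse-complement (pyrimidine) channel.
    Mutations at the first/last base of a chromosome (no flank) and
    mutations whose ref mismatches the genome or whose context contains
    N are excluded and counted.
    """
    counts96 = dict.fromkeys(SPECTRUM_CLASSES_96, 0)
    n_edge = 0
    n_mismatch = 0
    for row in mutations.itertuples(index=False):
        chrom_len = genome.chrom_lengths[row.chrom]
        pos = int(row.pos)
        if pos == 0 or pos == chrom_len - 1:
            n_edge += 1
            continue
        context = genome.sequence(row.chrom, pos - 1, pos + 2)
        ref, alt = row.ref, row.alt
        if context[1] != ref or "N" in context:
            n_mismatch += 1
            continue
        if ref not in PYRIMIDINES:
            context = _revcomp(context)
            ref = context[1]
            alt = alt.translate(_COMPLEMENT)
        counts96[f"{context[0]}[{ref}>{alt}]{context[2]}"] += 1

    counts_96 = pd.Series(counts96, name="count").reindex(SPECTRUM_CLASSES_96)
    change = counts_96.index.str.slice(2, 5)
    counts_6 = (
        counts_96.groupby(change).sum().reindex(SPECTRUM_CLASSES_6).rename("count")
    )
    return SpectrumCounts(counts_96, counts_6, n_edge, n_mismatch)


def category_mutation_shares(
    mutations: pd.DataFrame,
    window_labels: dict[tuple[str, int], str],
    width: int = 50,
) -> pd.DataFrame:
    """Per-category, per-cancer-type mutation percentages.

    ``window_labels`` maps (chrom, window_start) to a category label —
    conventionally RHM (recurrent and hypermutated), HM (hypermutated
    only) and OR (other regions).  Every mutation's window must be
    labeled.  Rows are categories, columns cancer-type cohorts; each row
    sums to 100.
    """
    win_start = (mutations["pos"] // width) * width
    keys = list(zip(mutations["chrom"], win_start))
    labels = []
    for key in keys:
        label = window_labels.get(key)
        if label is None:
            raise ValueError(f"unlabeled window {key[0]}:{key[1]}")
        labels.append(label)
    table = pd.crosstab(pd.Series(labels, name="category"),
                        mutations["cohort"].reset_index(drop=True))
    return table.div(table.sum(axis=1), axis=0) * 100.0


def region_category(hypermutated: bool, recurrent: bool) -> str:
    """Category label: RHM (both), HM (hypermutated only), OR (rest)."""
    if hypermutated and recurrent:
        return "RHM"
    if hypermutated:
        return "HM"
    return "OR"
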