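"""Somatic SNV ingestion, filtering, and window assignment.

Mutation calls arrive as a MAF-like TSV or a minimal VCF and are held in
a pandas DataFrame (columns ``sample``, ``cohort``, ``chrom``, ``pos``,
``ref``, ``alt``; positions 0-based).  Two cohort-level filters mirror
standard practice for merged pan-cancer call sets: removal of calls at
known germline-variant positions unless the position is also present in
a somatic catalogue, and removal of samples whose total burden falls
below a minimum (applied after the germline filter — order matters,
because the germline filter lowers per-sample counts).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals_io import GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "Mutation",
    "Cohort",
    "read_mutations",
    "filter_germline_positions",
    "filter_low_burden_samples",
    "assign_to_windows",
    "positions_from_bed",
]

MUTATION_COLUMNS = ["sample", "cohort", "chrom", "pos", "ref", "alt"]
_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class Mutation:
    """One somatic single-nucleotide variant with sample and cohort identity."""

    sample_id: str
    cohort: str
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref == alt is not a variant")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"non-SNV alleles {self.ref}>{self.alt}")
        if self.pos < 0:
            raise ValueError("negative position")


@dataclass
class Cohort:
    """A set of somatic SNVs across samples, plus processing metadata.

    ``df`` holds one row per mutation; ``meta`` accumulates filter
    reports (counts of dropped records, removed samples, ...).
    """

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in MUTATION_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)

    @property
    def samples(self) -> set[str]:
        return set(self.df["sample"].unique())

    @property
    def n_mutations(self) -> int:
        return len(self.df)

    @property
    def cohort_labels(self) -> set[str]:
        return set(self.df["cohort"].unique())

    def mutations(self) -> list[Mutation]:
        return [
            Mutation(r.sample, r.cohort, r.chrom, int(r.pos), r.ref, r.alt)
            for r in self.df.itertuples(index=False)
        ]

    def subset_cohort(self, label: str) -> "Cohort":
        sub = self.df[self.df["cohort"] == label]
        if sub.empty:
            raise ValueError(f"no mutations for cohort {label!r}")
        return Cohort(sub.copy(), dict(self.meta))


def _finalize(df: pd.DataFrame, meta: dict) -> Cohort:
    """Validate SNV-ness, drop non-SNVs/invalid records, collapse duplicates."""
    df = df.copy()
    df["ref"] = df["ref"].astype(str).str.upper()
    df["alt"] = df["alt"].astype(str).str.upper()
    df["pos"] = df["pos"].astype(np.int64)

    is_snv = df["ref"].isin(_BASES) & df["alt"].isin(_BASES)
    n_non_snv = int((~is_snv).sum())
    if n_non_snv:
        logger.warning("%d non-SNV record(s) dropped", n_non_snv)
    df = df[is_snv]

    ref_eq_alt = df["ref"] == df["alt"]
    n_ref_eq_alt = int(ref_eq_alt.sum())
    if n_ref_eq_alt:
        warnings.warn(f"{n_ref_eq_alt} record(s) with ref == alt rejected")
        df = df[~ref_eq_alt]

    n_before = len(df)
    df = df.drop_duplicates(subset=["sample", "chrom", "pos", "alt"])
    n_dup = n_before - len(df)
    if n_dup:
        warnings.warn(f"{n_dup} duplicate record(s) collapsed")

    # a sample id appearing under two cohort labels usually means a merge error
    per_sample = df.groupby("sample")["cohort"].nunique()
    multi = per_sample[per_sample > 1]
    if len(multi):
        warnings.warn(
            f"sample id(s) appear in multiple cohorts: {sorted(multi.index)}"
        )

    meta = dict(meta)
    meta.update(
        n_non_snv_dropped=n_non_snv,
        n_ref_eq_alt_rejected=n_ref_eq_alt,
        n_duplicates_collapsed=n_dup,
    )
    return Cohort(df.sort_values(["chrom", "pos", "sample"]), meta)


def read_mutations(path, format: str = "maf_like_tsv", sample: str | None = None) -> Cohort:
    """Read somatic SNV calls.

    ``maf_like_tsv``: header line with columns sample, chrom, pos (0-based),
    ref, alt and optionally cohort.  ``vcf_minimal``: CHROM/POS/REF/ALT with
    1-based POS converted on read; the sample id comes from a SAMPLE INFO
    key or, failing that, from the ``sample`` argument.
    """
    if format == "maf_like_tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        required = ["sample", "chrom", "pos", "ref", "alt"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"missing required column(s): {missing}")
        if "cohort" not in df.columns:
            df["cohort"] = "default"
        return _finalize(df[MUTATION_COLUMNS], {"source": str(path)})

    if format == "vcf_minimal":
        from cyvcf2 import VCF

        rows = []
        for variant in VCF(str(path)):
            info_sample = variant.INFO.get("SAMPLE")
            sid = info_sample if info_sample is not None else sample
            if sid is None:
                raise ValueError(
                    "VCF record lacks a SAMPLE INFO key and no sample was given"
                )
            for alt in variant.ALT:
                rows.append(
                    {
                        "sample": sid,
                        "cohort": "default",
                        "chrom": variant.CHROM,
                        "pos": variant.POS - 1,  # 1-based -> 0-based
                        "ref": variant.REF,
                        "alt": alt,
                    }
                )
        df = pd.DataFrame(rows, columns=MUTATION_COLUMNS)
        return _finalize(df, {"source": str(path)})

    raise ValueError(f"unknown format {format!r}")


def positions_from_bed(intervals: list[GenomicInterval]) -> set[tuple[str, int]]:
    """Expand BED intervals to the per-base position set they cover."""
    positions: set[tuple[str, int]] = set()
    for iv in intervals:
        for pos in range(iv.start, iv.end):
            positions.add((iv.chrom, pos))
    return positions


def _position_mask(df: pd.DataFrame, positions: set[tuple[str, int]]) -> np.ndarray:
    """Boolean mask of rows whose (chrom, pos) is in ``positions``."""
    if not positions:
        return np.zeros(len(df), dtype=bool)
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in positions:
        by_chrom.setdefault(chrom, []).append(pos)  # type: ignore[arg-type]
    by_chrom = {c: np.asarray(sorted(p)) for c, p in by_chrom.items()}
    mask = np.zeros(len(df), dtype=bool)
    for chrom, sub in df.groupby("chrom", sort=False):
        sites = by_chrom.get(chrom)
        if sites is not None:
            mask[df.index.get_indexer(sub.index)] = np.isin(
                sub["pos"].to_numpy(), sites
            )
    return mask


def filter_germline_positions(
    cohort: Cohort,
    germline_positions: set[tuple[str, int]],
    somatic_catalogue_positions: set[tuple[str, int]] = frozenset(),
) -> Cohort:
    """Drop mutations at known germline-variant positions.

    A mutation is removed iff its position is a germline site AND is not
    present in the somatic catalogue (the catalogue rescues positions
    known to be recurrently somatically mutated).  Matching is by
    position only — alleles are deliberately ignored, so two different
    alt alleles at one germline site are both removed.
    """
    df = cohort.df.reset_index(drop=True)
    in_germline = _position_mask(df, germline_positions)
    in_catalogue = _position_mask(df, somatic_catalogue_positions)
    remove = in_germline & ~in_catalogue

    removed_per_cohort = (
        df.loc[remove, "cohort"].value_counts().to_dict() if remove.any() else {}
    )
    if remove.any():
        logger.info(
            "germline-position filter removed %d mutation(s): %s",
            int(remove.sum()),
            removed_per_cohort,
        )
    meta = dict(cohort.meta)
    meta["germline_removed_per_cohort"] = removed_per_cohort
    meta["germline_removed_total"] = int(remove.sum())
    return Cohort(df[~remove], meta)


def filter_low_burden_samples(cohort: Cohort, min_mutations: int) -> Cohort:
    """Remove samples with fewer than ``min_mutations`` total mutations.

    Samples with exactly ``min_mutations`` are retained.  Applied after
    the germline-position filter.
    """
    counts = cohort.df["sample"].value_counts()
    keep = set(counts[counts >= min_mutations].index)
    removed = sorted(set(counts.index) - keep)
    df = cohort.df[cohort.df["sample"].isin(keep)]
    if df.empty:
        raise ValueError("empty cohort: every sample fell below the burden minimum")
    if removed:
        logger.info(
            "burden filter (< %d mutations) removed %d sample(s)",
            min_mutations,
            len(removed),
        )
    meta = dict(cohort.meta)
    meta["low_burden_samples_removed"] = removed
    meta["surviving_samples"] = sorted(keep)
    return Cohort(df, meta)


def assign_to_windows(
    cohort: Cohort, windows: list[GenomicInterval]
) -> dict[GenomicInterval, pd.DataFrame]:
    """Assign each mutation to the unique window containing it.

    Windows must be non-overlapping and sorted by (chrom, start).
    Mutations on chromosomes absent from the window set are dropped with
    a logged count.  Returns only windows that received >= 1 mutation.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    for chrom, ws in by_chrom.items():
        for a, b in zip(ws, ws[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping windows {a} and {b}")
            if b.start < a.start:
                raise ValueError("windows not sorted by start")

    out: dict[GenomicInterval, pd.DataFrame] = {}
    n_unassigned = 0
    for chrom, sub in cohort.df.groupby("chrom", sort=False):
        ws = by_chrom.get(chrom)
        if ws is None:
            n_unassigned += len(sub)
            continue
        starts = np.array([w.start for w in ws])
        ends = np.array([w.end for w in ws])
        pos = sub["pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        n_unassigned += int((~inside).sum())
        for i in np.unique(idx[inside]):
            out[ws[i]] = sub[inside & (idx == i)].copy()
    if n_unassigned:
        logger.info("%d mutation(s) fell outside the window grid", n_unassigned)
    return out
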