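"""Recurrence, conservation, and combined hotspot scores.

The central statistic is a *recurrence score* for each fixed-width
genomic window: the window's mutation rate divided by the mutation rate
of its flanking region,

    raw_score = (T / T0) / ((L + R) / (L0 + R0))

where T is the number of mutations in the window, T0 the window length,
L and R the mutation counts in the left and right flanks (0.5 Mb each by
default, truncated at chromosome ends, restricted to bases whose
mappability passes a threshold), and L0, R0 the valid-base lengths of
those flanks.  Dividing by the local flanking rate normalizes away
mutational processes that vary smoothly over large genomic scales, so
the score measures *focal* enrichment.

A parallel *conservation score* is the mean of a per-base conservation
track (PhyloP-like: positive = conserved, negative = accelerated) taken
over the mutations in the window — per mutation, not per distinct base,
so a base mutated in k samples contributes k terms.

Raw scores are made comparable by robust standardization over the
candidate set: subtract the median and divide by the median absolute
deviation (scaled by the 1.4826 normal-consistency constant).  The
*combined score* is the simple average of the two normalized scores.

Candidate windows are those mutated in at least ``min_samples`` distinct
samples with mean mutation mappability at or above a threshold; windows
failing these filters are never scored (their sparse or unreliable calls
cannot support a recurrence claim).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals_io import GenomeIndex, GenomicInterval, FlankStats, ScoreTrack
from .mutations import Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreParams",
    "WindowStats",
    "ScoreRecord",
    "compute_window_stats",
    "candidate_filter",
    "raw_recurrence",
    "raw_conservation",
    "normalize",
    "combined_score",
    "score_pipeline",
    "top_regions",
]

#: flag labels attached to score records
FLAG_NO_VALID_FLANK = "no_valid_flank"
FLAG_NO_FLANK_MUTATIONS = "no_flank_mutations"
FLAG_NO_CONSERVATION = "no_conservation_values"
FLAG_DEGENERATE_NORM = "degenerate_normalization"


@dataclass
class ScoreParams:
    """Tunable parameters of the scoring pipeline.

    Defaults are the canonical analysis settings: 50-bp windows, 0.5-Mb
    flanks, candidate windows mutated in >= 3 patients with mean
    mappability >= 0.5, MAD scaled by the normal-consistency constant.
    """

    window_width: int = 50
    flank_size: int = 500_000
    min_samples: int = 3
    min_mean_mappability: float = 0.5
    mad_constant: float = 1.4826
    rank_by: str = "recurrence"  # "recurrence" | "combined"
    conservation_per_position: bool = False
    exclude_flank_intervals: list[GenomicInterval] | None = None
    exclude_high_burden_samples: bool = False

    def __post_init__(self) -> None:
        if self.rank_by not in ("recurrence", "combined"):
            raise ValueError("rank_by must be 'recurrence' or 'combined'")
        if self.window_width < 1 or self.flank_size < 1:
            raise ValueError("window_width and flank_size must be >= 1")


@dataclass(frozen=True)
class WindowStats:
    """Per-window mutation tallies feeding the raw scores."""

    window: GenomicInterval
    T: int
    n_samples: int
    mean_mappability: float
    mean_conservation: float

    @property
    def T0(self) -> int:
        return self.window.length

    def __post_init__(self) -> None:
        if self.n_samples > self.T:
            raise ValueError("distinct samples cannot exceed mutation count")


@dataclass(frozen=True)
class ScoreRecord:
    """Raw and normalized scores for one candidate window."""

    window: GenomicInterval
    T: int
    n_samples: int
    raw_recurrence: float
    norm_recurrence: float
    raw_conservation: float
    norm_conservation: float
    combined: float
    flags: frozenset[str] = field(default_factory=frozenset)
    rank: int | None = None


def _nanmean_or_nan(values: np.ndarray) -> float:
    defined = values[~np.isnan(values)]
    return float(defined.mean()) if defined.size else float("nan")


def compute_window_stats(
    cohort: Cohort,
    genome: GenomeIndex,
    width: int = 50,
    mappability: ScoreTrack | None = None,
    conservation: ScoreTrack | None = None,
    per_position_conservation: bool = False,
) -> pd.DataFrame:
    """Tally mutations into fixed-width windows.

    Returns one row per window with >= 1 mutation: chrom, start, end, T,
    n_samples, mean_mappability, mean_conservation.  Track means are over
    mutations (missing values excluded; all-missing gives NaN).  With no
    mappability track every mutation counts as fully mappable.  In
    per-position mode the conservation mean is over distinct mutated
    bases instead of mutations.
    """
    rows = []
    for chrom, sub in cohort.df.groupby("chrom", sort=True):
        chrom_len = genome.chrom_lengths.get(chrom)
        if chrom_len is None:
            logger.info("dropping %d mutation(s) on unknown chromosome %s",
                        len(sub), chrom)
            continue
        pos = sub["pos"].to_numpy()
        if pos.max() >= chrom_len:
            raise ValueError(f"mutation position beyond end of {chrom}")
        widx = pos // width
        map_vals = (
            mappability.values_at(chrom, pos)
            if mappability is not None
            else np.ones(pos.size)
        )
        cons_vals = (
            conservation.values_at(chrom, pos)
            if conservation is not None
            else np.full(pos.size, np.nan)
        )
        samples = sub["sample"].to_numpy()
        order = np.argsort(widx, kind="stable")
        widx, pos, map_vals, cons_vals, samples = (
            widx[order], pos[order], map_vals[order], cons_vals[order],
            samples[order],
        )
        bounds = np.flatnonzero(np.diff(widx)) + 1
        for grp_pos, grp_map, grp_cons, grp_samp, grp_idx in zip(
            np.split(pos, bounds),
            np.split(map_vals, bounds),
            np.split(cons_vals, bounds),
            np.split(samples, bounds),
            np.split(widx, bounds),
        ):
            w = int(grp_idx[0])
            start = w * width
            if per_position_conservation:
                _, first = np.unique(grp_pos, return_index=True)
                cons = _nanmean_or_nan(grp_cons[first])
            else:
                cons = _nanmean_or_nan(grp_cons)
            rows.append(
                (
                    chrom,
                    start,
                    min(start + width, chrom_len),
                    grp_pos.size,
                    len(set(grp_samp)),
                    _nanmean_or_nan(grp_map),
                    cons,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "T", "n_samples",
            "mean_mappability", "mean_conservation",
        ],
    )


def candidate_filter(
    stats: pd.DataFrame,
    min_samples: int = 3,
    min_mean_mappability: float = 0.5,
    require_conservation: bool = False,
) -> pd.DataFrame:
    """Retain windows eligible for scoring.

    A candidate must be mutated in >= ``min_samples`` distinct samples
    and have mean mutation mappability >= ``min_mean_mappability``
    (boundary inclusive: 0.50 passes, 0.49 does not).  Windows whose
    mappability mean is undefined (all values missing) are excluded, as
    are — when ``require_conservation`` — windows with an undefined
    conservation mean.
    """
    if stats.empty:
        return stats
    keep = (
        (stats["n_samples"] >= min_samples)
        & stats["mean_mappability"].notna()
        & (stats["mean_mappability"] >= min_mean_mappability)
    )
    if require_conservation:
        keep &= stats["mean_conservation"].notna()
    return stats[keep].reset_index(drop=True)


def raw_recurrence(T: int, T0: int, flank: FlankStats) -> float:
    """Focal enrichment ratio: window mutation rate over flanking rate.

    Returns NaN (undefined) when the flanks contain no valid bases or no
    mutations; callers flag those windows rather than ranking them.
    """
    if T0 < 1:
        raise ValueError("T0 must be >= 1")
    n_flank = flank.left_mutations + flank.right_mutations
    len_flank = flank.left_valid_bases + flank.right_valid_bases
    if len_flank == 0 or n_flank == 0:
        return float("nan")
    return (T / T0) / (n_flank / len_flank)


def raw_conservation(positions, conservation: ScoreTrack, chrom: str | None = None) -> float:
    """Mean conservation-track value over a window's mutations.

    ``positions`` is one entry per *mutation* (repeat a base mutated in
    several samples), as (chrom, pos) pairs or bare positions with
    ``chrom`` given.  Missing track values are excluded from the mean;
    NaN is returned when every value is missing.
    """
    values = []
    for p in positions:
        c, pos = p if chrom is None else (chrom, p)
        values.append(conservation.at(c, pos))
    return _nanmean_or_nan(np.asarray(values, dtype=float))


def normalize(values, mad_constant: float = 1.4826) -> np.ndarray:
    """Robust standardization: (v - median) / MAD over the defined values.

    The MAD is scaled by ``mad_constant`` (1.4826 makes it a consistent
    estimator of the normal standard deviation; pass 1.0 for the plain
    MAD).  NaN inputs propagate as NaN.  Raises on fewer than two defined
    values or a zero MAD.
    """
    v = np.asarray(values, dtype=float)
    defined = v[~np.isnan(v)]
    if defined.size < 2:
        raise ValueError("need at least 2 defined values to normalize")
    med = np.median(defined)
    mad = np.median(np.abs(defined - med)) * mad_constant
    if mad == 0:
        raise ValueError("degenerate score distribution: MAD is zero")
    return (v - med) / mad


def combined_score(norm_recurrence: float, norm_conservation: float) -> float:
    """Simple average of the two normalized scores (NaN if either is NaN)."""
    return (norm_recurrence + norm_conservation) / 2.0


def _chrom_flank_stats(
    starts: np.ndarray,
    ends: np.ndarray,
    chrom: str,
    chrom_len: int,
    mut_positions: np.ndarray,
    flank_size: int,
    mappability: ScoreTrack | None,
    min_mappability: float,
    exclude: list[GenomicInterval] | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized L+R and L0+R0 for all candidate windows on one chromosome.

    Counts only mutations at valid flank bases; valid = mappability >=
    threshold (missing invalid) and outside any excluded interval.
    """
    if mappability is not None:
        vals = mappability.values(chrom, 0, chrom_len)
        valid = ~np.isnan(vals) & (vals >= min_mappability)
    else:
        valid = np.ones(chrom_len, dtype=bool)
    if exclude:
        for iv in exclude:
            if iv.chrom == chrom:
                valid[iv.start : min(iv.end, chrom_len)] = False

    cum_valid = np.concatenate([[0], np.cumsum(valid)])
    valid_mut = np.sort(mut_positions[valid[mut_positions]])

    lstart = np.maximum(0, starts - flank_size)
    rend = np.minimum(chrom_len, ends + flank_size)
    n_valid = (cum_valid[starts] - cum_valid[lstart]) + (
        cum_valid[rend] - cum_valid[ends]
    )
    n_mut = (
        np.searchsorted(valid_mut, starts) - np.searchsorted(valid_mut, lstart)
    ) + (np.searchsorted(valid_mut, rend) - np.searchsorted(valid_mut, ends))
    return n_mut, n_valid


def _exclude_high_burden(cohort: Cohort) -> Cohort:
    """Drop samples whose burden exceeds mean + 2 SD (robustness recount)."""
    counts = cohort.df["sample"].value_counts()
    cutoff = counts.mean() + 2 * counts.std(ddof=1)
    keep = set(counts[counts <= cutoff].index)
    removed = sorted(set(counts.index) - keep)
    if removed:
        logger.info("excluding %d high-burden sample(s): %s", len(removed), removed)
    meta = dict(cohort.meta)
    meta["high_burden_samples_excluded"] = removed
    return Cohort(cohort.df[cohort.df["sample"].isin(keep)], meta)


def score_pipeline(
    cohort: Cohort,
    genome: GenomeIndex,
    mappability: ScoreTrack | None = None,
    conservation: ScoreTrack | None = None,
    params: ScoreParams | None = None,
) -> pd.DataFrame:
    """Run the full window-scoring chain and return a ranked table.

    Chain: assign mutations to windows -> per-window stats -> candidate
    filter -> flanking rates -> raw scores -> median/MAD normalization
    over candidates -> combined score -> deterministic ranking (chosen
    score descending, ties broken by (chrom, start)).

    Columns: rank, chrom, start, end, T, n_samples,
    mutations_per_sample, mean_mappability, raw_recurrence,
    norm_recurrence, raw_conservation, norm_conservation, combined,
    flags.  Windows with an undefined recurrence score (empty or
    mutation-free flanks) carry an explanatory flag and are excluded
    from normalization.  If fewer than two candidates have defined raw
    scores, or their spread is zero, normalized columns are NaN and
    every record is flagged ``degenerate_normalization``.
    """
    params = params or ScoreParams()
    if params.rank_by == "combined" and conservation is None:
        raise ValueError("ranking by combined score requires a conservation track")
    if params.exclude_high_burden_samples:
        cohort = _exclude_high_burden(cohort)

    stats = compute_window_stats(
        cohort,
        genome,
        width=params.window_width,
        mappability=mappability,
        conservation=conservation,
        per_position_conservation=params.conservation_per_position,
    )
    cand = candidate_filter(
        stats,
        min_samples=params.min_samples,
        min_mean_mappability=params.min_mean_mappability,
        require_conservation=conservation is not None,
    )
    if cand.empty:
        raise ValueError("no candidate windows after filtering")
    cand = cand.copy()

    n_mut = np.zeros(len(cand), dtype=np.int64)
    n_valid = np.zeros(len(cand), dtype=np.int64)
    for chrom, sub in cand.groupby("chrom", sort=False):
        mut_positions = cohort.df.loc[
            cohort.df["chrom"] == chrom, "pos"
        ].to_numpy()
        m, v = _chrom_flank_stats(
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            chrom,
            genome.chrom_lengths[chrom],
            mut_positions,
            params.flank_size,
            mappability,
            params.min_mean_mappability,
            params.exclude_flank_intervals,
        )
        idx = cand.index.get_indexer(sub.index)
        n_mut[idx], n_valid[idx] = m, v

    T = cand["T"].to_numpy()
    T0 = (cand["end"] - cand["start"]).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        raw_rec = np.where(
            (n_valid > 0) & (n_mut > 0),
            (T / T0) / np.where(n_valid > 0, n_mut / np.maximum(n_valid, 1), np.nan),
            np.nan,
        )
    flags = [set() for _ in range(len(cand))]
    for i in np.flatnonzero(n_valid == 0):
        flags[i].add(FLAG_NO_VALID_FLANK)
    for i in np.flatnonzero((n_valid > 0) & (n_mut == 0)):
        flags[i].add(FLAG_NO_FLANK_MUTATIONS)
    if conservation is not None:
        for i in np.flatnonzero(cand["mean_conservation"].isna().to_numpy()):
            flags[i].add(FLAG_NO_CONSERVATION)

    raw_cons = cand["mean_conservation"].to_numpy()

    def _try_normalize(values: np.ndarray) -> np.ndarray | None:
        try:
            return normalize(values, mad_constant=params.mad_constant)
        except ValueError:
            return None

    norm_rec = _try_normalize(raw_rec)
    norm_cons = _try_normalize(raw_cons) if conservation is not None else None
    degenerate = norm_rec is None or (conservation is not None and norm_cons is None)
    if degenerate:
        norm_rec = np.full(len(cand), np.nan)
        norm_cons = np.full(len(cand), np.nan)
        for f in flags:
            f.add(FLAG_DEGENERATE_NORM)
        logger.warning("normalization degenerate; normalized scores undefined")
    elif norm_cons is None:
        norm_cons = np.full(len(cand), np.nan)

    combined = (norm_rec + norm_cons) / 2.0

    out = cand.copy()
    out["mutations_per_sample"] = out["T"] / out["n_samples"]
    out["raw_recurrence"] = raw_rec
    out["norm_recurrence"] = norm_rec
    out["raw_conservation"] = raw_cons
    out["norm_conservation"] = norm_cons
    out["combined"] = combined
    out["flags"] = [",".join(sorted(f)) for f in flags]

    sort_col = "raw_recurrence" if params.rank_by == "recurrence" else "combined"
    # NaN scores sort last; ties broken by coordinate for reproducible tables
    out["_key"] = -out[sort_col]
    out = out.sort_values(
        ["_key", "chrom", "start"], na_position="last", kind="mergesort"
    ).drop(columns="_key")
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out.reset_index(drop=True)


def top_regions(scores: pd.DataFrame, k: int) -> list[GenomicInterval]:
    """The top-k ranked windows as intervals (for BED export)."""
    head = scores.nsmallest(k, "rank")
    return [
        GenomicInterval(r.chrom, int(r.start), int(r.end))
        for r in head.itertuples(index=False)
    ]
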