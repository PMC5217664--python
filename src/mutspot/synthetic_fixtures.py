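"""Self-contained synthetic genomes, tracks, and mutation cohorts.

The generator emulates the structure of a pan-cancer whole-genome call
set at desk scale: several cancer-type cohorts whose per-sample mutation
burdens spread over orders of magnitude (lognormal rate multipliers),
uniform or piecewise-regional background mutation placement, planted
mutually-exclusive hotspots (one mutation per hit sample — the signature
of selection on activating events), planted multi-hit hypermutated foci
(several mutations per hit sample — the signature of a focal mutational
process), conserved elements and low-mappability stretches in the
per-base tracks, and contamination of the call set with mutations at
germline-variant positions, a fraction of which are rescued by presence
in a somatic catalogue.

Background placement skips planted intervals, so planted multiplicity is
exact: hotspot regions carry exactly one mutation per hit sample.  Every
output is reproducible from the seed and parses with this package's own
readers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals_io import (
    GenomeIndex,
    GenomicInterval,
    ScoreTrack,
    write_bed,
    write_bedgraph,
    write_chrom_sizes,
    write_fasta,
)
from .mutations import Cohort

__all__ = [
    "PlantedRegion",
    "SimulationConfig",
    "SyntheticDataset",
    "TruthTables",
    "simulate_cohort",
    "truth_eval",
]

_BASES_S1 = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class PlantedRegion:
    """A region with a planted mutation pattern.

    ``mutations_per_hit`` = 1 plants a mutually-exclusive hotspot; >= 2
    plants a hypermutated focus.  ``cohort`` restricts the hit samples
    to one cancer type (None draws from the whole cohort).
    """

    interval: GenomicInterval
    n_samples_hit: int
    mutations_per_hit: int = 1
    cohort: str | None = None

    def __post_init__(self) -> None:
        if self.n_samples_hit < 1 or self.mutations_per_hit < 1:
            raise ValueError("n_samples_hit and mutations_per_hit must be >= 1")
        if self.mutations_per_hit > self.interval.length:
            raise ValueError(
                f"planted load {self.mutations_per_hit} exceeds capacity of "
                f"{self.interval}"
            )


@dataclass
class SimulationConfig:
    """Study conditions of a synthetic cohort.

    Defaults describe a desk-scale pan-cancer set: three cohorts of 30
    samples on a 2 x 1 Mb genome, background 1e-5 mutations/bp/sample
    with lognormal burden dispersion (sigma 1.15, mean-1 multipliers,
    giving a roughly thousand-fold burden spread across cohort tails),
    and 5% germline-position contamination over germline sites covering
    0.2% of the genome, 10% of which also appear in the somatic
    catalogue.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    cohorts: dict[str, int] = field(
        default_factory=lambda: {"BRCA-UK": 30, "MALY-DE": 30, "PACA-AU": 30}
    )
    background_rate: float = 1e-5  # mutations / bp / sample
    burden_sigma: float = 1.15  # lognormal sigma of per-sample rate multipliers
    planted_hotspots: list[PlantedRegion] = field(default_factory=list)
    planted_hypermut: list[PlantedRegion] = field(default_factory=list)
    conserved_elements: list[tuple[GenomicInterval, float]] = field(default_factory=list)
    low_mappability: list[GenomicInterval] = field(default_factory=list)
    rate_map: list[tuple[GenomicInterval, float]] = field(default_factory=list)
    germline_contamination_rate: float = 0.05
    n_germline_sites: int | None = None  # default: 0.2% of genome length
    catalogue_fraction: float = 0.1
    driver_exons: list[GenomicInterval] = field(default_factory=list)
    conservation_tile: int = 200  # bp; baseline noise resolution
    conservation_noise_sd: float = 0.5
    low_mappability_value: float = 0.1

    def chrom_name(self, i: int) -> str:
        return f"chr{i + 1}"

    def validate(self, genome: GenomeIndex) -> None:
        n_total = sum(self.cohorts.values())
        for planted in self.planted_hotspots + self.planted_hypermut:
            genome.check_interval(planted.interval)
            pool = (
                self.cohorts.get(planted.cohort, 0)
                if planted.cohort is not None
                else n_total
            )
            if planted.n_samples_hit > pool:
                raise ValueError(
                    f"planted region {planted.interval} needs "
                    f"{planted.n_samples_hit} samples but only {pool} available"
                )
        for iv, _ in self.conserved_elements + self.rate_map:
            genome.check_interval(iv)
        for iv in self.low_mappability + self.driver_exons:
            genome.check_interval(iv)
        if self.background_rate < 0 or self.germline_contamination_rate < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class TruthTables:
    """Ground truth of planted structure, aligned to the genome."""

    hotspots: pd.DataFrame  # chrom start end n_samples_hit mutations_per_hit cohort
    hypermut: pd.DataFrame
    n_contaminant: int = 0

    @staticmethod
    def _frame(regions: list[PlantedRegion]) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": r.interval.chrom,
                    "start": r.interval.start,
                    "end": r.interval.end,
                    "n_samples_hit": r.n_samples_hit,
                    "mutations_per_hit": r.mutations_per_hit,
                    "cohort": r.cohort or "",
                }
                for r in regions
            ],
            columns=["chrom", "start", "end", "n_samples_hit",
                     "mutations_per_hit", "cohort"],
        )


@dataclass
class SyntheticDataset:
    """In-memory bundle of everything a pipeline run consumes."""

    config: SimulationConfig
    genome: GenomeIndex
    cohort: Cohort
    conservation: ScoreTrack
    mappability: ScoreTrack
    germline_sites: list[tuple[str, int]]
    catalogue_sites: list[tuple[str, int]]
    driver_exons: list[GenomicInterval]
    truth: TruthTables

    def write(self, outdir) -> dict[str, str]:
        """Write the bundle as text files; returns name -> path."""
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "genome_fasta": os.path.join(outdir, "genome.fa"),
            "chrom_sizes": os.path.join(outdir, "genome.chrom.sizes"),
            "mutations": os.path.join(outdir, "mutations.tsv"),
            "conservation": os.path.join(outdir, "conservation.bedgraph"),
            "mappability": os.path.join(outdir, "mappability.bedgraph"),
            "germline": os.path.join(outdir, "germline.bed"),
            "catalogue": os.path.join(outdir, "catalogue.bed"),
            "driver_exons": os.path.join(outdir, "driver_exons.bed"),
            "truth_hotspots": os.path.join(outdir, "truth_hotspots.tsv"),
            "truth_hypermut": os.path.join(outdir, "truth_hypermut.tsv"),
        }
        write_fasta(self.genome, paths["genome_fasta"])
        write_chrom_sizes(self.genome, paths["chrom_sizes"])
        self.cohort.df.to_csv(paths["mutations"], sep="\t", index=False)
        write_bedgraph(self.conservation, paths["conservation"])
        write_bedgraph(self.mappability, paths["mappability"])
        write_bed(
            [GenomicInterval(c, p, p + 1) for c, p in self.germline_sites],
            paths["germline"],
        )
        write_bed(
            [GenomicInterval(c, p, p + 1) for c, p in self.catalogue_sites],
            paths["catalogue"],
        )
        write_bed(self.driver_exons, paths["driver_exons"])
        self.truth.hotspots.to_csv(paths["truth_hotspots"], sep="\t", index=False)
        self.truth.hypermut.to_csv(paths["truth_hypermut"], sep="\t", index=False)
        return paths


def _sample_ids(config: SimulationConfig) -> pd.DataFrame:
    rows = [
        {"sample": f"{label}_S{i:03d}", "cohort": label}
        for label in sorted(config.cohorts)
        for i in range(config.cohorts[label])
    ]
    return pd.DataFrame(rows)


def simulate_cohort(config: SimulationConfig) -> SyntheticDataset:
    """Generate a synthetic dataset under ``config``.

    Background mutations are placed per sample at rate
    background_rate x multiplier (lognormal with unit mean), uniformly
    within chromosomes except where ``rate_map`` rescales the local rate
    and excluding planted intervals (so planted multiplicity is exact).
    """
    rng = np.random.default_rng(config.seed)

    chrom_names = [config.chrom_name(i) for i in range(config.n_chromosomes)]
    if not chrom_names:
        raise ValueError("need at least one chromosome")
    sequences = {
        c: _BASES_S1[rng.integers(0, 4, config.chrom_length)]
        .tobytes()
        .decode("ascii")
        for c in chrom_names
    }
    genome = GenomeIndex({c: config.chrom_length for c in chrom_names}, sequences)
    config.validate(genome)

    samples = _sample_ids(config)
    n_samples = len(samples)
    if n_samples == 0:
        raise ValueError("no samples configured")

    # per-base placement weights: rate-map rescaling, planted regions excluded
    weights = {c: np.ones(config.chrom_length) for c in chrom_names}
    for iv, mult in config.rate_map:
        if mult < 0:
            raise ValueError("rate-map multipliers must be >= 0")
        weights[iv.chrom][iv.start : iv.end] = mult
    for planted in config.planted_hotspots + config.planted_hypermut:
        iv = planted.interval
        weights[iv.chrom][iv.start : iv.end] = 0.0
    flat_weights = np.concatenate([weights[c] for c in chrom_names])
    cum_weights = np.cumsum(flat_weights)
    total_weight = cum_weights[-1]
    chrom_offsets = {
        c: i * config.chrom_length for i, c in enumerate(chrom_names)
    }

    def flat_to_chrom(flat_pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        chrom_idx = flat_pos // config.chrom_length
        return chrom_idx, flat_pos % config.chrom_length

    multipliers = rng.lognormal(
        mean=-config.burden_sigma**2 / 2, sigma=config.burden_sigma, size=n_samples
    )

    rows: list[pd.DataFrame] = []

    def add_mutations(sample, cohort_label, chroms, positions):
        refs = [sequences[c][p] for c, p in zip(chroms, positions)]
        # alt drawn uniformly from the three non-reference bases
        alt_choice = rng.integers(0, 3, size=len(refs))
        alts = []
        for ref, k in zip(refs, alt_choice):
            others = [b for b in "ACGT" if b != ref]
            alts.append(others[k])
        rows.append(
            pd.DataFrame(
                {
                    "sample": sample,
                    "cohort": cohort_label,
                    "chrom": chroms,
                    "pos": positions,
                    "ref": refs,
                    "alt": alts,
                }
            )
        )

    # germline sites and somatic-catalogue overlap
    genome_len = config.n_chromosomes * config.chrom_length
    n_sites = (
        config.n_germline_sites
        if config.n_germline_sites is not None
        else max(1, round(0.002 * genome_len))
    )
    site_flat = rng.choice(genome_len, size=n_sites, replace=False)
    site_flat.sort()
    site_chrom_idx, site_pos = flat_to_chrom(site_flat)
    germline_sites = [
        (chrom_names[ci], int(p)) for ci, p in zip(site_chrom_idx, site_pos)
    ]
    n_catalogue = round(config.catalogue_fraction * n_sites)
    cat_idx = rng.choice(n_sites, size=n_catalogue, replace=False)
    catalogue_sites = sorted(germline_sites[i] for i in cat_idx)

    # background + germline contamination, per sample
    expected = config.background_rate * total_weight
    n_contaminant_total = 0
    for (sample, cohort_label), mult in zip(
        samples.itertuples(index=False), multipliers
    ):
        n_bg = rng.poisson(expected * mult)
        if n_bg:
            u = rng.random(n_bg) * total_weight
            flat_pos = np.searchsorted(cum_weights, u, side="right")
            chrom_idx, positions = flat_to_chrom(flat_pos)
            add_mutations(
                sample, cohort_label,
                [chrom_names[ci] for ci in chrom_idx], positions,
            )
        n_contam = rng.poisson(config.germline_contamination_rate * n_bg)
        if n_contam:
            picked = rng.integers(0, n_sites, size=n_contam)
            add_mutations(
                sample, cohort_label,
                [germline_sites[i][0] for i in picked],
                np.array([germline_sites[i][1] for i in picked]),
            )
            n_contaminant_total += n_contam

    # planted structure
    def plant(planted: PlantedRegion) -> None:
        pool = (
            samples[samples["cohort"] == planted.cohort]
            if planted.cohort is not None
            else samples
        )
        hit = pool.iloc[
            rng.choice(len(pool), size=planted.n_samples_hit, replace=False)
        ]
        iv = planted.interval
        for sample, cohort_label in hit.itertuples(index=False):
            positions = iv.start + rng.choice(
                iv.length, size=planted.mutations_per_hit, replace=False
            )
            add_mutations(
                sample, cohort_label, [iv.chrom] * planted.mutations_per_hit,
                np.sort(positions),
            )

    for planted in config.planted_hotspots:
        plant(planted)
    for planted in config.planted_hypermut:
        plant(planted)

    df = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["sample", "cohort", "chrom", "pos", "ref", "alt"])
    )
    df["pos"] = df["pos"].astype(np.int64)
    df = df.drop_duplicates(subset=["sample", "chrom", "pos", "alt"])
    df = df.sort_values(["chrom", "pos", "sample"]).reset_index(drop=True)
    cohort = Cohort(df, {"synthetic_seed": config.seed})

    # conservation: piecewise tile noise, elevated in conserved elements
    cons_arrays = {}
    for c in chrom_names:
        n_tiles = -(-config.chrom_length // config.conservation_tile)
        tile_vals = np.round(
            rng.normal(0.0, config.conservation_noise_sd, n_tiles), 3
        )
        cons_arrays[c] = np.repeat(tile_vals, config.conservation_tile)[
            : config.chrom_length
        ]
    for iv, level in config.conserved_elements:
        cons_arrays[iv.chrom][iv.start : iv.end] = level
    conservation = ScoreTrack(cons_arrays)

    map_arrays = {c: np.ones(config.chrom_length) for c in chrom_names}
    for iv in config.low_mappability:
        map_arrays[iv.chrom][iv.start : iv.end] = config.low_mappability_value
    mappability = ScoreTrack(map_arrays)

    truth = TruthTables(
        TruthTables._frame(config.planted_hotspots),
        TruthTables._frame(config.planted_hypermut),
        n_contaminant=n_contaminant_total,
    )
    return SyntheticDataset(
        config, genome, cohort, conservation, mappability,
        germline_sites, catalogue_sites, list(config.driver_exons), truth,
    )


def truth_eval(
    scores: pd.DataFrame,
    truth: TruthTables,
    k: int = 10,
    width: int = 50,
    hypermut_threshold: float = 1.2,
) -> dict:
    """Evaluate a ranked score table against planted truth.

    Returns recall@k over planted hotspot windows (None when nothing was
    planted) and a confusion matrix for the hypermutation flag over all
    planted regions (hypermutated foci are positives, mutually-exclusive
    hotspots negatives; a planted region absent from the table counts as
    predicted non-hypermutated).
    """
    for frame in (truth.hotspots, truth.hypermut):
        for row in frame.itertuples(index=False):
            if row.start % width != 0 or row.end - row.start != width:
                raise ValueError(
                    f"planted region {row.chrom}:{row.start}-{row.end} is not "
                    f"aligned to the {width}-bp window grid"
                )

    key = list(zip(scores["chrom"], scores["start"]))
    rank_of = dict(zip(key, scores["rank"]))
    ratio_of = dict(zip(key, scores["mutations_per_sample"]))

    if len(truth.hotspots):
        hit = [
            rank_of.get((r.chrom, r.start), np.inf) <= k
            for r in truth.hotspots.itertuples(index=False)
        ]
        recall_at_k = float(np.mean(hit))
    else:
        recall_at_k = None

    def predicted_hyper(frame: pd.DataFrame) -> np.ndarray:
        return np.array(
            [
                ratio_of.get((r.chrom, r.start), 1.0) > hypermut_threshold
                for r in frame.itertuples(index=False)
            ],
            dtype=bool,
        )

    pred_pos = predicted_hyper(truth.hypermut)
    pred_neg = predicted_hyper(truth.hotspots)
    tp, fn = int(pred_pos.sum()), int((~pred_pos).sum())
    fp, tn = int(pred_neg.sum()), int((~pred_neg).sum())
    total = tp + fn + fp + tn
    return {
        "recall_at_k": recall_at_k,
        "k": k,
        "confusion": {"tp": tp, "fn": fn, "fp": fp, "tn": tn},
        "hypermut_accuracy": (tp + tn) / total if total else None,
    }
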