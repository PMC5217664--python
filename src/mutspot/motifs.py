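"""Position-weight-matrix scanning of reference vs mutant sequences.

Recurrently mutated regulatory regions often act through transcription
factor binding; a substitution that lowers (or raises) the best PWM
match score in a region suggests motif disruption (or creation).  PWMs
are read from JASPAR text position-frequency matrices, converted to
log-odds with a pseudocount split by the background distribution, and
slid over both strands of a sequence; the statistic of interest is the
maximum hit score of the reference sequence versus each single-base
mutant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio import motifs as bio_motifs

__all__ = [
    "PWM",
    "MotifHit",
    "MutantEffect",
    "RefVsMutant",
    "read_jaspar",
    "scan_sequence",
    "best_hit",
    "ref_vs_mutant_max",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)


class PWM:
    """A position weight matrix with natural-log log-odds scores.

    ``counts`` is a 4 x m array (rows A, C, G, T).  Columns are
    normalized to probabilities after adding ``pseudocount`` distributed
    according to the background frequencies; log-odds are
    ln(p / background).  An N in a scanned sequence contributes 0
    (background-neutral).
    """

    def __init__(
        self,
        name: str,
        counts: np.ndarray,
        background: tuple[float, float, float, float] = UNIFORM_BACKGROUND,
        pseudocount: float = 0.8,
    ):
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x m matrix (rows A,C,G,T)")
        if (counts < 0).any():
            raise ValueError("negative counts")
        bg = np.asarray(background, dtype=float)
        if not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must sum to 1")
        self.name = name
        self.background = tuple(bg)
        col_tot = counts.sum(axis=0)
        probs = (counts + pseudocount * bg[:, None]) / (col_tot + pseudocount)
        self.probabilities = probs
        log_odds = np.log(probs / bg[:, None])
        # row 4 = N: background-neutral, contributes nothing
        self.log_odds = np.vstack([log_odds, np.zeros(log_odds.shape[1])])

    @property
    def length(self) -> int:
        return self.log_odds.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.log_odds[:4].max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds[:4].min(axis=0).sum())

    def relative(self, score: float) -> float:
        """Score as a fraction of the attainable range [min, max]."""
        span = self.max_score - self.min_score
        return (score - self.min_score) / span if span > 0 else 1.0

    def reverse_complement_log_odds(self) -> np.ndarray:
        lo = self.log_odds
        rc = np.empty_like(lo)
        rc[:4] = lo[3::-1, ::-1]  # complement rows, reverse columns
        rc[4] = lo[4, ::-1]
        return rc


@dataclass(frozen=True)
class MotifHit:
    pwm_name: str
    offset: int  # 0-based offset of the match start on the forward strand
    strand: str  # "+" or "-"
    score: float  # natural-log log-odds
    relative_score: float


@dataclass(frozen=True)
class MutantEffect:
    offset: int
    alt: str
    max_score: float
    delta: float  # max_mut - max_ref
    classification: str  # disruptive | creating | neutral


@dataclass(frozen=True)
class RefVsMutant:
    pwm_name: str
    max_ref: float
    mutants: tuple[MutantEffect, ...]


def read_jaspar(path, background=UNIFORM_BACKGROUND, pseudocount: float = 0.8) -> list[PWM]:
    """Read JASPAR text PFMs (">ID NAME" header + four base rows)."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
        pwms = []
        for m in parsed:
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
            name = m.name or m.matrix_id
            pwms.append(PWM(name, counts, background, pseudocount))
    if not pwms:
        raise ValueError(f"no matrices in {path}")
    return pwms


def _encode(seq: str) -> np.ndarray:
    seq = seq.upper()
    try:
        return np.array([_BASE_INDEX[b] for b in seq], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r} in sequence") from None


def _strand_scores(code: np.ndarray, lo: np.ndarray) -> np.ndarray:
    m = lo.shape[1]
    n_offsets = code.size - m + 1
    scores = np.zeros(n_offsets)
    for j in range(m):
        scores += lo[:, j][code[j : j + n_offsets]]
    return scores


def _all_hits(seq: str, pwm: PWM) -> list[MotifHit]:
    code = _encode(seq)
    if code.size < pwm.length:
        return []
    hits = []
    for strand, lo in (("+", pwm.log_odds), ("-", pwm.reverse_complement_log_odds())):
        for offset, score in enumerate(_strand_scores(code, lo)):
            hits.append(
                MotifHit(pwm.name, offset, strand, float(score), pwm.relative(score))
            )
    return hits


def scan_sequence(seq: str, pwm: PWM, min_relative_score: float = 0.8) -> list[MotifHit]:
    """Scan both strands of ``seq``; return hits at or above the relative
    score threshold, sorted by offset then strand.

    A sequence shorter than the PWM yields an empty result with a
    warning rather than an error.
    """
    if len(seq) < pwm.length:
        warnings.warn(
            f"sequence ({len(seq)} bp) shorter than PWM {pwm.name} ({pwm.length} bp)"
        )
        return []
    hits = [h for h in _all_hits(seq, pwm) if h.relative_score >= min_relative_score]
    return sorted(hits, key=lambda h: (h.offset, h.strand))


def best_hit(seq: str, pwm: PWM) -> MotifHit:
    """Maximum-scoring hit over both strands regardless of threshold.

    Ties resolve to the earliest offset, forward strand first.
    """
    hits = _all_hits(seq, pwm)
    if not hits:
        raise ValueError(f"sequence shorter than PWM {pwm.name}")
    return max(hits, key=lambda h: (h.score, -h.offset, h.strand == "+"))


def ref_vs_mutant_max(
    seq_ref: str,
    mutations: list[tuple[int, str]],
    pwm: PWM,
    dead_band: float = 0.0,
) -> RefVsMutant:
    """Maximum PWM match score of the reference vs each single-base mutant.

    ``mutations`` are (offset, alt) pairs; each defines one mutant
    sequence with that single substitution applied.  The classification
    compares max_mut - max_ref against ``dead_band``: below -dead_band
    is disruptive, above +dead_band creating, otherwise neutral.
    """
    max_ref = best_hit(seq_ref, pwm).score
    effects = []
    for offset, alt in mutations:
        if not 0 <= offset < len(seq_ref):
            raise ValueError(f"mutation offset {offset} outside sequence")
        seq_mut = seq_ref[:offset] + alt + seq_ref[offset + 1 :]
        max_mut = best_hit(seq_mut, pwm).score
        delta = max_mut - max_ref
        if delta < -dead_band:
            cls = "disruptive"
        elif delta > dead_band:
            cls = "creating"
        else:
            cls = "neutral"
        effects.append(MutantEffect(offset, alt, max_mut, delta, cls))
    return RefVsMutant(pwm.name, max_ref, tuple(effects))
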