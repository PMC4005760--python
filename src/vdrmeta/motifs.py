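"""DR3 motif representation and log-odds scanning around peak summits.

The vitamin D receptor binds DNA as a VDR-RXR heterodimer on DR3-type
elements: two RGGTCA-like hexameric half-sites in direct repeat spaced by
three nucleotides, consensus RGGTCANNGRGTTCA. A position weight matrix
built from that consensus is scanned over both strands of the +/-100 bp
sequence around each peak summit; a hit is a window whose cumulative
log-odds score (natural log, probability over background) exceeds a
threshold. The representative motif carries its native threshold of
9.184643; threshold sweeps go down to 4.

Score scale: natural logarithm, uniform 0.25 background and a 0.001
probability floor. Exact parity with any specific scanner's background
model is not claimed; thresholds are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import PeakCall, as_genome, read_fasta_window
from .overlaps import percentage

__all__ = [
    "PWM",
    "MotifHit",
    "DR3_CONSENSUS",
    "DR3_NATIVE_THRESHOLD",
    "dr3_pwm",
    "pwm_from_iupac",
    "read_jaspar",
    "log_odds_score",
    "revcomp",
    "scan_summit_region",
    "best_scores",
    "dr3_threshold_sweep",
    "motif_density_profile",
    "fe_window_curve",
    "motif_snp_distance",
]

DR3_CONSENSUS = "RGGTCANNGRGTTCA"
DR3_NATIVE_THRESHOLD = 9.184643

PROB_FLOOR = 1e-3
_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate("ACGTN")}
_COMP_INDEX = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N->N
_REVCOMP = str.maketrans("ACGTN", "TGCAN")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


@dataclass(frozen=True)
class PWM:
    """Probability matrix over A/C/G/T with background and native threshold.

    ``probs`` has shape (4, length), rows in A, C, G, T order; each column
    sums to 1 and every entry is at least the probability floor.
    """

    name: str
    probs: np.ndarray
    background: np.ndarray
    native_threshold: float | None = None

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if probs.shape[0] != 4:
            raise ValueError("probs must have 4 rows (A, C, G, T)")
        if not np.allclose(probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        if np.any(probs < PROB_FLOOR - 1e-12):
            raise ValueError(f"PWM probabilities must be >= {PROB_FLOOR}")
        if not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    def log_odds(self) -> np.ndarray:
        """5 x length natural-log-odds matrix; row 4 is the N penalty."""
        lo = np.log(self.probs / self.background.reshape(4, 1))
        n_row = np.full((1, self.length), np.log(PROB_FLOOR / 0.25))
        return np.vstack([lo, n_row])

    def max_score(self) -> float:
        return float(self.log_odds()[:4].max(axis=0).sum())


def _floor_and_renormalize(probs: np.ndarray) -> np.ndarray:
    probs = np.maximum(probs, PROB_FLOOR)
    return probs / probs.sum(axis=0, keepdims=True)


def pwm_from_iupac(
    consensus: str,
    match_prob: float = 0.997,
    name: str | None = None,
    native_threshold: float | None = None,
) -> PWM:
    """Build a PWM from an IUPAC consensus string.

    The match probability is split equally over the letter's allowed bases
    and the remainder equally over the disallowed ones; N gives a uniform
    column. Probabilities are floored at 0.001 and columns renormalized.
    """
    if not 0.25 < match_prob <= 1 - 3 * PROB_FLOOR + 1e-12:
        raise ValueError("match_prob must be in (0.25, 0.997]")
    cols = []
    for letter in consensus.upper():
        allowed = IUPAC.get(letter)
        if allowed is None:
            raise ValueError(f"invalid IUPAC letter {letter!r}")
        col = np.empty(4)
        n_allowed = len(allowed)
        if n_allowed == 4:
            col[:] = 0.25
        else:
            rest = (1.0 - match_prob) / (4 - n_allowed)
            col[:] = rest
            for b in allowed:
                col[_BASE_INDEX[b]] = match_prob / n_allowed
        cols.append(col)
    probs = _floor_and_renormalize(np.array(cols).T)
    return PWM(
        name=name or consensus,
        probs=probs,
        background=np.full(4, 0.25),
        native_threshold=native_threshold,
    )


def dr3_pwm(match_prob: float = 0.997) -> PWM:
    """The representative DR3-type motif with its native score threshold."""
    return pwm_from_iupac(
        DR3_CONSENSUS, match_prob, name="DR3", native_threshold=DR3_NATIVE_THRESHOLD
    )


def read_jaspar(path, native_threshold: float | None = None) -> PWM:
    """Read a JASPAR-format position frequency matrix into a PWM."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        m = bio_motifs.read(fh, "jaspar")
    counts = np.array([m.counts[b] for b in _BASES], dtype=float)
    totals = counts.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("JASPAR matrix has an empty column")
    probs = _floor_and_renormalize(counts / totals)
    return PWM(
        name=m.name or m.matrix_id or "motif",
        probs=probs,
        background=np.full(4, 0.25),
        native_threshold=native_threshold,
    )


@dataclass(frozen=True)
class MotifHit:
    """A scored motif placement relative to a peak summit.

    ``offset`` is the motif start minus the summit position on the plus
    strand of the genome (negative = upstream of the summit).
    """

    offset: int
    strand: str
    score: float


_ENCODE_TABLE = bytes.maketrans(b"ACGTN", bytes(range(5)))


def _encode(seq: str) -> np.ndarray:
    idx = np.frombuffer(
        seq.upper().encode().translate(_ENCODE_TABLE), dtype=np.uint8
    ).astype(np.intp)
    idx[idx > 4] = 4  # anything outside ACGTN scores as N
    return idx


def log_odds_score(pwm: PWM, seq: str, strand: str = "+") -> float:
    """Cumulative natural-log-odds score of one sequence against the PWM."""
    if len(seq) != pwm.length:
        raise ValueError(f"sequence length {len(seq)} != motif length {pwm.length}")
    if strand == "-":
        seq = revcomp(seq)
    elif strand != "+":
        raise ValueError("strand must be '+' or '-'")
    lo = pwm.log_odds()
    idx = _encode(seq)
    return float(lo[idx, np.arange(pwm.length)].sum())


def _window_scores(pwm: PWM, seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Scores of every motif-length window of ``seq`` on both strands.

    Returns (plus, minus) arrays indexed by window start; minus-strand
    scores are computed in place via the reverse-complemented matrix, so
    minus[i] equals the plus-strand score of the reverse complement of the
    window starting at i.
    """
    L = pwm.length
    idx = _encode(seq)
    if idx.size < L:
        empty = np.empty(0)
        return empty, empty
    lo = pwm.log_odds()
    lo_rc = lo[_COMP_INDEX][:, ::-1]
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    cols = np.arange(L)
    plus = lo[windows, cols].sum(axis=1)
    minus = lo_rc[windows, cols].sum(axis=1)
    return plus, minus


def scan_summit_region(
    pwm: PWM,
    genome,
    chrom: str,
    summit: int,
    flank: int = 100,
    threshold: float | None = None,
) -> MotifHit | None:
    """Best motif hit in ``[summit - flank, summit + flank)`` on both strands.

    Returns the highest-scoring placement with score strictly above the
    threshold (the PWM's native threshold when omitted); ties are broken
    by offset ascending, plus strand before minus. ``None`` when no
    placement qualifies. Windows running off the chromosome are N-padded.
    """
    if flank < pwm.length:
        raise ValueError("flank must be at least the motif length")
    if threshold is None:
        threshold = pwm.native_threshold
        if threshold is None:
            raise ValueError("no threshold given and PWM has no native threshold")
    seq = read_fasta_window(genome, chrom, summit, flank)
    plus, minus = _window_scores(pwm, seq)
    if plus.size == 0:
        return None
    # interleave (offset asc, + before -) so argmax returns the tie-winner
    stacked = np.column_stack([plus, minus]).ravel()
    i = int(np.argmax(stacked))
    score = float(stacked[i])
    if not score > threshold:
        return None
    return MotifHit(offset=i // 2 - flank, strand="+-"[i % 2], score=score)


def best_scores(
    pwm: PWM, genome, peaks: Sequence[PeakCall], flank: int = 100
) -> np.ndarray:
    """Best log-odds score (any strand/offset) per peak's summit window."""
    genome = as_genome(genome)
    out = np.full(len(peaks), -np.inf)
    for i, p in enumerate(peaks):
        seq = read_fasta_window(genome, p.interval.chrom, p.summit, flank)
        plus, minus = _window_scores(pwm, seq)
        if plus.size:
            out[i] = max(plus.max(), minus.max())
    return out


def dr3_threshold_sweep(
    peaks: Sequence[PeakCall],
    genome,
    pwm: PWM,
    thresholds: Sequence[float],
    flank: int = 100,
) -> pd.DataFrame:
    """Percentage of peaks with a motif hit, per score threshold.

    The percentage is non-increasing in the threshold; each peak counts
    once however many hits it has.
    """
    thresholds = list(thresholds)
    if sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be sorted ascending")
    scores = best_scores(pwm, genome, peaks, flank)
    rows = [
        {
            "threshold": t,
            "pct_with_hit": percentage(int((scores > t).sum()), len(peaks))
            if len(peaks)
            else 0.0,
        }
        for t in thresholds
    ]
    return pd.DataFrame(rows)


def motif_density_profile(
    peaks: Sequence[PeakCall],
    genome,
    pwm: PWM,
    threshold: float | None = None,
    profile_flank: int = 500,
    bin_size: int = 25,
) -> pd.DataFrame:
    """Motif hit density per offset bin around peak summits.

    Counts every above-threshold placement on both strands whose motif
    center lies within ``[-profile_flank, +profile_flank)`` of the summit,
    normalized to hits per peak per bp. Bin rows are labelled by the bin's
    left offset.
    """
    if (2 * profile_flank) % bin_size != 0:
        raise ValueError("bin_size must divide 2 * profile_flank")
    if threshold is None:
        threshold = pwm.native_threshold
    genome = as_genome(genome)
    L = pwm.length
    center_shift = L // 2
    edges = np.arange(-profile_flank, profile_flank + bin_size, bin_size)
    counts = np.zeros(edges.size - 1, dtype=np.int64)
    fetch_flank = profile_flank + L
    for p in peaks:
        seq = read_fasta_window(genome, p.interval.chrom, p.summit, fetch_flank)
        plus, minus = _window_scores(pwm, seq)
        if plus.size == 0:
            continue
        centers = np.arange(plus.size) - fetch_flank + center_shift
        for scores in (plus, minus):
            sel = centers[(scores > threshold)]
            sel = sel[(sel >= -profile_flank) & (sel < profile_flank)]
            counts += np.histogram(sel, bins=edges)[0]
    denom = max(1, len(peaks)) * bin_size
    return pd.DataFrame(
        {"offset": edges[:-1], "hits_per_peak_per_bp": counts / denom}
    )


def fe_window_curve(
    peaks: Sequence[PeakCall],
    genome,
    pwm: PWM,
    rank_window: int = 100,
    scan_flank: int = 100,
    threshold: float | None = None,
) -> pd.DataFrame:
    """DR3 percentage per window of consecutively FE-ranked peaks.

    Peaks are ranked by fold enrichment descending (ties by genomic
    position); each full window of ``rank_window`` peaks reports its mean
    FE and the percentage of peaks with an above-threshold hit within
    +/- ``scan_flank`` of the summit. A trailing partial window is dropped.
    """
    if len(peaks) < rank_window:
        raise ValueError(f"need at least {rank_window} peaks")
    if threshold is None:
        threshold = pwm.native_threshold
    ranked = sorted(
        peaks,
        key=lambda p: (-p.fold_enrichment, p.interval.chrom, p.interval.start),
    )
    scores = best_scores(pwm, genome, ranked, scan_flank)
    rows = []
    for w, start in enumerate(range(0, len(ranked) - rank_window + 1, rank_window)):
        chunk = ranked[start : start + rank_window]
        chunk_scores = scores[start : start + rank_window]
        rows.append(
            {
                "window_rank": w + 1,
                "mean_fe": float(np.mean([p.fold_enrichment for p in chunk])),
                "dr3_pct": percentage(int((chunk_scores > threshold).sum()), rank_window),
            }
        )
    return pd.DataFrame(rows)


def motif_snp_distance(
    motif_centers: Sequence[tuple[str, int]],
    snps: Mapping[str, np.ndarray],
) -> list[float]:
    """Signed distance from each motif center to its nearest SNP.

    Distance = snp_position - center: negative when the SNP lies upstream
    (toward smaller coordinates) of the motif's central nucleotide. When
    two SNPs are equidistant the upstream one is reported. NaN when the
    chromosome has no SNPs.
    """
    out: list[float] = []
    for chrom, center in motif_centers:
        positions = snps.get(chrom)
        if positions is None or len(positions) == 0:
            out.append(float("nan"))
            continue
        positions = np.asarray(positions)
        i = int(np.searchsorted(positions, center))
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(positions):
                d = int(positions[j]) - center
                if best is None or abs(d) < abs(best) or (abs(d) == abs(best) and d < best):
                    best = d
        out.append(float(best))
    return out


def motif_center(peak: PeakCall, hit: MotifHit, motif_length: int) -> tuple[str, int]:
    """Absolute (chrom, center) of a hit: start + floor(length / 2)."""
    return peak.interval.chrom, peak.summit + hit.offset + motif_length // 2
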