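"""Genomic file formats and the shared coordinate model.

All coordinates in this package are 0-based, half-open ``[start, end)``
(the BED/narrowPeak convention). Peak summits are stored as *absolute*
positions, never as offsets from the peak start.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "PeakCall",
    "SampleSet",
    "ScoreTrack",
    "Genome",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_fasta_window",
    "read_bed_positions",
    "track_value_at",
    "filter_by_fdr",
    "consensus_to_frame",
    "write_consensus_table",
    "write_consensus_bed",
    "write_fasta",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _open_text(path):
    """Open plain or gzip-compressed text, sniffed by extension."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    def width(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    def overlap_width(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class PeakCall:
    """One called peak: interval, absolute summit, fold enrichment, -log10(q).

    ``name``, ``score``, ``strand`` and ``neg_log10_p`` carry the remaining
    narrowPeak columns so that files round-trip losslessly.
    """

    interval: GenomicInterval
    summit: int
    fold_enrichment: float
    neg_log10_q: float
    name: str = "."
    score: int = 0
    strand: str = "."
    neg_log10_p: float = -1.0

    def __post_init__(self):
        if not self.interval.contains(self.summit):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"[{self.interval.start}, {self.interval.end})"
            )
        if self.fold_enrichment < 0:
            raise ValueError("fold enrichment must be non-negative")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


def _peak_sort_key(p: PeakCall):
    return (p.interval.chrom, p.interval.start, p.interval.end)


@dataclass
class SampleSet:
    """A labelled peak set for one (cell type, stimulation state) sample."""

    sample_id: str
    cell_type: str
    stimulated: bool
    peaks: list = field(default_factory=list)

    def __post_init__(self):
        self.peaks = sorted(self.peaks, key=_peak_sort_key)

    def __len__(self) -> int:
        return len(self.peaks)


class ScoreTrack:
    """A chromosome-wise step function, e.g. a MACS2 bdgcmp score track.

    Intervals per chromosome must be non-overlapping; the value is 0
    anywhere not covered by a listed interval.
    """

    def __init__(self, intervals: Iterable[tuple[GenomicInterval, float]]):
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for iv, value in intervals:
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, float(value)))
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, rows in per_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            values = np.array([r[2] for r in rows], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping track intervals on {chrom}")
            self._data[chrom] = (starts, ends, values)

    @classmethod
    def from_bedgraph(cls, path) -> "ScoreTrack":
        out = []
        with _open_text(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("track", "#", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"{path}: line {lineno}: expected 4 bedGraph columns")
                chrom, start, end, value = fields[:4]
                out.append((GenomicInterval(chrom, int(start), int(end)), float(value)))
        return cls(out)

    def value_at(self, chrom: str, position: int) -> float:
        data = self._data.get(chrom)
        if data is None:
            return 0.0
        starts, ends, values = data
        i = int(np.searchsorted(starts, position, side="right")) - 1
        if i >= 0 and position < ends[i]:
            return float(values[i])
        return 0.0


def track_value_at(track: ScoreTrack, chrom: str, position: int) -> float:
    """Value of the step function at ``position``; 0 where uncovered."""
    return track.value_at(chrom, position)


def _sanitize(seq: str) -> str:
    """Uppercase and collapse every non-ACGT character to N."""
    seq = seq.upper()
    if all(c in "ACGT" for c in seq):
        return seq
    return "".join(c if c in "ACGT" else "N" for c in seq)


class Genome:
    """Random-access genome sequence: a FASTA file (via pyfaidx) or a dict.

    ``fetch`` clips at chromosome ends and pads with ``N`` so the requested
    width is always honoured; bases are uppercased and non-ACGT characters
    become ``N``.
    """

    def __init__(self, seqs: Mapping[str, str]):
        self._seqs = seqs

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        from pyfaidx import Fasta

        return cls(Fasta(str(path)))

    @classmethod
    def from_dict(cls, seqs: Mapping[str, str]) -> "Genome":
        return cls(dict(seqs))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def chroms(self) -> list[str]:
        return list(self._seqs.keys())

    def chrom_length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        record = self._seqs[chrom]
        n = len(record)
        lo, hi = max(0, start), min(n, end)
        core = str(record[lo:hi]) if hi > lo else ""
        pad_left = max(0, min(end, 0) - start)
        pad_right = max(0, end - max(start, n))
        return "N" * pad_left + _sanitize(core) + "N" * pad_right


def read_fasta_window(genome, chrom: str, center: int, flank: int) -> str:
    """Sequence of ``[center - flank, center + flank)``, exactly 2*flank long.

    ``genome`` may be a Genome, a dict of sequences, or a FASTA path.
    """
    genome = as_genome(genome)
    return genome.fetch(chrom, center - flank, center + flank)


def as_genome(genome) -> Genome:
    if isinstance(genome, Genome):
        return genome
    if isinstance(genome, Mapping):
        return Genome.from_dict(genome)
    return Genome.from_fasta(genome)


def read_narrowpeak(path) -> list[PeakCall]:
    """Parse an ENCODE narrowPeak (BED6+4) file into sorted PeakCalls.

    Column 7 is the fold enrichment, column 9 the -log10 q-value and
    column 10 the summit offset from the peak start.
    """
    peaks = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise ValueError(
                    f"{path}: line {lineno}: expected 10 narrowPeak columns, "
                    f"got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                score = int(fields[4])
                strand = fields[5]
                fe = float(fields[6])
                neg_log10_p = float(fields[7])
                neg_log10_q = float(fields[8])
                offset = int(fields[9])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            summit = start + offset
            if not (start <= summit < end):
                raise ValueError(
                    f"{path}: line {lineno}: summit offset {offset} outside peak"
                )
            peaks.append(
                PeakCall(
                    interval=GenomicInterval(chrom, start, end),
                    summit=summit,
                    fold_enrichment=fe,
                    neg_log10_q=neg_log10_q,
                    name=name,
                    score=score,
                    strand=strand,
                    neg_log10_p=neg_log10_p,
                )
            )
    peaks.sort(key=_peak_sort_key)
    return peaks


def write_narrowpeak(peaks: Sequence[PeakCall], path) -> None:
    with open(path, "wt") as fh:
        for p in peaks:
            fh.write(
                "\t".join(
                    [
                        p.interval.chrom,
                        str(p.interval.start),
                        str(p.interval.end),
                        p.name,
                        str(p.score),
                        p.strand,
                        repr(p.fold_enrichment),
                        repr(p.neg_log10_p),
                        repr(p.neg_log10_q),
                        str(p.summit - p.interval.start),
                    ]
                )
                + "\n"
            )


def read_bed_positions(path) -> dict[str, np.ndarray]:
    """Read point features (e.g. SNPs) from a BED file.

    Returns per-chromosome sorted arrays of the feature start positions.
    """
    per_chrom: dict[str, list[int]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 BED columns")
            per_chrom.setdefault(fields[0], []).append(int(fields[1]))
    return {c: np.array(sorted(v), dtype=np.int64) for c, v in per_chrom.items()}


def filter_by_fdr(peaks: Iterable[PeakCall], neg_log10_q: float = 2.0) -> list[PeakCall]:
    """Keep peaks passing FDR < 10^-neg_log10_q (default: FDR < 1%)."""
    return [p for p in peaks if p.neg_log10_q > neg_log10_q]


def write_fasta(seqs: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "wt") as fh:
        for chrom, seq in seqs.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def consensus_to_frame(consensus, sample_ids: Sequence[str] | None = None):
    """Flatten consensus peaks into a tidy table (one row per peak)."""
    import pandas as pd

    if sample_ids is None:
        seen: dict[str, None] = {}
        for cp in consensus:
            for sid in cp.per_sample:
                seen.setdefault(sid)
        sample_ids = list(seen)
    rows = []
    for cp in consensus:
        row = {
            "chrom": cp.interval.chrom,
            "start": cp.interval.start,
            "end": cp.interval.end,
            "summit": cp.summit,
            "n_cell_types": cp.n_cell_types,
        }
        for sid in sample_ids:
            m = cp.per_sample.get(sid)
            row[f"{sid}_present"] = int(m.present) if m else 0
            row[f"{sid}_fe"] = m.fold_enrichment if m else 0.0
            row[f"{sid}_q"] = m.neg_log10_q if m else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def write_consensus_table(consensus, path, sample_ids: Sequence[str] | None = None) -> None:
    consensus_to_frame(consensus, sample_ids).to_csv(path, sep="\t", index=False)


def write_consensus_bed(consensus, path) -> None:
    with open(path, "wt") as fh:
        for i, cp in enumerate(consensus):
            fh.write(
                f"{cp.interval.chrom}\t{cp.interval.start}\t{cp.interval.end}"
                f"\tconsensus_{i}\t{cp.n_cell_types}\t.\n"
            )
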