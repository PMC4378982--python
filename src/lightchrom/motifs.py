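"""IUPAC motif scanning and tandem-spacing analysis.

Supports exact degenerate-pattern scanning on both strands (palindromic
patterns such as GATC are reported once), the distribution of pairwise
center-to-center motif distances inside summit-centered regions (default
300 bp) against a random-region background, and motif positional density
around binding-site summits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .io import GenomeSequence

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(pattern: str) -> str:
    return pattern.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    contig: str
    start: int        # 0-based
    strand: str
    pattern: str
    matched: str

    @property
    def center(self) -> float:
        return self.start + len(self.matched) / 2.0


@dataclass
class SpacingDistribution:
    """Counts of motif pairs per center-to-center distance within regions."""

    counts: np.ndarray          # index d = distance 0..max_spacing
    n_regions: int
    max_spacing: int
    mean_hits_per_region: float = 0.0
    background: Optional["SpacingDistribution"] = None

    @property
    def total_pairs(self) -> int:
        return int(self.counts.sum())

    def mode(self) -> Optional[int]:
        if self.counts.sum() == 0:
            return None
        return int(np.argmax(self.counts))


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValueError(f"illegal IUPAC letter {ch!r} in pattern {pattern!r}")
        chars = IUPAC[ch]
        parts.append(chars if len(chars) == 1 else f"[{chars}]")
    # lookahead makes overlapping matches visible
    return re.compile(f"(?=({''.join(parts)}))")


def _scan_sequence(seq: str, pattern: str) -> List[Tuple[int, str]]:
    rx = _iupac_regex(pattern)
    return [(m.start(), m.group(1)) for m in rx.finditer(seq)]


def scan_iupac(
    genome: GenomeSequence,
    pattern: str,
    both_strands: bool = True,
) -> List[MotifHit]:
    """All exact degenerate matches of an IUPAC pattern in the genome.

    With ``both_strands``, the reverse-complement pattern is also scanned
    (hits reported at their + strand coordinates with strand '-'); a
    palindromic pattern is scanned once so each site appears exactly once.
    """
    pattern = pattern.upper().replace(" ", "")
    hits: List[MotifHit] = []
    rc = reverse_complement(pattern)
    palindromic = rc == pattern
    for contig in genome:
        seq = genome[contig]
        for start, matched in _scan_sequence(seq, pattern):
            hits.append(MotifHit(contig, start, "+", pattern, matched))
        if both_strands and not palindromic:
            for start, matched in _scan_sequence(seq, rc):
                hits.append(MotifHit(contig, start, "-", pattern, matched))
    hits.sort(key=lambda h: (h.contig, h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Tandem spacing in summit regions
# ---------------------------------------------------------------------------

def _tally_regions(
    regions: Sequence[Tuple[str, int, int]],
    genome: GenomeSequence,
    pattern: str,
    max_spacing: int,
    both_strands: bool,
) -> Tuple[np.ndarray, float]:
    counts = np.zeros(max_spacing + 1, dtype=np.int64)
    n_hits = 0
    rc = reverse_complement(pattern)
    palindromic = rc == pattern
    for contig, lo, hi in regions:
        seq = genome[contig][lo:hi]
        starts = [s for s, _ in _scan_sequence(seq, pattern)]
        if both_strands and not palindromic:
            starts += [s for s, _ in _scan_sequence(seq, rc)]
        starts.sort()
        n_hits += len(starts)
        centers = [s + len(pattern) / 2.0 for s in starts]
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                d = int(round(abs(centers[j] - centers[i])))
                if d <= max_spacing:
                    counts[d] += 1
    mean_hits = n_hits / len(regions) if regions else 0.0
    return counts, mean_hits


def tandem_spacing(
    summits: Sequence[Tuple[str, int]],
    genome: GenomeSequence,
    pattern: str = "GATC",
    region: int = 300,
    max_spacing: int = 150,
    both_strands: bool = True,
) -> SpacingDistribution:
    """Pairwise motif spacing inside summit-centered regions.

    Each summit defines a ``region`` bp window centered on it; all
    within-region hit pairs contribute their center-to-center distance.
    """
    half = region // 2
    regions = []
    lengths = genome.lengths()
    for contig, pos in summits:
        if not half <= pos <= lengths[contig] - half:
            raise ValueError(f"summit {contig}:{pos} too close to a contig edge")
        regions.append((contig, pos - half, pos - half + region))
    counts, mean_hits = _tally_regions(regions, genome, pattern, max_spacing, both_strands)
    return SpacingDistribution(counts, len(regions), max_spacing, mean_hits)


def random_region_background(
    genome: GenomeSequence,
    n_regions: int,
    region: int = 300,
    seed: int = 0,
    pattern: str = "GATC",
    max_spacing: int = 150,
    both_strands: bool = True,
) -> SpacingDistribution:
    """Same spacing tally over uniformly random regions of the genome."""
    rng = np.random.default_rng(seed)
    contigs = list(genome)
    lengths = genome.lengths()
    weights = np.array([max(0, lengths[c] - region) for c in contigs], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("genome smaller than the region size")
    regions = []
    picks = rng.choice(len(contigs), size=n_regions, p=weights / weights.sum())
    for k in picks:
        contig = contigs[k]
        lo = int(rng.integers(0, lengths[contig] - region + 1))
        regions.append((contig, lo, lo + region))
    counts, mean_hits = _tally_regions(regions, genome, pattern, max_spacing, both_strands)
    return SpacingDistribution(counts, n_regions, max_spacing, mean_hits)


# ---------------------------------------------------------------------------
# Positional density around summits
# ---------------------------------------------------------------------------

def positional_density(
    hits: Sequence[MotifHit],
    summits: Sequence[Tuple[str, int]],
    flank: int = 500,
    bandwidth_bp: float = 30.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Density of motif hit centers versus signed distance to summits.

    For every summit, hits whose center lies within +/- flank contribute
    the signed offset (hit center - summit); the histogram is smoothed
    with a Gaussian kernel (bandwidth 0 disables smoothing).  Returns
    (offsets, density).
    """
    if not summits:
        raise ValueError("need at least one summit")
    offsets = np.arange(-flank, flank + 1)
    hist = np.zeros(len(offsets))
    by_contig: Dict[str, List[float]] = {}
    for h in hits:
        by_contig.setdefault(h.contig, []).append(h.center)
    for contig, pos in summits:
        for center in by_contig.get(contig, ()):
            d = int(round(center - pos))
            if -flank <= d <= flank:
                hist[d + flank] += 1
    if bandwidth_bp and bandwidth_bp > 0:
        hist = gaussian_filter1d(hist, sigma=bandwidth_bp, truncate=4.0, mode="constant")
    return offsets, hist
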