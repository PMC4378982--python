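"""MNase-seq nucleosome occupancy, positioning and footprint analysis.

Paired-end fragments are split by length into nucleosomal (100-1000 bp)
and sub-nucleosomal (< 100 bp) classes.  Nucleosomal fragments contribute
the middle 50 bp around their midpoint to a coverage track which is
normalized so the 90th percentile of 150 bp window coverage equals 1,
then smoothed by Gaussian kernel regression.  Downstream analyses:
TSS/+1-nucleosome-aligned metagene profiles over +/- 1500 bp, the +1
nucleosome as the coverage maximum in a 200 bp window around the TSS,
per-nucleosome occupancy as the area under the curve over a 176 bp
nucleosome, repeat-length estimation from profile autocorrelation or
successive dyads, binding-site occupancy against an NB-distance
randomized background, and sub-nucleosomal footprint profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .io import CoverageTrack, FormatError, GeneModel, GenomeSequence

logger = logging.getLogger(__name__)


@dataclass
class MetageneProfile:
    """Averaged occupancy as a function of distance to an anchor."""

    offsets: np.ndarray   # -flank .. +flank
    values: np.ndarray    # mean occupancy per offset (nan where no anchor covers)
    n_anchors: int


@dataclass
class SpacingEstimate:
    repeat_bp: Optional[float]
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


# ---------------------------------------------------------------------------
# Fragment classification and coverage
# ---------------------------------------------------------------------------

def classify_fragments(
    pairs: pd.DataFrame,
    nuc_min_len: int = 100,
    nuc_max_len: int = 1000,
) -> Dict[str, pd.DataFrame]:
    """Partition paired-end fragments by length.

    Fragments of nuc_min_len..nuc_max_len bp are nucleosomal (the 100 bp
    boundary is inclusive on the nucleosomal side), shorter ones are
    sub-nucleosomal footprint candidates, longer ones are discarded.
    """
    length = pairs["end"] - pairs["start"]
    if (length <= 0).any():
        raise FormatError("fragment with nonpositive length")
    nuc = pairs[(length >= nuc_min_len) & (length <= nuc_max_len)]
    sub = pairs[length < nuc_min_len]
    return {"nucleosomal": nuc, "subnucleosomal": sub}


def midpoint_coverage(
    fragments: pd.DataFrame,
    genome: GenomeSequence,
    span: int = 50,
) -> CoverageTrack:
    """Each fragment contributes +1 over ``span`` bp centered on its midpoint.

    The midpoint is floor((start + end) / 2); the covered interval is
    [mid - span//2, mid + span - span//2), clipped at contig ends.
    """
    half = span // 2
    data = {}
    for contig, L in genome.lengths().items():
        diff = np.zeros(L + 1)
        grp = fragments[fragments["contig"] == contig]
        if len(grp):
            mid = (grp["start"].to_numpy() + grp["end"].to_numpy()) // 2
            lo = np.clip(mid - half, 0, L)
            hi = np.clip(mid - half + span, 0, L)
            np.add.at(diff, lo, 1.0)
            np.add.at(diff, hi, -1.0)
        data[contig] = np.cumsum(diff[:-1])
    return CoverageTrack(data, source="midpoint coverage")


def normalize_track(
    track: CoverageTrack,
    percentile: float = 90.0,
    window: int = 150,
) -> CoverageTrack:
    """Scale the track so the ``percentile`` of window coverage equals 1.

    The normalization statistic is the given percentile of mean coverage
    over non-overlapping ``window`` bp tiles restricted to tiles with
    nonzero coverage, so the operation is idempotent and scale invariant.
    """
    window_means = []
    for cov in track.data.values():
        n_tiles = len(cov) // window
        if n_tiles:
            tiles = cov[: n_tiles * window].reshape(n_tiles, window).mean(axis=1)
            window_means.append(tiles[tiles > 0])
    if not window_means:
        raise ValueError("track too short to normalize")
    window_means = np.concatenate(window_means)
    if len(window_means) == 0:
        raise ValueError("cannot normalize an all-zero track")
    factor = float(np.percentile(window_means, percentile))
    if factor <= 0:
        raise ValueError("nonpositive normalization factor")
    out = CoverageTrack(
        {c: v / factor for c, v in track.data.items()},
        normalized=True,
        source=track.source,
    )
    return out


def smooth_track(track: CoverageTrack, bandwidth_bp: float = 30.0) -> CoverageTrack:
    """Gaussian kernel regression smoothing (kernel truncated at 4 sd)."""
    if bandwidth_bp < 1:
        raise ValueError("bandwidth must be >= 1 bp")
    data = {
        c: gaussian_filter1d(v, sigma=bandwidth_bp, truncate=4.0, mode="reflect")
        for c, v in track.data.items()
    }
    return CoverageTrack(data, normalized=track.normalized, source=track.source)


# ---------------------------------------------------------------------------
# +1 nucleosome and metagene profiles
# ---------------------------------------------------------------------------

def locate_plus_one(
    track: CoverageTrack,
    gene: GeneModel,
    window: int = 200,
) -> Optional[int]:
    """Center of the +1 nucleosome: coverage maximum near the TSS.

    The maximum is sought in [TSS - window/2, TSS + window/2] (inclusive);
    ties are broken toward the TSS and then downstream of the gene.
    Returns None (with a log note) when the window has zero coverage.
    """
    cov = track.data[gene.contig]
    half = window // 2
    lo = max(0, gene.tss - half)
    hi = min(len(cov), gene.tss + half + 1)
    region = cov[lo:hi]
    if len(region) == 0 or region.max() <= 0:
        logger.info("gene %s skipped: no coverage around TSS", gene.gene_id)
        return None
    maxval = region.max()
    candidates = lo + np.flatnonzero(region == maxval)
    downstream_sign = 1 if gene.strand == "+" else -1
    best = min(
        candidates,
        key=lambda pos: (abs(pos - gene.tss), -downstream_sign * (pos - gene.tss)),
    )
    return int(best)


def metagene_profile(
    track: CoverageTrack,
    anchors: Sequence[Tuple[str, int, str]],
    flank: int = 1500,
) -> MetageneProfile:
    """Average track coverage around anchors, strand-aware.

    ``anchors`` are (contig, position, strand); - strand anchors
    contribute their neighbourhood reversed.  Anchors closer than
    ``flank`` to a contig edge contribute only their defined offsets.
    """
    width = 2 * flank + 1
    sums = np.zeros(width)
    counts = np.zeros(width)
    used = 0
    for contig, pos, strand in anchors:
        if contig not in track.data:
            continue
        cov = track.data[contig]
        lo = max(0, pos - flank)
        hi = min(len(cov), pos + flank + 1)
        if hi <= lo:
            continue
        sl = cov[lo:hi]
        idx = np.arange(lo - pos + flank, hi - pos + flank)
        if strand == "-":
            idx = width - 1 - idx
        sums[idx] += sl
        counts[idx] += 1
        used += 1
    if used == 0:
        raise ValueError("no usable anchors for the metagene profile")
    values = np.full(width, np.nan)
    np.divide(sums, counts, out=values, where=counts > 0)
    return MetageneProfile(np.arange(-flank, flank + 1), values, used)


def nucleosome_occupancy(
    track: CoverageTrack,
    contig: str,
    dyad: int,
    width: int = 176,
) -> float:
    """Area under the curve over one nucleosome: sum over [dyad-88, dyad+88)."""
    cov = track.data[contig]
    half = width // 2
    lo = max(0, dyad - half)
    hi = min(len(cov), dyad - half + width)
    return float(cov[lo:hi].sum())


# ---------------------------------------------------------------------------
# Nucleosome repeat length
# ---------------------------------------------------------------------------

def estimate_spacing(
    dyads: Optional[Sequence[Sequence[int]]] = None,
    profile: Optional[MetageneProfile] = None,
    min_lag: int = 50,
    max_lag: int = 400,
    min_acf: float = 0.1,
    n_boot: int = 200,
    seed: int = 0,
) -> SpacingEstimate:
    """Nucleosome repeat length from dyad calls or a phased profile.

    With ``dyads`` (a list of ordered dyad runs) the estimate is the
    median successive-dyad distance with a bootstrap percentile CI.  With
    ``profile`` the estimate is the lag of the fundamental maximum of the
    profile autocorrelation; aperiodic input (peak autocorrelation below
    ``min_acf``) yields repeat_bp None.
    """
    if dyads is not None:
        diffs = np.concatenate(
            [np.diff(np.sort(np.asarray(run))) for run in dyads if len(run) >= 2]
        ) if any(len(run) >= 2 for run in dyads) else np.array([])
        if len(diffs) < 4:
            raise ValueError("need at least 5 dyads to estimate spacing")
        est = float(np.median(diffs))
        rng = np.random.default_rng(seed)
        boots = [
            float(np.median(rng.choice(diffs, size=len(diffs), replace=True)))
            for _ in range(n_boot)
        ]
        return SpacingEstimate(est, float(np.percentile(boots, 2.5)),
                               float(np.percentile(boots, 97.5)))
    if profile is None:
        raise ValueError("provide dyads or a profile")
    v = profile.values[np.isfinite(profile.values)]
    if len(v) < 3 * min_lag:
        raise ValueError("profile too short for spacing estimation")
    x = v - v.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        return SpacingEstimate(None)
    hi = min(max_lag, len(x) - 1)
    acf = np.array([np.dot(x[:-lag], x[lag:]) / denom for lag in range(min_lag, hi + 1)])
    best = int(np.argmax(acf))
    if acf[best] < min_acf:
        return SpacingEstimate(None)
    return SpacingEstimate(float(min_lag + best))


# ---------------------------------------------------------------------------
# Binding-site occupancy vs randomized background
# ---------------------------------------------------------------------------

def site_occupancy_ratio(
    track: CoverageTrack,
    sites: Sequence[Tuple[str, int]],
    genes: Sequence[GeneModel],
    seed: int = 0,
    n_draws: Optional[int] = None,
) -> Tuple[float, float, float]:
    """Mean site occupancy as a ratio to a TSS-distance-matched background.

    Observed: mean normalized coverage at site summits.  Background: the
    distances |summit - nearest TSS| are fitted with a negative binomial
    by the method of moments; the same number of random distances is drawn
    and placed relative to randomly chosen TSSs, strand-aware and on the
    same side of the TSS as the observed sites, and the mean coverage at
    those random positions is computed.  Returns (observed, background,
    ratio); the ratio removes promoter-proximity bias.
    """
    if len(sites) < 10:
        raise ValueError("need at least 10 sites")
    rng = np.random.default_rng(seed)
    observed_vals = []
    dists, sides = [], []
    genes_by_contig: Dict[str, List[GeneModel]] = {}
    for g in genes:
        genes_by_contig.setdefault(g.contig, []).append(g)
    for contig, summit in sites:
        observed_vals.append(track.data[contig][summit])
        cands = genes_by_contig.get(contig, [])
        if not cands:
            continue
        g = min(cands, key=lambda g: abs(g.tss - summit))
        off = summit - g.tss if g.strand == "+" else g.tss - summit
        dists.append(abs(off))
        sides.append(1 if off >= 0 else -1)
    observed = float(np.mean(observed_vals))
    if not dists:
        raise ValueError("no genes available to anchor the background")

    dists = np.asarray(dists, dtype=float)
    n = n_draws or max(len(sites) * 20, 1000)
    m, v = dists.mean(), dists.var(ddof=1)
    if v > m > 0:
        r = m**2 / (v - m)
        rand_d = rng.negative_binomial(r, r / (r + m), size=n).astype(float)
    else:
        logger.info("NB moment fit infeasible (var <= mean); resampling distances")
        rand_d = rng.choice(dists, size=n, replace=True)
    rand_sides = rng.choice(np.asarray(sides), size=n, replace=True)

    all_genes = [g for g in genes if g.contig in track.data]
    pick = rng.integers(0, len(all_genes), size=n)
    bg_vals = np.empty(n)
    for i in range(n):
        g = all_genes[pick[i]]
        step = rand_sides[i] if g.strand == "+" else -rand_sides[i]
        pos = int(g.tss + step * rand_d[i])
        pos = min(max(pos, 0), len(track.data[g.contig]) - 1)
        bg_vals[i] = track.data[g.contig][pos]
    background = float(bg_vals.mean())
    if background <= 0:
        raise ValueError("background coverage is zero; cannot form a ratio")
    return observed, background, observed / background


# ---------------------------------------------------------------------------
# Sub-nucleosomal footprints
# ---------------------------------------------------------------------------

def footprint_profile(
    subnuc_fragments: pd.DataFrame,
    sites: Sequence[Tuple[str, int]],
    genome: GenomeSequence,
    flank: int = 500,
) -> MetageneProfile:
    """Average sub-nucleosomal coverage around site summits.

    Fragments < 100 bp contribute their full extent to the coverage; the
    profile over summit +/- flank is normalized by the genome-wide mean
    sub-nucleosomal coverage, so 1.0 is background level.
    """
    if len(subnuc_fragments) == 0:
        raise ValueError("no sub-nucleosomal fragments")
    from .peaks import fragment_coverage

    track = fragment_coverage(subnuc_fragments, genome)
    mean_cov = track.total_mass() / genome.total_length()
    if mean_cov <= 0:
        raise ValueError("zero sub-nucleosomal coverage")
    prof = metagene_profile(track, [(c, p, "+") for c, p in sites], flank=flank)
    return MetageneProfile(prof.offsets, prof.values / mean_cov, prof.n_anchors)


# ---------------------------------------------------------------------------
# End-to-end driver
# ---------------------------------------------------------------------------

def run_nucmap(
    fragments: pd.DataFrame,
    genome: GenomeSequence,
    genes: Sequence[GeneModel],
    percentile: float = 90.0,
    bandwidth: float = 30.0,
    flank: int = 1500,
    plus_one_window: int = 200,
    nucleosome_width: int = 176,
):
    """Fragments -> normalized smoothed track, +1 calls, metagene, spacing."""
    classes = classify_fragments(fragments)
    raw = midpoint_coverage(classes["nucleosomal"], genome)
    norm = normalize_track(raw, percentile=percentile)
    smooth = smooth_track(norm, bandwidth_bp=bandwidth)

    plus_one = {}
    for g in genes:
        pos = locate_plus_one(smooth, g, window=plus_one_window)
        if pos is not None:
            plus_one[g.gene_id] = pos
    gene_by_id = {g.gene_id: g for g in genes}
    anchors = [(gene_by_id[gid].contig, pos, gene_by_id[gid].strand)
               for gid, pos in plus_one.items()]
    profile = metagene_profile(smooth, anchors, flank=flank) if anchors else None
    occupancy = {
        gid: nucleosome_occupancy(smooth, gene_by_id[gid].contig, pos, nucleosome_width)
        for gid, pos in plus_one.items()
    }
    spacing = estimate_spacing(profile=profile) if profile is not None else SpacingEstimate(None)
    return {
        "classes": classes,
        "track": smooth,
        "plus_one": plus_one,
        "profile": profile,
        "occupancy": occupancy,
        "spacing": spacing,
    }
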