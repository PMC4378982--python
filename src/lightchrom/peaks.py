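"""Sliding-window Poisson ChIP-seq peak calling and downstream analyses.

The genome is scanned with 150 bp windows advancing by 50 bp; fragment 5'
positions are counted per window and each treatment window is tested
against the depth-scaled control count under a Poisson null.  A binding
site is called where at least four consecutive windows are significant at
p < 1e-5, then filtered for enrichment (>= 1.5-fold over the genome-wide
mean window coverage and above the 90th percentile of window coverage).
Peaks are annotated to genes through a three-rule promoter/nearest-gene
procedure, and dark-versus-light differential binding is classified with
an 80% prediction interval around a log-scale regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import CoverageTrack, GeneModel, GenomeSequence


@dataclass
class Peak:
    """A called binding site: interval, summit and coverage statistics."""

    contig: str
    start: int
    end: int
    summit: int
    coverage: float          # mean per-base treatment coverage over the peak
    min_p: float
    fold_enrichment: float = 0.0
    name: str = ""
    provenance: Tuple[str, ...] = ()


@dataclass
class WindowStats:
    """Per-contig window counts for treatment and control plus Poisson p."""

    width: int
    step: int
    treat: Dict[str, np.ndarray]
    control: Dict[str, np.ndarray]
    p: Dict[str, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Window scan
# ---------------------------------------------------------------------------

def window_scan(
    fragments: pd.DataFrame,
    genome: GenomeSequence,
    width: int = 150,
    step: int = 50,
) -> Dict[str, np.ndarray]:
    """Count fragment 5' positions per sliding window.

    A fragment is counted in every window whose [start, start+width) span
    contains its 5' position; windows advance by ``step``.
    """
    if width % step != 0:
        raise ValueError("window width should be a multiple of the step")
    counts: Dict[str, np.ndarray] = {}
    for contig, L in genome.lengths().items():
        n_win = max(0, (L - width) // step + 1)
        counts[contig] = np.zeros(n_win, dtype=np.int64)
    for contig, grp in fragments.groupby("contig"):
        if contig not in counts:
            continue
        n_win = len(counts[contig])
        x = grp["start"].to_numpy()
        base = x // step
        for k in range(width // step):
            j = base - k
            ok = (j >= 0) & (j < n_win)
            counts[contig] += np.bincount(j[ok], minlength=n_win)
    return counts


def poisson_window_test(k_treat, k_control, scale: float, lambda_floor: float = 0.5):
    """Upper-tail Poisson p for a treatment window against its control.

    lambda = max(k_control, lambda_floor) * scale, where ``scale`` is the
    treatment/control total-mapped-reads ratio; p = P(X >= k_treat).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    lam = np.maximum(np.asarray(k_control, dtype=float), lambda_floor) * scale
    return stats.poisson.sf(np.asarray(k_treat) - 1, lam)


def scan_and_test(
    treat_frags: pd.DataFrame,
    control_frags: pd.DataFrame,
    genome: GenomeSequence,
    width: int = 150,
    step: int = 50,
    lambda_floor: float = 0.5,
) -> WindowStats:
    """Window counts for both samples plus per-window Poisson p-values."""
    treat = window_scan(treat_frags, genome, width, step)
    control = window_scan(control_frags, genome, width, step)
    n_t = max(1, len(treat_frags))
    n_c = max(1, len(control_frags))
    scale = n_t / n_c
    stats_ = WindowStats(width=width, step=step, treat=treat, control=control)
    for contig in treat:
        stats_.p[contig] = poisson_window_test(
            treat[contig], control[contig], scale, lambda_floor
        )
    return stats_


# ---------------------------------------------------------------------------
# Coverage and peak calling
# ---------------------------------------------------------------------------

def fragment_coverage(fragments: pd.DataFrame, genome: GenomeSequence) -> CoverageTrack:
    """Per-base coverage of fragment intervals."""
    data = {}
    for contig, L in genome.lengths().items():
        diff = np.zeros(L + 1)
        grp = fragments[fragments["contig"] == contig]
        if len(grp):
            starts = np.clip(grp["start"].to_numpy(), 0, L)
            ends = np.clip(grp["end"].to_numpy(), 0, L)
            np.add.at(diff, starts, 1.0)
            np.add.at(diff, ends, -1.0)
        data[contig] = np.cumsum(diff[:-1])
    return CoverageTrack(data, source="fragment coverage")


def call_peaks(
    stats_: WindowStats,
    coverage: CoverageTrack,
    p_thresh: float = 1e-5,
    min_consecutive: int = 4,
) -> List[Peak]:
    """Merge runs of >= min_consecutive significant windows into peaks.

    A peak spans from the first window start of the run to the last
    window's end; its summit is the position of maximum per-base treatment
    coverage inside the peak (first position on ties).
    """
    peaks: List[Peak] = []
    width, step = stats_.width, stats_.step
    for contig in sorted(stats_.p):
        pvals = stats_.p[contig]
        sig = pvals < p_thresh
        cov = coverage.data[contig]
        i = 0
        n = len(sig)
        while i < n:
            if not sig[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and sig[j + 1]:
                j += 1
            if j - i + 1 >= min_consecutive:
                start = i * step
                end = j * step + width
                local = cov[start:end]
                summit = start + int(np.argmax(local))
                peaks.append(
                    Peak(
                        contig=contig,
                        start=start,
                        end=end,
                        summit=summit,
                        coverage=float(local.mean()),
                        min_p=float(pvals[i: j + 1].min()),
                    )
                )
            i = j + 1
    for k, p in enumerate(peaks, 1):
        p.name = f"peak_{k:04d}"
    return peaks


def filter_enrichment(
    peaks: Sequence[Peak],
    track: CoverageTrack,
    min_fold: float = 1.5,
    percentile: float = 90.0,
    width: int = 150,
    step: int = 50,
) -> List[Peak]:
    """Drop low-enrichment peaks.

    A peak is kept when its mean per-base coverage is at least ``min_fold``
    times the genome-wide mean window coverage and at least the
    ``percentile``-th percentile of window coverage.
    """
    win_cov = []
    for contig, cov in track.data.items():
        c = np.concatenate([[0.0], np.cumsum(cov)])
        n_win = max(0, (len(cov) - width) // step + 1)
        if n_win:
            starts = np.arange(n_win) * step
            win_cov.append((c[starts + width] - c[starts]) / width)
    if not win_cov:
        return []
    win_cov = np.concatenate(win_cov)
    general = float(win_cov.mean())
    cutoff = float(np.percentile(win_cov, percentile))
    kept = []
    for p in peaks:
        fold = p.coverage / general if general > 0 else np.inf
        if p.coverage >= min_fold * general and p.coverage >= cutoff:
            kept.append(replace(p, fold_enrichment=fold))
    return kept


def merge_peak_sets(a: Sequence[Peak], b: Sequence[Peak]) -> List[Peak]:
    """Union peaks overlapping by >= 1 bp; provenance of both retained."""
    tagged = [(p, p.provenance or ("a",)) for p in a] + [
        (p, p.provenance or ("b",)) for p in b
    ]
    tagged.sort(key=lambda t: (t[0].contig, t[0].start, t[0].end))
    merged: List[Peak] = []
    for p, prov in tagged:
        if merged and merged[-1].contig == p.contig and p.start < merged[-1].end:
            last = merged[-1]
            best = last if last.coverage >= p.coverage else p
            merged[-1] = Peak(
                contig=last.contig,
                start=last.start,
                end=max(last.end, p.end),
                summit=best.summit,
                coverage=max(last.coverage, p.coverage),
                min_p=min(last.min_p, p.min_p),
                fold_enrichment=max(last.fold_enrichment, p.fold_enrichment),
                provenance=tuple(sorted(set(last.provenance) | set(prov))),
            )
        else:
            merged.append(replace(p, provenance=tuple(sorted(set(prov)))))
    for k, p in enumerate(merged, 1):
        p.name = f"site_{k:04d}"
    return merged


# ---------------------------------------------------------------------------
# Peak-to-gene annotation
# ---------------------------------------------------------------------------

def annotate_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    upstream: int = 1000,
    downstream: int = 500,
) -> List[Tuple[Peak, Optional[str], str, Optional[int]]]:
    """Annotate peak summits to genes by the three-rule procedure.

    Rule "promoter": every gene whose strand-aware promoter window
    [TSS - upstream, TSS + downstream] (boundaries inclusive; flipped for
    - strand genes) contains the summit.  Rule "nearest-upstream": if no
    promoter window matches, the nearest gene whose TSS lies downstream of
    the summit in the gene's orientation, with no distance limit.  Rule
    "unannotated" otherwise.  Returns (peak, gene_id or None, rule,
    signed distance summit-to-TSS or None).
    """
    out = []
    for p in peaks:
        contig_genes = [g for g in genes if g.contig == p.contig]
        hits = []
        for g in contig_genes:
            if g.strand == "+":
                lo, hi = g.tss - upstream, g.tss + downstream
            else:
                lo, hi = g.tss - downstream, g.tss + upstream
            if lo <= p.summit <= hi:
                hits.append(g)
        if hits:
            for g in hits:
                out.append((p, g.gene_id, "promoter", p.summit - g.tss))
            continue
        upstream_genes = [
            g
            for g in contig_genes
            if (g.strand == "+" and p.summit < g.tss)
            or (g.strand == "-" and p.summit > g.tss)
        ]
        if upstream_genes:
            g = min(upstream_genes, key=lambda g: (abs(g.tss - p.summit), g.gene_id))
            out.append((p, g.gene_id, "nearest-upstream", p.summit - g.tss))
        else:
            out.append((p, None, "unannotated", None))
    return out


# ---------------------------------------------------------------------------
# Differential binding via prediction intervals
# ---------------------------------------------------------------------------

@dataclass
class SiteClassification:
    site_id: str
    dark: float
    light: float
    predicted: float
    lower: float
    upper: float
    label: str  # light-induced / unchanged / light-reduced


def classify_light_regulated(
    site_ids: Sequence[str],
    dark_intensity: Sequence[float],
    light_intensity: Sequence[float],
    band: float = 0.80,
) -> List[SiteClassification]:
    """Classify sites by position relative to a regression prediction band.

    Ordinary least squares of log2(light + 1) on log2(dark + 1) across all
    sites; each site is compared with its ``band`` (default 80%) prediction
    interval: above the upper bound -> light-induced, below the lower ->
    light-reduced, otherwise unchanged.
    """
    if len(site_ids) < 10:
        raise ValueError("need at least 10 sites for the regression")
    x = np.log2(np.asarray(dark_intensity, dtype=float) + 1.0)
    y = np.log2(np.asarray(light_intensity, dtype=float) + 1.0)
    if np.ptp(x) == 0:
        raise ValueError("degenerate regression: dark intensities have zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    frame = model.get_prediction(sm.add_constant(x)).summary_frame(alpha=1.0 - band)
    lower = frame["obs_ci_lower"].to_numpy()
    upper = frame["obs_ci_upper"].to_numpy()
    fitted = frame["mean"].to_numpy()
    out = []
    for i, sid in enumerate(site_ids):
        if y[i] > upper[i]:
            label = "light-induced"
        elif y[i] < lower[i]:
            label = "light-reduced"
        else:
            label = "unchanged"
        out.append(
            SiteClassification(
                site_id=str(sid),
                dark=float(x[i]),
                light=float(y[i]),
                predicted=float(fitted[i]),
                lower=float(lower[i]),
                upper=float(upper[i]),
                label=label,
            )
        )
    return out


# ---------------------------------------------------------------------------
# End-to-end driver
# ---------------------------------------------------------------------------

def run_peak_calling(
    treat_frags: pd.DataFrame,
    control_frags: pd.DataFrame,
    genome: GenomeSequence,
    genes: Sequence[GeneModel] = (),
    width: int = 150,
    step: int = 50,
    p_thresh: float = 1e-5,
    min_consecutive: int = 4,
    min_fold: float = 1.5,
    percentile: float = 90.0,
    lambda_floor: float = 0.5,
):
    """Scan, test, call, filter and (optionally) annotate in one pass."""
    stats_ = scan_and_test(treat_frags, control_frags, genome, width, step, lambda_floor)
    coverage = fragment_coverage(treat_frags, genome)
    raw = call_peaks(stats_, coverage, p_thresh, min_consecutive)
    peaks = filter_enrichment(raw, coverage, min_fold, percentile, width, step)
    annotation = annotate_peaks(peaks, genes) if genes else []
    return peaks, annotation, stats_, coverage
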