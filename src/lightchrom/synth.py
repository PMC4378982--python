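"""Synthetic genomes, annotations, counts, ChIP and MNase fragments.

Every generator is a pure function of its parameters and an explicit seed,
and returns its planted ground truth alongside the data so that pipeline
stages can be scored against what was actually planted.

The generators emulate the statistical structure the downstream analysis
assumes: negative-binomial gene counts with a smooth mean-variance trend
and planted light-induction time profiles (dark plus 30/60/120 min),
single-end ChIP fragments with Poisson background and planted enriched
sites, paired-end MNase fragments from phased nucleosome arrays with
planted sub-nucleosomal TF footprints, and genome sequence with planted
motifs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import GeneModel, GenomeSequence

LIGHT_TIMEPOINTS = ("30", "60", "120")
DARK = "DD"


@dataclass
class TruthRecord:
    """Planted ground truth, serialized alongside generated data."""

    seed: int = 0
    de_genes: Optional[pd.DataFrame] = None       # gene_id, class, dependent, fold_30/60/120
    sites: Optional[pd.DataFrame] = None          # contig, position, fold
    dyads: Optional[pd.DataFrame] = None          # contig, position, array_id, repeat, occupancy
    footprints: Optional[pd.DataFrame] = None     # contig, position, width
    motifs: Optional[pd.DataFrame] = None         # contig, position, pattern

    _PARTS = ("de_genes", "sites", "dyads", "footprints", "motifs")

    def save(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "truth_meta.txt"), "w") as fh:
            fh.write(f"seed = {self.seed}\n")
            for part in self._PARTS:
                df = getattr(self, part)
                fh.write(f"{part} = {'absent' if df is None else len(df)}\n")
        for part in self._PARTS:
            df = getattr(self, part)
            if df is not None:
                df.to_csv(os.path.join(outdir, f"truth_{part}.tsv"), sep="\t", index=False)

    @classmethod
    def load(cls, outdir: str) -> "TruthRecord":
        rec = cls()
        with open(os.path.join(outdir, "truth_meta.txt")) as fh:
            for line in fh:
                key, _, val = line.partition("=")
                if key.strip() == "seed":
                    rec.seed = int(val)
        for part in cls._PARTS:
            path = os.path.join(outdir, f"truth_{part}.tsv")
            if os.path.exists(path):
                setattr(rec, part, pd.read_csv(path, sep="\t"))
        return rec

    def merge(self, other: "TruthRecord") -> "TruthRecord":
        out = TruthRecord(seed=self.seed)
        for part in self._PARTS:
            mine, theirs = getattr(self, part), getattr(other, part)
            setattr(out, part, theirs if mine is None else mine)
        return out


# ---------------------------------------------------------------------------
# Genome and annotation
# ---------------------------------------------------------------------------

def make_genome(
    n_contigs: int = 1,
    contig_length: int = 1_000_000,
    gc_fraction: float = 0.5,
    seed: int = 0,
) -> GenomeSequence:
    """I.i.d. random genome at the stated GC content."""
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must lie strictly between 0 and 1")
    if contig_length < 1:
        raise ValueError("contig_length must be positive")
    rng = np.random.default_rng(seed)
    at, gc = (1.0 - gc_fraction) / 2.0, gc_fraction / 2.0
    bases = np.frombuffer(b"ACGT", dtype="S1")
    contigs = {}
    for i in range(n_contigs):
        draw = rng.choice(bases, size=contig_length, p=[at, gc, gc, at])
        contigs[f"contig_{i + 1}"] = draw.tobytes().decode("ascii")
    return GenomeSequence(contigs)


def make_annotation(
    genome: GenomeSequence,
    n_genes: int = 100,
    min_gene_length: int = 1000,
    max_gene_length: int = 3000,
    min_intergenic: int = 500,
    strand_prob: float = 0.5,
    seed: int = 0,
) -> List[GeneModel]:
    """Place non-overlapping genes with mixed strands across the genome.

    Genes are laid out contig by contig with random lengths in
    [min_gene_length, max_gene_length] and random extra slack distributed
    between them, so gene starts are irregular but gaps never fall below
    ``min_intergenic``.
    """
    rng = np.random.default_rng(seed)
    contigs = list(genome)
    lengths = genome.lengths()
    total = sum(lengths.values())
    per_contig = [max(1, round(n_genes * lengths[c] / total)) for c in contigs]
    # adjust rounding so the total is exact
    while sum(per_contig) > n_genes:
        per_contig[int(np.argmax(per_contig))] -= 1
    while sum(per_contig) < n_genes:
        per_contig[int(np.argmin(per_contig))] += 1

    genes: List[GeneModel] = []
    idx = 0
    for contig, k in zip(contigs, per_contig):
        L = lengths[contig]
        glens = rng.integers(min_gene_length, max_gene_length + 1, size=k)
        needed = int(glens.sum()) + (k + 1) * min_intergenic
        if needed > L:
            raise ValueError(
                f"cannot pack {k} genes into contig {contig!r} "
                f"({needed} bp needed, {L} bp available)"
            )
        slack = L - needed
        # spread the slack over the k+1 gaps
        cuts = np.sort(rng.integers(0, slack + 1, size=k))
        extra = np.diff(np.concatenate([[0], cuts, [slack]]))
        pos = 0
        for j in range(k):
            pos += min_intergenic + int(extra[j])
            start, end = pos, pos + int(glens[j])
            strand = "+" if rng.random() < strand_prob else "-"
            idx += 1
            if strand == "+":
                genes.append(GeneModel(f"gene_{idx:05d}", contig, "+", tss=start, end=end))
            else:
                genes.append(GeneModel(f"gene_{idx:05d}", contig, "-", tss=end - 1, end=start))
            pos = end
    return genes


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

@dataclass
class CountModel:
    """Generative model for NB gene counts with a smooth mean-variance trend.

    Per-gene baseline means are log-normal.  The variance function is
    v(m) = m + phi(m) * m^2 with trend phi(m) = phi0 + phi1/m, which
    decreases in m; phi0 = phi1 = 0 gives the Poisson limit.  Planted
    induced genes follow one of two time profiles over dark (DD) and the
    30/60/120-min light timepoints: "early" genes peak at 30 min and decay,
    "late" genes rise monotonically.  A fraction of induced genes is
    genotype-dependent: their light folds are multiplied by the genotype's
    factor (e.g. halved in a knock-out, doubled in an over-expressor).
    """

    mean_log_mu: float = float(np.log(50.0))
    mean_log_sigma: float = 1.0
    phi0: float = 0.01
    phi1: float = 0.5
    frac_induced: float = 0.10
    frac_early: float = 0.5
    frac_dependent: float = 0.5
    early_profile: Dict[str, float] = field(
        default_factory=lambda: {"30": 8.0, "60": 4.0, "120": 2.0}
    )
    late_profile: Dict[str, float] = field(
        default_factory=lambda: {"30": 1.5, "60": 3.0, "120": 6.0}
    )
    genotype_factor: Dict[str, float] = field(
        default_factory=lambda: {"wt": 1.0, "ko": 0.5, "oe": 2.0}
    )
    size_factors: Optional[Dict[str, float]] = None

    def dispersion(self, mean: np.ndarray) -> np.ndarray:
        mean = np.asarray(mean, dtype=float)
        with np.errstate(divide="ignore"):
            return self.phi0 + np.where(mean > 0, self.phi1 / mean, 0.0)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Draw NB(mean, variance = mean + phi*mean^2); Poisson where phi==0."""
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape)
    out = np.zeros(mean.shape, dtype=np.int64)
    pois = phi <= 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    nb = ~pois & (mean > 0)
    if nb.any():
        r = 1.0 / phi[nb]
        p = r / (r + mean[nb])
        out[nb] = rng.negative_binomial(r, p)
    return out


def simulate_counts(
    model: CountModel,
    genes: Sequence[str],
    samples: Sequence[str],
    seed: int = 0,
) -> Tuple[pd.DataFrame, TruthRecord]:
    """Simulate an integer count table with planted induction profiles.

    ``samples`` are ``genotype_timepoint`` labels; timepoints are DD (dark)
    or minutes after light exposure.  Null genes have fold 1 everywhere.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    samples = list(samples)
    n = len(genes)
    mu = rng.lognormal(model.mean_log_mu, model.mean_log_sigma, size=n)

    n_induced = int(round(model.frac_induced * n))
    induced_idx = rng.choice(n, size=n_induced, replace=False)
    n_early = int(round(model.frac_early * n_induced))
    early = set(induced_idx[:n_early].tolist())
    late = set(induced_idx[n_early:].tolist())
    n_dep = int(round(model.frac_dependent * n_induced))
    dependent = set(rng.permutation(induced_idx)[:n_dep].tolist())

    sf = model.size_factors or {s: 1.0 for s in samples}

    def fold(i: int, genotype: str, timepoint: str) -> float:
        if timepoint == DARK:
            return 1.0
        if i in early:
            f = model.early_profile[timepoint]
        elif i in late:
            f = model.late_profile[timepoint]
        else:
            return 1.0
        g = model.genotype_factor.get(genotype, 1.0)
        if i in dependent and g != 1.0:
            f = max(1.0, f * g) if g < 1.0 else f * g
        return f

    counts = np.zeros((n, len(samples)), dtype=np.int64)
    for j, label in enumerate(samples):
        genotype, _, timepoint = label.rpartition("_")
        folds = np.array([fold(i, genotype, timepoint) for i in range(n)])
        m = sf[label] * mu * folds
        counts[:, j] = _nb_draw(rng, m, model.dispersion(m))

    table = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples)
    truth = pd.DataFrame(
        {
            "gene_id": [genes[i] for i in sorted(induced_idx.tolist())],
            "class": ["early" if i in early else "late" for i in sorted(induced_idx.tolist())],
            "dependent": [i in dependent for i in sorted(induced_idx.tolist())],
        }
    )
    for t in LIGHT_TIMEPOINTS:
        truth[f"fold_{t}"] = [
            model.early_profile[t] if i in early else model.late_profile[t]
            for i in sorted(induced_idx.tolist())
        ]
    truth["baseline_mean"] = [mu[i] for i in sorted(induced_idx.tolist())]
    return table, TruthRecord(seed=seed, de_genes=truth)


# ---------------------------------------------------------------------------
# ChIP fragments
# ---------------------------------------------------------------------------

def simulate_chip(
    genome: GenomeSequence,
    sites: Sequence[Tuple[str, int, float]],
    depth: float = 30.0,
    fragment_mean: int = 200,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Simulate treatment and control ChIP fragments.

    Control fragment midpoints are uniform on the genome.  Treatment
    midpoints are drawn with relative rate ``fold`` inside a window of
    +/- fragment_mean/2 around each planted summit and 1 elsewhere, so
    per-base treatment coverage peaks at the planted summit.  Fragment
    lengths are normal(fragment_mean, fragment_mean/5) truncated at 50 bp.
    Returns (treatment, control, truth).
    """
    rng = np.random.default_rng(seed)
    lengths = genome.lengths()
    for contig, pos, fold_ in sites:
        if contig not in lengths or not 0 <= pos < lengths[contig]:
            raise ValueError(f"site {contig}:{pos} outside the genome")
        if fold_ < 1:
            raise ValueError("site fold enrichments must be >= 1")

    half = fragment_mean // 2
    t_frames, c_frames = [], []
    for contig, L in lengths.items():
        n_frag = int(round(depth * L / fragment_mean))
        weight = np.ones(L)
        for sc, pos, fold_ in sites:
            if sc == contig:
                weight[max(0, pos - half): min(L, pos + half)] = fold_
        t_mid = rng.choice(L, size=n_frag, p=weight / weight.sum())
        c_mid = rng.integers(0, L, size=n_frag)
        for mids, frames in ((t_mid, t_frames), (c_mid, c_frames)):
            flen = np.maximum(
                50, np.rint(rng.normal(fragment_mean, fragment_mean / 5, size=n_frag))
            ).astype(int)
            start = np.clip(mids - flen // 2, 0, None)
            end = np.minimum(start + flen, L)
            frames.append(pd.DataFrame({"contig": contig, "start": start, "end": end}))
    treat = pd.concat(t_frames, ignore_index=True)
    ctrl = pd.concat(c_frames, ignore_index=True)
    truth = TruthRecord(
        seed=seed,
        sites=pd.DataFrame(sites, columns=["contig", "position", "fold"]),
    )
    return treat, ctrl, truth


# ---------------------------------------------------------------------------
# MNase fragments
# ---------------------------------------------------------------------------

def simulate_mnase(
    genome: GenomeSequence,
    arrays: Sequence[Tuple[str, int, int, int, float]],
    footprints: Sequence[Tuple[str, int, int]] = (),
    depth: float = 30.0,
    center_jitter_sd: float = 10.0,
    background_per_kb: float = 2.0,
    seed: int = 0,
) -> Tuple[pd.DataFrame, TruthRecord]:
    """Simulate paired-end MNase fragments from phased nucleosome arrays.

    ``arrays`` are (contig, anchor, n_nucs, repeat_length, occupancy):
    dyads sit at anchor + i*repeat_length.  Nucleosomal fragments are
    centered on dyads with normal(0, center_jitter_sd) jitter and lengths
    normal(150, 10) truncated to [100, 1000]; each dyad emits
    Poisson(depth * occupancy) fragments.  ``footprints`` are
    (contig, position, width < 100): footprint fragments have lengths
    normal(60, 10) truncated below 100.  A uniform background of both
    fragment classes is added at ``background_per_kb`` fragments per kb
    per class.
    """
    rng = np.random.default_rng(seed)
    lengths = genome.lengths()

    spans = []
    for contig, anchor, n_nucs, repeat, occupancy in arrays:
        if repeat < 147:
            raise ValueError("nucleosome repeat length must be >= 147 bp")
        lo = anchor - repeat // 2
        hi = anchor + (n_nucs - 1) * repeat + repeat // 2
        if not (0 <= lo and hi < lengths[contig]):
            raise ValueError(f"array at {contig}:{anchor} extends outside the genome")
        for c2, lo2, hi2 in spans:
            if c2 == contig and lo < hi2 and lo2 < hi:
                raise ValueError(f"nucleosome arrays overlap on {contig}")
        spans.append((contig, lo, hi))
    for contig, pos, width in footprints:
        if width >= 100:
            raise ValueError("footprint width must be < 100 bp")

    frames = []
    dyad_rows = []
    for a_id, (contig, anchor, n_nucs, repeat, occupancy) in enumerate(arrays):
        L = lengths[contig]
        for k in range(n_nucs):
            dyad = anchor + k * repeat
            dyad_rows.append((contig, dyad, a_id, repeat, occupancy))
            n = rng.poisson(depth * occupancy)
            if n == 0:
                continue
            centers = dyad + rng.normal(0.0, center_jitter_sd, size=n)
            flen = np.clip(np.rint(rng.normal(150.0, 10.0, size=n)), 100, 1000).astype(int)
            start = np.clip(np.rint(centers).astype(int) - flen // 2, 0, None)
            end = np.minimum(start + flen, L)
            frames.append(pd.DataFrame({"contig": contig, "start": start, "end": end}))

    for contig, pos, width in footprints:
        L = lengths[contig]
        n = rng.poisson(depth)
        if n == 0:
            continue
        centers = pos + rng.normal(0.0, 5.0, size=n)
        flen = np.clip(np.rint(rng.normal(60.0, 10.0, size=n)), 20, 99).astype(int)
        start = np.clip(np.rint(centers).astype(int) - flen // 2, 0, None)
        end = np.minimum(start + flen, L)
        frames.append(pd.DataFrame({"contig": contig, "start": start, "end": end}))

    # uniform background: one nucleosomal-length and one sub-nucleosomal class
    for contig, L in lengths.items():
        n_bg = rng.poisson(background_per_kb * L / 1000.0)
        for mean_len, sd, lo, hi in ((150.0, 10.0, 100, 1000), (60.0, 10.0, 20, 99)):
            mids = rng.integers(0, L, size=n_bg)
            flen = np.clip(np.rint(rng.normal(mean_len, sd, size=n_bg)), lo, hi).astype(int)
            start = np.clip(mids - flen // 2, 0, None)
            end = np.minimum(start + flen, L)
            frames.append(pd.DataFrame({"contig": contig, "start": start, "end": end}))

    frags = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["contig", "start", "end"])
    )
    truth = TruthRecord(
        seed=seed,
        dyads=pd.DataFrame(
            dyad_rows, columns=["contig", "position", "array_id", "repeat", "occupancy"]
        ),
        footprints=pd.DataFrame(list(footprints), columns=["contig", "position", "width"]),
    )
    return frags, truth


# ---------------------------------------------------------------------------
# Motif planting
# ---------------------------------------------------------------------------

def plant_motifs(
    genome: GenomeSequence,
    placements: Sequence[Tuple[str, int, str]],
) -> Tuple[GenomeSequence, TruthRecord]:
    """Substitute exact patterns into the genome at the stated positions.

    Placements must be non-overlapping and inside the genome.  To plant a
    tandem pair at center-to-center spacing d, supply two placements whose
    positions differ by d.
    """
    lengths = genome.lengths()
    by_contig: Dict[str, List[Tuple[int, str]]] = {}
    for contig, pos, pattern in placements:
        if contig not in lengths:
            raise ValueError(f"unknown contig {contig!r}")
        if not 0 <= pos <= lengths[contig] - len(pattern):
            raise ValueError(f"placement at {contig}:{pos} out of range")
        by_contig.setdefault(contig, []).append((pos, pattern.upper()))

    new = {c: genome[c] for c in genome}
    for contig, items in by_contig.items():
        items.sort()
        for (p1, m1), (p2, m2) in zip(items, items[1:]):
            if p1 + len(m1) > p2:
                raise ValueError(f"overlapping placements at {contig}:{p1} and {contig}:{p2}")
        seq = list(new[contig])
        for pos, pattern in items:
            seq[pos: pos + len(pattern)] = pattern
        new[contig] = "".join(seq)

    truth = TruthRecord(
        motifs=pd.DataFrame(list(placements), columns=["contig", "position", "pattern"])
    )
    return GenomeSequence(new), truth
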