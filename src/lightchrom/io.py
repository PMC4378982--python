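"""Domain types, standard-format I/O and run configuration.

Internal coordinates are 0-based half-open everywhere.  Conversion to and
from 1-based conventions (GFF3, fixedStep wiggle) happens only inside the
readers and writers in this module.
"""

from __future__ import annotations

import dataclasses
import io as _io
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """A file did not conform to the expected format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class GenomeSequence(Mapping):
    """Genome as a mapping contig name -> upper-case nucleotide string.

    The alphabet is restricted to A/C/G/T/N; contig names are unique and
    every contig is non-empty.
    """

    def __init__(self, contigs: Dict[str, str]):
        if not contigs:
            raise ValueError("genome must contain at least one contig")
        clean: Dict[str, str] = {}
        for name, seq in contigs.items():
            seq = seq.upper()
            if len(seq) < 1:
                raise ValueError(f"contig {name!r} is empty")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"contig {name!r} contains illegal characters: {sorted(bad)}"
                )
            clean[name] = seq
        self._contigs = clean

    def __getitem__(self, name: str) -> str:
        return self._contigs[name]

    def __iter__(self):
        return iter(self._contigs)

    def __len__(self) -> int:
        return len(self._contigs)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenomeSequence):
            return NotImplemented
        return self._contigs == other._contigs

    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self._contigs.items()}

    def total_length(self) -> int:
        return sum(len(s) for s in self._contigs.values())


@dataclass(frozen=True)
class GeneModel:
    """A gene anchor: id, contig, strand, TSS and far end (0-based).

    ``tss`` is the transcription start; ``end`` is the 0-based exclusive
    coordinate of the gene body on the + strand.  For a - strand gene the
    TSS is the larger coordinate (``tss == gff_end - 1``) and ``end`` holds
    the 0-based start of the span.
    """

    gene_id: str
    contig: str
    strand: str
    tss: int
    end: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def span(self) -> tuple:
        """0-based half-open genomic interval covered by the gene."""
        if self.strand == "+":
            return (self.tss, self.end)
        return (self.end, self.tss + 1)


@dataclass
class CoverageTrack:
    """Per-base numeric coverage on named contigs."""

    data: Dict[str, np.ndarray]
    normalized: bool = False
    source: str = ""

    def __post_init__(self):
        self.data = {c: np.asarray(v, dtype=float) for c, v in self.data.items()}
        for c, v in self.data.items():
            if v.ndim != 1:
                raise ValueError(f"track for contig {c!r} must be 1-D")

    def total_mass(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(
            {c: v.copy() for c, v in self.data.items()},
            normalized=self.normalized,
            source=self.source,
        )


@dataclass
class RunConfig:
    """All tunable parameters of the pipeline, with published defaults.

    Defaults follow the analysis this package reimplements: 150/50 bp
    window scan at p<1e-5 over >=4 consecutive windows, 1.5-fold / 90th
    percentile enrichment filter, promoter window -1000..+500 around the
    TSS, p<0.05 with a 2-fold gate for differential expression, 100-1000 bp
    nucleosomal fragments with middle-50-bp coverage normalized to the 90th
    percentile, 1500 bp metagene flank, 200 bp +1-nucleosome search window,
    176 bp nucleosome width, 80% prediction band, and 300 bp motif regions.
    """

    # counts / differential expression
    low_expr_quantile: float = 0.20
    de_alpha: float = 0.05
    de_min_fold: float = 2.0
    fold_pseudocount: float = 0.5
    lowess_span: float = 0.3

    # ChIP peak calling
    window_width: int = 150
    window_step: int = 50
    peak_p_thresh: float = 1e-5
    min_consecutive: int = 4
    lambda_floor: float = 0.5
    min_fold_enrichment: float = 1.5
    enrichment_percentile: float = 90.0
    promoter_upstream: int = 1000
    promoter_downstream: int = 500
    prediction_band: float = 0.80

    # MNase / nucleosomes
    nuc_min_len: int = 100
    nuc_max_len: int = 1000
    midpoint_span: int = 50
    norm_percentile: float = 90.0
    norm_window: int = 150
    smooth_bandwidth: float = 30.0
    metagene_flank: int = 1500
    plus_one_window: int = 200
    nucleosome_width: int = 176
    footprint_flank: int = 500

    # motifs
    motif_region: int = 300
    max_spacing: int = 150

    # misc
    seed: int = 0

    def override(self, **kwargs) -> "RunConfig":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **kwargs)


def load_config(path: str) -> RunConfig:
    """Read a flat ``key = value`` text file into a RunConfig.

    Blank lines and ``#`` comments are ignored; unknown keys are an error.
    """
    fields = {f.name: f.type for f in dataclasses.fields(RunConfig)}
    values = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected key = value")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise FormatError(f"{path}:{lineno}: unknown parameter {key!r}")
            default = getattr(RunConfig(), key)
            caster = int if isinstance(default, int) else float
            values[key] = caster(val)
    return RunConfig(**values)


def save_config(config: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        for f in dataclasses.fields(RunConfig):
            fh.write(f"{f.name} = {getattr(config, f.name)}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> GenomeSequence:
    """Load a FASTA file into a GenomeSequence (lower case folded up)."""
    contigs: Dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
        if first and not first.startswith(">"):
            raise FormatError(f"{path}:1: expected FASTA header line starting with '>'")
    for record in SeqIO.parse(path, "fasta"):
        if record.id in contigs:
            raise FormatError(f"{path}: duplicate contig name {record.id!r}")
        contigs[record.id] = str(record.seq).upper()
    if not contigs:
        raise FormatError(f"{path}: no FASTA records found")
    for name, seq in contigs.items():
        bad = set(seq) - VALID_BASES
        if bad:
            lineno = _find_bad_fasta_line(path, bad)
            raise FormatError(
                f"{path}:{lineno}: illegal character(s) {sorted(bad)} in contig {name!r}"
            )
    return GenomeSequence(contigs)


def _find_bad_fasta_line(path: str, bad: set) -> int:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">"):
                continue
            if set(line.strip().upper()) & bad:
                return lineno
    return 0


def write_fasta(genome: GenomeSequence, path: str, width: int = 70) -> None:
    """Write a genome as FASTA with canonical line wrapping."""
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Gene models (GFF3 gene-feature subset)
# ---------------------------------------------------------------------------

def read_gene_models(path: str) -> List[GeneModel]:
    """Parse gene features from a GFF3 subset.

    Only ``gene`` feature lines are consumed; each must carry an ``ID``
    attribute.  GFF3 1-based closed coordinates are converted to internal
    0-based: TSS = start-1 on the + strand and end-1 on the - strand.
    """
    genes: List[GeneModel] = []
    seen = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns")
            contig, _src, ftype, start, end, _score, strand, _frame, attrs = parts
            if ftype != "gene":
                continue
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            gene_id = None
            for item in attrs.split(";"):
                item = item.strip()
                if item.startswith("ID="):
                    gene_id = item[3:]
            if not gene_id:
                raise FormatError(f"{path}:{lineno}: gene feature missing ID attribute")
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene ID {gene_id!r}")
            seen.add(gene_id)
            start_i, end_i = int(start), int(end)
            if strand == "+":
                genes.append(GeneModel(gene_id, contig, "+", tss=start_i - 1, end=end_i))
            else:
                genes.append(GeneModel(gene_id, contig, "-", tss=end_i - 1, end=start_i - 1))
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str) -> None:
    """Write gene models as GFF3 gene lines (inverse of read_gene_models)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            if g.strand == "+":
                start, end = g.tss + 1, g.end
            else:
                start, end = g.end + 1, g.tss + 1
            fh.write(
                f"{g.contig}\tlightchrom\tgene\t{start}\t{end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# BED6 and fragment tables
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable, path: str) -> None:
    """Write BED6; score column carries fold enrichment x100 (integer).

    ``intervals`` yields objects with attributes contig/start/end/name/
    fold_enrichment (missing attributes default sensibly).
    """
    with open(path, "w") as fh:
        for iv in intervals:
            name = getattr(iv, "name", None) or getattr(iv, "peak_id", ".")
            fold = getattr(iv, "fold_enrichment", 0.0) or 0.0
            strand = getattr(iv, "strand", ".")
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t{int(round(fold * 100))}\t{strand}\n"
            )


def read_bed(path: str) -> pd.DataFrame:
    """Read BED (3-6 columns) into a DataFrame with 0-based half-open coords."""
    names = ["contig", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: BED needs at least 3 columns")
    df = df.iloc[:, :6]
    df.columns = names[: df.shape[1]]
    return df


def write_fragments(frags: pd.DataFrame, path: str) -> None:
    """Write fragments as 3-column TSV (contig, start, end; 0-based half-open)."""
    frags[["contig", "start", "end"]].to_csv(path, sep="\t", index=False)


def read_fragments(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"contig", "start", "end"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: fragment TSV needs columns {sorted(required)}")
    if (df["end"] <= df["start"]).any():
        raise FormatError(f"{path}: fragment with end <= start")
    return df


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

def read_counts(path: str) -> pd.DataFrame:
    """Read a counts TSV: gene_id column then one integer column per sample.

    Sample column labels follow the ``genotype_timepoint`` convention,
    e.g. ``wt_DD``, ``wt_30``, ``dsub1_120``.
    """
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise FormatError(f"{path}: first column must be 'gene_id'")
    df = df.set_index("gene_id")
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate gene ids")
    if (df.values < 0).any():
        raise FormatError(f"{path}: negative counts")
    return df.astype(np.int64)


def write_counts(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id")


def split_sample_label(label: str) -> tuple:
    """Split ``genotype_timepoint`` into its two parts (last underscore wins)."""
    genotype, _, timepoint = label.rpartition("_")
    if not genotype:
        raise FormatError(f"sample label {label!r} is not genotype_timepoint")
    return genotype, timepoint


# ---------------------------------------------------------------------------
# Wiggle (fixedStep)
# ---------------------------------------------------------------------------

def write_wiggle(track: CoverageTrack, path: str, step: int = 1) -> None:
    """Write a coverage track as fixedStep wiggle (1-based starts, UCSC).

    With ``step`` > 1 the value written for each step is the track value at
    the first base of the step.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if not track.data or all(len(v) == 0 for v in track.data.values()):
        raise ValueError("cannot write an empty track")
    with open(path, "w") as fh:
        for contig, values in track.data.items():
            fh.write(f"fixedStep chrom={contig} start=1 step={step} span={step}\n")
            for v in values[::step]:
                fh.write(f"{_fmt_value(float(v))}\n")


def _fmt_value(v: float) -> str:
    if v == int(v) and abs(v) < 1e15:
        return str(int(v))
    return repr(v)


def read_wiggle(path: str) -> CoverageTrack:
    """Read a fixedStep wiggle back into a per-base CoverageTrack.

    Each step's value is expanded over its span, so a write/read round
    trip reproduces the original track at step resolution.
    """
    data: Dict[str, list] = {}
    contig = None
    step = span = 1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("track"):
                continue
            if line.startswith("fixedStep"):
                info = dict(kv.split("=") for kv in line.split()[1:])
                contig = info["chrom"]
                step = int(info.get("step", 1))
                span = int(info.get("span", step))
                if int(info.get("start", 1)) != 1:
                    raise FormatError(f"{path}:{lineno}: only start=1 blocks supported")
                data.setdefault(contig, [])
            elif contig is None:
                raise FormatError(f"{path}:{lineno}: value before fixedStep header")
            else:
                data[contig].extend([float(line)] * span)
    if not data:
        raise FormatError(f"{path}: no wiggle data")
    return CoverageTrack({c: np.array(v) for c, v in data.items()})
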