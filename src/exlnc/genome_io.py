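"""Genomic annotation, peak and table I/O.

All internal coordinates are 0-based half-open. GTF (1-based closed) is
converted on read and on write; BED/narrowPeak coordinates pass through
unchanged. This module also builds the ATAC master peak list (trim each
peak to a fixed width around its summit, merge overlaps) and applies the
raw-count peak filter used before differential accessibility analysis.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: chromosomes kept by default: autosomes plus X and Y, with or without
#: a "chr" prefix (species-agnostic allow-list, overridable).
STANDARD_CHROM_RE = re.compile(r"^(chr)?([0-9]+|X|Y)$")

BIOTYPE_LNCRNA = "lncRNA"
BIOTYPE_CODING = "protein_coding"
BIOTYPE_OTHER = "other"


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene locus with biotype, strand-aware TSS and exon structure.

    The TSS is the 5'-most base of the locus: ``interval.start`` on the
    plus (or unknown) strand, ``interval.end - 1`` on the minus strand.
    """

    gene_id: str
    biotype: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.biotype not in {BIOTYPE_LNCRNA, BIOTYPE_CODING, BIOTYPE_OTHER}:
            raise ValueError(f"invalid biotype {self.biotype!r}")
        prev_end = None
        for ex in self.exons:
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"exon {ex} outside gene {self.gene_id}")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"exons overlap or unsorted in {self.gene_id}")
            prev_end = ex.end

    @property
    def tss(self) -> int:
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class Peak:
    """An accessibility interval with a summit position."""

    peak_id: str
    interval: GenomicInterval
    summit: int

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"[{self.interval.start}, {self.interval.end}) for {self.peak_id}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class PeakCounts:
    """Raw read counts for one peak across samples (fixed sample order)."""

    peak_id: str
    counts: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError(f"negative count for {self.peak_id}")


def _map_biotype(raw: str) -> str:
    if raw in ("lncRNA", "lincRNA"):
        return BIOTYPE_LNCRNA
    if raw == "protein_coding":
        return BIOTYPE_CODING
    return BIOTYPE_OTHER


def _prescan_gtf(path: str) -> None:
    """Validate GTF field counts and gene_id uniqueness up-front.

    gffutils' default merge strategy silently renames duplicate ids, so
    duplicates are caught here, along with line numbers for malformed rows
    (gffutils reports neither).
    """
    seen: set[str] = set()
    gid_re = re.compile(r'gene_id "([^"]+)"')
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(
                    f"{path}: malformed GTF line {lineno}: expected 9 "
                    f"tab-separated fields, got {len(fields)}"
                )
            if fields[2] == "gene":
                m = gid_re.search(fields[8])
                if m is None:
                    raise ValueError(
                        f"{path}: GTF line {lineno}: gene record lacks gene_id"
                    )
                if m.group(1) in seen:
                    raise ValueError(
                        f"{path}: duplicate gene_id {m.group(1)!r} "
                        f"at line {lineno}"
                    )
                seen.add(m.group(1))


def read_gene_models(path: str) -> list[GeneModel]:
    """Read gene records from an Ensembl-dialect GTF into GeneModels.

    1-based closed GTF coordinates become 0-based half-open. Biotypes other
    than lncRNA/protein_coding are mapped to "other". Exon records, when
    present, are attached to their gene sorted by start.
    """
    _prescan_gtf(path)
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    exons_by_gene: dict[str, list[GenomicInterval]] = {}
    for ex in db.features_of_type("exon"):
        gid = ex.attributes.get("gene_id", [None])[0]
        if gid is None:
            continue
        exons_by_gene.setdefault(gid, []).append(
            GenomicInterval(ex.seqid, ex.start - 1, ex.end, ex.strand or ".")
        )
    models = []
    for g in db.features_of_type("gene"):
        gid = g.attributes["gene_id"][0]
        biotype = _map_biotype(g.attributes.get("gene_biotype", ["other"])[0])
        interval = GenomicInterval(g.seqid, g.start - 1, g.end, g.strand or ".")
        exons = tuple(sorted(exons_by_gene.get(gid, []), key=lambda e: e.start))
        models.append(GeneModel(gid, biotype, interval, exons))
    return models


def write_gene_models(models: list[GeneModel], path: str) -> None:
    """Write GeneModels as a minimal Ensembl-dialect GTF (genes + exons)."""
    with open(path, "w") as fh:
        for g in models:
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            iv = g.interval
            fh.write(
                f"{iv.chrom}\texlnc\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )
            for ex in g.exons:
                fh.write(
                    f"{ex.chrom}\texlnc\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{ex.strand}\t.\t{attrs}\n"
                )


def read_peaks(path: str) -> list[Peak]:
    """Read peaks from BED3+/narrowPeak.

    narrowPeak (10 columns) supplies the summit as an offset from start;
    a negative offset, or plain BED, falls back to the interval midpoint.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED requires >= 3 columns")
    peaks = []
    for i, row in enumerate(df.itertuples(index=False)):
        chrom, start, end = str(row[0]), int(row[1]), int(row[2])
        if start >= end:
            raise ValueError(
                f"{path}: row {i + 1}: start {start} >= end {end}"
            )
        peak_id = str(row[3]) if df.shape[1] >= 4 and str(row[3]) != "." else f"peak_{i}"
        if df.shape[1] >= 10 and int(row[9]) >= 0:
            summit = start + int(row[9])
            if not (start <= summit < end):
                raise ValueError(
                    f"{path}: row {i + 1}: summit {summit} outside "
                    f"[{start}, {end})"
                )
        else:
            summit = (start + end) // 2
        peaks.append(Peak(peak_id, GenomicInterval(chrom, start, end), summit))
    return peaks


def write_peaks(peaks: list[Peak], path: str) -> None:
    """Write peaks as ENCODE narrowPeak (summit as offset in column 10)."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.peak_id}\t0\t.\t"
                f"0\t-1\t-1\t{p.summit - iv.start}\n"
            )


def trim_and_merge_peaks(
    *peak_sets: list[Peak], half_width: int = 100
) -> list[Peak]:
    """Build the master peak list: trim to ``2*half_width`` bp around each
    summit, then merge overlapping or book-ended intervals per chromosome.

    The merged peak's summit is the midpoint of the merged interval. Trimmed
    intervals that would extend below position 0 are clamped (with a logged
    warning), so those are the only outputs shorter than ``2*half_width``
    before merging.
    """
    trimmed: dict[str, list[tuple[int, int]]] = {}
    n_clamped = 0
    for peaks in peak_sets:
        for p in peaks:
            lo = p.summit - half_width
            if lo < 0:
                n_clamped += 1
                lo = 0
            trimmed.setdefault(p.chrom, []).append((lo, p.summit + half_width))
    if n_clamped:
        logger.warning("clamped %d trimmed peak(s) at position 0", n_clamped)
    out: list[Peak] = []
    for chrom in sorted(trimmed):
        ivs = sorted(trimmed[chrom])
        merged: list[list[int]] = []
        for lo, hi in ivs:
            if merged and lo <= merged[-1][1]:  # book-ended intervals merge
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        for lo, hi in merged:
            pid = f"{chrom}:{lo}-{hi}"
            out.append(
                Peak(pid, GenomicInterval(chrom, lo, hi), (lo + hi) // 2)
            )
    return out


def filter_peaks_by_counts(
    peaks: list[Peak],
    counts: list[PeakCounts] | dict[str, "np.ndarray"],
    min_reads: int = 10,
    min_samples: int = 4,
    allowed_chroms: list[str] | None = None,
) -> list[Peak]:
    """Keep peaks with >= ``min_reads`` reads in >= ``min_samples`` samples,
    restricted to standard chromosomes (autosomes, X, Y by default).

    ``allowed_chroms`` overrides the default allow-list.
    """
    if not isinstance(counts, dict):
        counts = {pc.peak_id: np.asarray(pc.counts) for pc in counts}
    kept = []
    for p in peaks:
        if allowed_chroms is not None:
            if p.chrom not in allowed_chroms:
                continue
        elif not STANDARD_CHROM_RE.match(p.chrom):
            continue
        if p.peak_id not in counts:
            raise ValueError(f"no counts row for peak {p.peak_id!r}")
        row = np.asarray(counts[p.peak_id])
        if int((row >= min_reads).sum()) >= min_samples:
            kept.append(p)
    return kept


def read_peak_counts(path: str) -> dict[str, np.ndarray]:
    """Read a peak-by-sample raw count TSV (first column: peak_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative counts")
    return {pid: df.loc[pid].to_numpy() for pid in df.index}


def write_peak_counts(counts: dict[str, np.ndarray], path: str,
                      sample_names: list[str] | None = None) -> None:
    first = next(iter(counts.values()))
    cols = sample_names or [f"s{i + 1}" for i in range(len(first))]
    df = pd.DataFrame.from_dict(
        {k: np.asarray(v) for k, v in counts.items()}, orient="index",
        columns=cols,
    )
    df.index.name = "peak_id"
    df.to_csv(path, sep="\t")
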