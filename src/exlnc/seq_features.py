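"""Sequence-level characterization of lncRNAs vs protein-coding transcripts.

Covers exonic GC content, small-ORF (smORF) discovery in the three sense
frames (>= 30 nt from ATG through the stop codon, i.e. >= 9-aa peptides),
microprotein search-database construction, and the nonparametric group
comparisons used for length/GC (Mann-Whitney U) and for precomputed
minimum-free-energy distributions (Kolmogorov-Smirnov).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from scipy import stats

STOP_CODONS = {"TAA", "TAG", "TGA"}

#: exact Mann-Whitney enumeration is used up to this product of group sizes
EXACT_U_LIMIT = 400


@dataclass(frozen=True)
class ORFRecord:
    seq_id: str
    frame: int
    start_nt: int
    end_nt: int  # exclusive, past the stop codon
    peptide: str

    @property
    def nt_len(self) -> int:
        return self.end_nt - self.start_nt


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    n_a: int
    n_b: int


def gc_content(sequence: str) -> float:
    """Percent G+C over unambiguous bases; U counts as T, N etc. excluded."""
    s = sequence.upper().replace("U", "T")
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("no unambiguous bases in sequence")
    return 100.0 * gc / (gc + at)


def find_smorfs(sequence: str, min_len: int = 30, seq_id: str = "",
                frames: int = 3) -> list[ORFRecord]:
    """Scan for small ORFs: ATG through the first in-frame stop, inclusive.

    Every ATG opens a candidate (ATGs nested inside a reported ORF are
    scanned too); ORFs without an in-frame stop are not reported. ``frames``
    is 3 (sense strand, default) or 6 (both strands; minus-strand
    coordinates refer to the reverse complement).
    """
    if frames not in (3, 6):
        raise ValueError("frames must be 3 or 6")
    seq = sequence.upper().replace("U", "T")
    out = _scan_sense(seq, min_len, seq_id, frame_offset=0)
    if frames == 6:
        rc = str(Seq(seq).reverse_complement())
        out += _scan_sense(rc, min_len, seq_id, frame_offset=3)
    return out


def _scan_sense(seq: str, min_len: int, seq_id: str,
                frame_offset: int) -> list[ORFRecord]:
    n = len(seq)
    out = []
    for frame in range(3):
        # first in-frame stop at or after each codon index, per frame
        codon_starts = range(frame, n - 2, 3)
        stops = [i for i in codon_starts if seq[i:i + 3] in STOP_CODONS]
        stop_arr = np.array(stops, dtype=int)
        for i in codon_starts:
            if seq[i:i + 3] != "ATG":
                continue
            j = np.searchsorted(stop_arr, i)
            if j == len(stop_arr):
                continue  # no in-frame stop downstream
            end = int(stop_arr[j]) + 3
            if end - i < min_len:
                continue
            peptide = str(Seq(seq[i:end - 3]).translate())
            out.append(ORFRecord(seq_id, frame + frame_offset, i, end, peptide))
    return out


def build_microprotein_db(fasta_in: str, fasta_out: str, min_len: int = 30,
                          frames: int = 3) -> int:
    """Translate all smORFs into a peptide FASTA search database.

    Peptides are deduplicated per source sequence by (seq_id, peptide);
    headers encode ``seq_id|frame|start-end``. Returns the record count.
    """
    n = 0
    with open(fasta_out, "w") as fh:
        for rec in SeqIO.parse(fasta_in, "fasta"):
            seen: set[str] = set()
            for orf in find_smorfs(str(rec.seq), min_len=min_len,
                                   seq_id=rec.id, frames=frames):
                if orf.peptide in seen:
                    continue
                seen.add(orf.peptide)
                fh.write(f">{rec.id}|f{orf.frame}|{orf.start_nt}-{orf.end_nt}\n"
                         f"{orf.peptide}\n")
                n += 1
    return n


def compare_groups(values_a, values_b, test: str = "rank") -> TestResult:
    """Two-sided nonparametric group comparison.

    ``test='rank'``: Mann-Whitney U, exact enumeration for small tie-free
    samples (n*m <= 400), otherwise the normal approximation with tie
    correction. ``test='distribution'``: two-sample Kolmogorov-Smirnov.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if test == "rank":
        has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        method = "exact" if (a.size * b.size <= EXACT_U_LIMIT
                             and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        name = "mann-whitney-u"
    elif test == "distribution":
        res = stats.ks_2samp(a, b, alternative="two-sided")
        name = "kolmogorov-smirnov"
    else:
        raise ValueError(f"unknown test {test!r}")
    return TestResult(float(res.statistic), float(res.pvalue), name,
                      a.size, b.size)
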