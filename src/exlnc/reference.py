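"""Straightforward reference implementations used for validation.

Each function here is a deliberately naive, definitional version of an
operation implemented elsewhere in the package (closed forms, double
loops, all-pairs scans). They are kept free of the optimized code paths
they check and are exercised by the test suite and the validation
experiments.
"""

from __future__ import annotations

import math

import numpy as np

from .genome_io import STANDARD_CHROM_RE


def chi2_df4_sf(x: float) -> float:
    """Upper tail of chi-square with 4 df, closed form exp(-x/2)(1 + x/2)."""
    return math.exp(-x / 2.0) * (1.0 + x / 2.0)


def bh_stepup(p_values) -> np.ndarray:
    """Literal BH step-up: q_(i) = min_{j>=i} p_(j)*m/j, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i in range(m):
        best = min(p[order[j]] * m / (j + 1) for j in range(rank_i, m))
        q[order[rank_i]] = min(best, 1.0)
    return q


def pearson_definitional(x, y) -> float:
    """Pearson r straight from the definition (loops, no vectorization)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((x[i] - mx) * (y[i] - my) for i in range(n))
    dx = math.sqrt(sum((x[i] - mx) ** 2 for i in range(n)))
    dy = math.sqrt(sum((y[i] - my) ** 2 for i in range(n)))
    return num / (dx * dy)


def local_pairs_bruteforce(lnc_models, peaks, window) -> set:
    """All-pairs O(n*m) scan; returns {(lnc_id, peak_id, distance)}."""
    out = set()
    for lnc in lnc_models:
        for p in peaks:
            if lnc.chrom != p.chrom:
                continue
            d = abs(lnc.interval.midpoint - p.interval.midpoint)
            if d <= window:
                out.add((lnc.gene_id, p.peak_id, d))
    return out


def count_filter_bruteforce(peaks, counts, min_reads=10, min_samples=4,
                            allowed_chroms=None) -> list:
    """Row-by-row scan of the count matrix."""
    kept = []
    for p in peaks:
        if allowed_chroms is not None:
            if p.chrom not in allowed_chroms:
                continue
        elif not STANDARD_CHROM_RE.match(p.chrom):
            continue
        n_ok = sum(1 for c in counts[p.peak_id] if c >= min_reads)
        if n_ok >= min_samples:
            kept.append(p)
    return kept


_CODON_TABLE = None


def _codon_table() -> dict:
    global _CODON_TABLE
    if _CODON_TABLE is None:
        bases = "TCAG"
        aas = ("FFLLSSSSYY**CC*W" "LLLLPPPPHHQQRRRR"
               "IIIMTTTTNNKKSSRR" "VVVVAAAADDEEGGGG")
        _CODON_TABLE = {
            a + b + c: aas[i * 16 + j * 4 + k]
            for i, a in enumerate(bases) for j, b in enumerate(bases)
            for k, c in enumerate(bases)
        }
    return _CODON_TABLE


def smorfs_bruteforce(sequence: str, min_len: int = 30) -> set:
    """Pattern scan: for every ATG, walk codon-by-codon to the first stop.

    Returns {(frame, start, end, peptide)} for sense-strand ORFs with
    nt length >= min_len (ATG through stop inclusive).
    """
    seq = sequence.upper().replace("U", "T")
    table = _codon_table()
    out = set()
    for i in range(len(seq) - 2):
        if seq[i:i + 3] != "ATG":
            continue
        j = i
        while j + 3 <= len(seq):
            codon = seq[j:j + 3]
            if codon in ("TAA", "TAG", "TGA"):
                end = j + 3
                if end - i >= min_len:
                    pep = "".join(table.get(seq[k:k + 3], "X")
                                  for k in range(i, j, 3))
                    out.add((i % 3, i, end, pep))
                break
            j += 3
    return out


def triads_bruteforce(candidates) -> dict:
    """Per-gene winner among triad candidates.

    ``candidates``: iterable of (gene_id, activity_score, tss_distance,
    lnc_id, peak_id). Max score wins; ties by smaller distance, then
    lexicographic lnc_id. Returns gene_id -> winning tuple.
    """
    best = {}
    for cand in candidates:
        gene = cand[0]
        key = (-cand[1], cand[2], cand[3])
        if gene not in best or key < (-best[gene][1], best[gene][2],
                                      best[gene][3]):
            best[gene] = cand
    return best
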