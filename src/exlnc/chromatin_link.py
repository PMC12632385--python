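"""lncRNA-chromatin accessibility integration.

The central procedure: pair each lncRNA locus with ATAC peaks whose
midpoints lie within +/-500 kb on the same chromosome, correlate their
training-response trajectories (log2FC over weeks 1/2/4/8, males then
females), and score each pair against the nearest protein-coding TSS with

    activity_score = r / (tss_distance + 1)

where ``tss_distance`` is the absolute distance from the peak summit to the
TSS. High positive correlation close to a promoter scores highest,
prioritizing putative cis-regulatory lncRNA-peak-gene triads. Triads keep
pairs with r >= 0.5 and retain, per coding gene, only the highest-scoring
triad.

Two distances are deliberately distinct: pairing uses locus/peak interval
midpoints; scoring uses the peak summit to the gene TSS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import BIOTYPE_CODING, GeneModel, Peak

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 500_000
DEFAULT_R_MIN = 0.5

#: fixed trajectory grid: male weeks 1,2,4,8 then female weeks 1,2,4,8
TRAJECTORY_GRID = [f"{s}_w{w}" for s in ("M", "F") for w in (1, 2, 4, 8)]


@dataclass
class LocalPair:
    lnc_id: str
    peak_id: str
    chrom: str
    midpoint_distance: int
    r: float | None = None


@dataclass(frozen=True)
class Triad:
    lnc_id: str
    peak_id: str
    gene_id: str
    tss_distance: int
    r: float
    activity_score: float
    gene_direction: str  # up | down | ns


def find_local_pairs(lnc_models: list[GeneModel], peaks: list[Peak],
                     window: int = DEFAULT_WINDOW) -> list[LocalPair]:
    """All same-chromosome lncRNA-peak pairs with midpoint distance <= window.

    The boundary is inclusive (distance exactly ``window`` pairs). Midpoints
    are floor((start+end)/2). Equivalent to the all-pairs scan, implemented
    with a sorted sweep per chromosome.
    """
    peaks_by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        peaks_by_chrom.setdefault(p.chrom, []).append(p)
    mids: dict[str, np.ndarray] = {}
    for chrom, ps in peaks_by_chrom.items():
        ps.sort(key=lambda p: (p.interval.midpoint, p.peak_id))
        mids[chrom] = np.array([p.interval.midpoint for p in ps])
    pairs = []
    for lnc in lnc_models:
        chrom = lnc.chrom
        if chrom not in mids:
            continue
        m = lnc.interval.midpoint
        lo = np.searchsorted(mids[chrom], m - window, side="left")
        hi = np.searchsorted(mids[chrom], m + window, side="right")
        for p in peaks_by_chrom[chrom][lo:hi]:
            pairs.append(
                LocalPair(lnc.gene_id, p.peak_id, chrom,
                          abs(m - p.interval.midpoint))
            )
    return pairs


def correlate_pair(lnc_traj, peak_traj) -> float | None:
    """Sample Pearson correlation of two trajectory vectors.

    Returns None (and logs a warning) when either vector has zero variance;
    such pairs are excluded downstream, never silently scored.
    """
    x = np.asarray(lnc_traj, dtype=float)
    y = np.asarray(peak_traj, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("trajectories must have equal length >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0 or sy == 0:
        logger.warning("zero-variance trajectory; pair excluded")
        return None
    return float((xc * yc).sum() / (sx * sy))


def correlate_pairs(pairs: list[LocalPair], lnc_traj: pd.DataFrame,
                    peak_traj: pd.DataFrame) -> list[LocalPair]:
    """Fill ``r`` on each pair from trajectory tables (rows: feature_id)."""
    for pair in pairs:
        pair.r = correlate_pair(lnc_traj.loc[pair.lnc_id].to_numpy(),
                                peak_traj.loc[pair.peak_id].to_numpy())
    return pairs


def nearest_coding_tss(peak: Peak, genes: list[GeneModel]
                       ) -> tuple[str, int] | None:
    """Closest protein-coding TSS to the peak summit on its chromosome.

    Ties go to the lexicographically smallest gene_id. Returns None (with a
    warning) when the chromosome carries no coding gene.
    """
    best: tuple[int, str] | None = None
    for g in genes:
        if g.biotype != BIOTYPE_CODING or g.chrom != peak.chrom:
            continue
        d = abs(peak.summit - g.tss)
        if best is None or (d, g.gene_id) < best:
            best = (d, g.gene_id)
    if best is None:
        logger.warning("no protein-coding gene on %s for peak %s",
                       peak.chrom, peak.peak_id)
        return None
    return best[1], best[0]


def activity_score(r: float, tss_distance: int) -> float:
    """Distance-weighted correlation: r / (tss_distance + 1)."""
    if tss_distance < 0:
        raise ValueError("tss_distance must be >= 0")
    return r / (tss_distance + 1)


def build_triads(pairs: list[LocalPair], genes: list[GeneModel],
                 peaks: list[Peak], de_genes_up: set, de_genes_down: set,
                 r_min: float = DEFAULT_R_MIN) -> list[Triad]:
    """Prioritized lncRNA-peak-gene triads.

    Keeps pairs with r >= ``r_min`` (pairs with missing r are dropped),
    attaches the nearest coding TSS and activity score, retains one triad
    per gene (max activity score; ties: smaller tss_distance, then
    lexicographic lnc_id) and labels the gene's exercise response direction
    from the up/down differential gene sets. Output sorted by descending
    activity score.
    """
    if de_genes_up & de_genes_down:
        raise ValueError("up/down DE gene sets must be disjoint")
    peak_by_id = {p.peak_id: p for p in peaks}
    candidates: list[Triad] = []
    for pair in pairs:
        if pair.r is None or pair.r < r_min:
            continue
        hit = nearest_coding_tss(peak_by_id[pair.peak_id], genes)
        if hit is None:
            continue
        gene_id, d = hit
        direction = ("up" if gene_id in de_genes_up
                     else "down" if gene_id in de_genes_down else "ns")
        candidates.append(
            Triad(pair.lnc_id, pair.peak_id, gene_id, d, pair.r,
                  activity_score(pair.r, d), direction)
        )
    best: dict[str, Triad] = {}
    for t in candidates:
        cur = best.get(t.gene_id)
        if cur is None or _triad_rank(t) < _triad_rank(cur):
            best[t.gene_id] = t
    out = list(best.values())
    out.sort(key=lambda t: (-t.activity_score, t.tss_distance, t.lnc_id))
    return out


def _triad_rank(t: Triad) -> tuple:
    # max score wins; ties by smaller distance, then lexicographic lnc_id
    return (-t.activity_score, t.tss_distance, t.lnc_id)


def pairs_to_frame(pairs: list[LocalPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.lnc_id, p.peak_id, p.chrom, p.midpoint_distance, p.r)
         for p in pairs],
        columns=["lnc_id", "peak_id", "chrom", "midpoint_distance", "r"],
    )


def triads_to_frame(triads: list[Triad]) -> pd.DataFrame:
    return pd.DataFrame(
        [(t.lnc_id, t.peak_id, t.gene_id, t.tss_distance, t.r,
          t.activity_score, t.gene_direction) for t in triads],
        columns=["lnc_id", "peak_id", "gene_id", "tss_distance", "r",
                 "activity_score", "gene_direction"],
    )
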