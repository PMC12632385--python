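"""Seeded synthetic multi-tissue training-response data with known truth.

Emulates the study design the pipeline targets: two sexes, four training
timepoints (weeks 1, 2, 4, 8), several tissues, each contrast expressed as
a log2 fold-change versus sex-matched sedentary controls. The generator
plants three kinds of ground truth:

* differential features — a fraction of lncRNA and coding genes carry a
  true |log2FC| of ``effect_size`` in a random non-empty subset of the
  eight (sex, week) cells; p-values come from a two-sided z-model on the
  observed effect. With ``guarantee_separation`` (default) planted cells
  are rejection-sampled to p < 1e-4 with |log2FC| >= 1 and null cells to
  p > 0.1, so threshold filters can be validated against truth exactly.
* lncRNA-peak couplings — a fraction of lncRNAs get a partner ATAC peak
  placed within 50 kb whose 8-point trajectory shares a latent signal with
  the lncRNA's; latent amplitude is calibrated so the expected Pearson
  correlation equals ``coupling_r`` given ``noise_sd``.
* training-significant peaks — coupled peaks (and a small background
  fraction) receive small per-sex p-values; the rest are uniform nulls.

Everything is deterministic under ``seed`` (one SeedSequence, spawned
child streams per stage) and every emitted file parses back through
:mod:`exlnc.genome_io`.
"""

from __future__ import annotations

import itertools
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from . import genome_io
from .chromatin_link import TRAJECTORY_GRID
from .genome_io import (BIOTYPE_CODING, BIOTYPE_LNCRNA, GeneModel,
                        GenomicInterval, Peak)

WEEKS = (1, 2, 4, 8)
SEXES = ("M", "F")
CELLS = [(s, w) for s in SEXES for w in WEEKS]

COUPLING_MAX_DIST = 50_000  # partner peak placed within this of the lncRNA
PEAK_HALF_WIDTH = 150


@dataclass
class SynthConfig:
    n_lnc: int = 200
    n_coding: int = 400
    n_peaks: int = 1000
    n_tissues: int = 2
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 50_000_000, "chr2": 50_000_000})
    frac_diff: float = 0.15
    effect_size: float = 2.0
    noise_sd: float = 0.1
    frac_coupled: float = 0.1
    coupling_r: float = 0.95
    seed: int = 0
    # secondary knobs
    n_samples: int = 10          # columns of the peak count matrix
    frac_low_expr: float = 0.2   # null features drawn below the FPKM gate
    frac_low_count: float = 0.05  # peaks drawn to fail the count filter
    frac_sig_bg_peaks: float = 0.05  # uncoupled peaks made training-significant
    cell_active_prob: float = 0.6
    guarantee_separation: bool = True
    coupling_max_dist: int = COUPLING_MAX_DIST

    def __post_init__(self) -> None:
        for name in ("frac_diff", "frac_coupled", "frac_low_expr",
                     "frac_low_count", "frac_sig_bg_peaks"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not -1 < self.coupling_r < 1:
            raise ValueError("coupling_r must be in (-1, 1)")

    @property
    def tissues(self) -> list[str]:
        return [f"tissue{i + 1}" for i in range(self.n_tissues)]


@dataclass
class SynthTruth:
    """Ground truth: per-tissue differential cells/features, coupled pairs,
    and per-tissue training-significant peaks."""

    diff_cells: dict      # tissue -> set of (feature_id, sex, week)
    diff_features: dict   # tissue -> set of feature_id
    coupled_pairs: set    # {(lnc_id, peak_id)}
    sig_peaks: dict       # tissue -> set of peak_id

    def to_json(self, path: str) -> None:
        obj = {
            "diff_cells": {t: sorted(map(list, v))
                           for t, v in self.diff_cells.items()},
            "diff_features": {t: sorted(v)
                              for t, v in self.diff_features.items()},
            "coupled_pairs": sorted(map(list, self.coupled_pairs)),
            "sig_peaks": {t: sorted(v) for t, v in self.sig_peaks.items()},
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)


@dataclass
class SynthDataset:
    config: SynthConfig
    genes: list
    raw_peaks: list                   # per-condition peaks, as emitted to file
    peaks: list                       # master list (trimmed + merged)
    peak_counts: dict                 # master peak_id -> np.ndarray
    diff_tables: dict                 # tissue -> DataFrame (DIFF_COLUMNS)
    lnc_trajectories: dict            # tissue -> DataFrame (rows lnc)
    peak_trajectories: dict           # tissue -> DataFrame (rows peaks)
    peak_pvalues: dict                # tissue -> DataFrame (p_male, p_female)
    truth: SynthTruth

    @property
    def lnc_models(self) -> list:
        return [g for g in self.genes if g.biotype == BIOTYPE_LNCRNA]

    @property
    def coding_models(self) -> list:
        return [g for g in self.genes if g.biotype == BIOTYPE_CODING]


def generate_annotation(cfg: SynthConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[list[GeneModel], list[Peak], set]:
    """Place genes (with minimum spacing) and peaks; returns coupled pairs.

    Each coupled lncRNA gets a partner peak whose midpoint lies within
    ``cfg.coupling_max_dist`` of the lncRNA midpoint; remaining peaks are
    placed uniformly. Raises when the gene density cannot satisfy the
    spacing constraint.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    chroms = sorted(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    slot = 25_000  # fits the largest gene plus spacing margin
    n_slots = {c: int(cfg.chrom_lengths[c] // slot) for c in chroms}
    n_genes = cfg.n_lnc + cfg.n_coding
    if n_genes > sum(n_slots.values()):
        raise ValueError(
            f"gene density too high: {n_genes} genes but only "
            f"{sum(n_slots.values())} placement slots"
        )
    # assign genes to chromosomes proportionally to length, then to slots
    assign = rng.choice(len(chroms), size=n_genes, p=lengths / lengths.sum())
    for i, c in enumerate(chroms):
        while (assign == i).sum() > n_slots[c]:
            # respill overflow onto the least-loaded chromosome
            j = np.argmin([(assign == k).sum() / n_slots[chroms[k]]
                           for k in range(len(chroms))])
            assign[np.flatnonzero(assign == i)[0]] = j
    genes: list[GeneModel] = []
    order = rng.permutation(n_genes)  # interleave biotypes across slots
    kinds = np.array([BIOTYPE_LNCRNA] * cfg.n_lnc
                     + [BIOTYPE_CODING] * cfg.n_coding)[order]
    counters = {BIOTYPE_LNCRNA: 0, BIOTYPE_CODING: 0}
    prefixes = {BIOTYPE_LNCRNA: "lnc", BIOTYPE_CODING: "pcg"}
    for i, c in enumerate(chroms):
        idx = np.flatnonzero(assign == i)
        slots = rng.choice(n_slots[c], size=len(idx), replace=False)
        for k, s in zip(idx, np.sort(slots)):
            biotype = kinds[k]
            counters[biotype] += 1
            gid = f"{prefixes[biotype]}_{counters[biotype]:04d}"
            length = int(rng.integers(500, 5000) if biotype == BIOTYPE_LNCRNA
                         else rng.integers(2000, 20000))
            start = int(s) * slot + int(rng.integers(0, slot - length))
            strand = "+" if rng.random() < 0.5 else "-"
            iv = GenomicInterval(c, start, start + length, strand)
            genes.append(GeneModel(gid, biotype, iv, _make_exons(iv, rng)))
    genes.sort(key=lambda g: (g.chrom, g.interval.start, g.gene_id))

    lncs = [g for g in genes if g.biotype == BIOTYPE_LNCRNA]
    n_coupled = int(round(cfg.frac_coupled * len(lncs)))
    coupled_lncs = [lncs[i] for i in
                    rng.choice(len(lncs), size=n_coupled, replace=False)]
    peaks: list[Peak] = []
    coupled_pairs: set[tuple[str, str]] = set()
    pid = 0
    for lnc in coupled_lncs:
        pid += 1
        L = cfg.chrom_lengths[lnc.chrom]
        offset = int(rng.integers(0, cfg.coupling_max_dist + 1))
        sign = 1 if rng.random() < 0.5 else -1
        summit = int(np.clip(lnc.interval.midpoint + sign * offset,
                             PEAK_HALF_WIDTH, L - PEAK_HALF_WIDTH - 1))
        p = Peak(f"peak_{pid:05d}",
                 GenomicInterval(lnc.chrom, summit - PEAK_HALF_WIDTH,
                                 summit + PEAK_HALF_WIDTH), summit)
        peaks.append(p)
        coupled_pairs.add((lnc.gene_id, p.peak_id))
    while pid < cfg.n_peaks:
        pid += 1
        c = chroms[int(rng.choice(len(chroms), p=lengths / lengths.sum()))]
        summit = int(rng.integers(PEAK_HALF_WIDTH,
                                  cfg.chrom_lengths[c] - PEAK_HALF_WIDTH))
        peaks.append(Peak(f"peak_{pid:05d}",
                          GenomicInterval(c, summit - PEAK_HALF_WIDTH,
                                          summit + PEAK_HALF_WIDTH), summit))
    return genes, peaks, coupled_pairs


def _make_exons(iv: GenomicInterval, rng: np.random.Generator
                ) -> tuple[GenomicInterval, ...]:
    n_ex = int(rng.integers(1, 4))
    if n_ex == 1 or len(iv) < 8 * n_ex:
        return (GenomicInterval(iv.chrom, iv.start, iv.end, iv.strand),)
    cuts = np.sort(rng.choice(np.arange(1, len(iv) - 1), size=2 * (n_ex - 1),
                              replace=False))
    bounds = [iv.start] + (iv.start + cuts).tolist() + [iv.end]
    return tuple(
        GenomicInterval(iv.chrom, bounds[2 * i], bounds[2 * i + 1], iv.strand)
        for i in range(n_ex)
    )


def _sample_cell(rng, true_lfc: float, noise_sd: float, planted: bool,
                 guarantee: bool) -> tuple[float, float]:
    """Observed (log2fc, p) for one contrast cell under the z-model."""
    sd = noise_sd if noise_sd > 0 else 1e-12
    for _ in range(1000):
        obs = true_lfc + rng.normal(0, noise_sd)
        # two-sided normal tail: 2*Phi(-|z|) = erfc(|z|/sqrt(2))
        p = float(np.clip(special.erfc(abs(obs) / sd / np.sqrt(2)),
                          1e-300, 1.0))
        if not guarantee:
            return obs, p
        if planted and p < 1e-4 and abs(obs) >= 1.0:
            return obs, p
        if not planted and p > 0.1:
            return obs, p
    raise RuntimeError(
        "could not achieve planted/null separation; effect_size and "
        "noise_sd are inconsistent with the separation guarantee"
    )


def _latent_amplitude(cfg: SynthConfig) -> float:
    # attenuation: E[r] ~ a^2/(a^2 + noise_sd^2) = |coupling_r|
    if cfg.noise_sd == 0:
        return 1.0
    r = abs(cfg.coupling_r)
    if r == 0:
        return 0.0
    return cfg.noise_sd * np.sqrt(r / (1 - r))


def generate_diff_tables(cfg: SynthConfig, genes: list[GeneModel],
                         peaks: list[Peak], coupled_pairs: set,
                         seed_seq: np.random.SeedSequence | None = None
                         ) -> tuple[dict, dict, dict, dict, SynthTruth]:
    """Per-tissue differential tables, trajectories and peak p-values.

    Coupled lncRNAs are always part of the planted differential set (their
    training response is the reason a partner peak exists); additional
    features are planted to reach ``frac_diff`` per biotype.
    """
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(seed_seq.spawn(1)[0])
    lnc_ids = [g.gene_id for g in genes if g.biotype == BIOTYPE_LNCRNA]
    pcg_ids = [g.gene_id for g in genes if g.biotype == BIOTYPE_CODING]
    peak_ids = [p.peak_id for p in peaks]
    coupled_lncs = {ln for ln, _ in coupled_pairs}
    coupled_peaks = {pk for _, pk in coupled_pairs}
    peak_of_lnc = dict(coupled_pairs)
    amp = _latent_amplitude(cfg)

    diff_tables, lnc_trajs, peak_trajs, peak_pvals = {}, {}, {}, {}
    truth_cells: dict[str, set] = {}
    truth_feats: dict[str, set] = {}
    truth_sig_peaks: dict[str, set] = {}
    for tissue in cfg.tissues:
        planted = set(coupled_lncs)
        for ids in (lnc_ids, pcg_ids):
            pool = [f for f in ids if f not in planted]
            want = int(round(cfg.frac_diff * len(ids)))
            have = len([f for f in ids if f in planted])
            extra = max(0, want - have)
            if extra:
                planted |= set(rng.choice(pool, size=extra, replace=False))
        rows, cells = [], set()
        for fid in lnc_ids + pcg_ids:
            is_planted = fid in planted
            if is_planted:
                active = rng.random(8) < cfg.cell_active_prob
                if not active.any():
                    active[int(rng.integers(0, 8))] = True
                sign = 1.0 if rng.random() < 0.5 else -1.0
                fpkm = 1.0 + float(rng.lognormal(0.5, 1.0))
            else:
                active = np.zeros(8, dtype=bool)
                if rng.random() < cfg.frac_low_expr:
                    fpkm = float(rng.uniform(0.05, 0.9999))
                else:
                    fpkm = 1.0 + float(rng.lognormal(0.5, 1.0))
            for k, (sex, week) in enumerate(CELLS):
                cell_planted = bool(active[k])
                true_lfc = sign * cfg.effect_size if cell_planted else 0.0
                obs, p = _sample_cell(rng, true_lfc, cfg.noise_sd,
                                      cell_planted, cfg.guarantee_separation)
                rows.append((fid, tissue, sex, week, obs, p, np.nan, fpkm))
                if cell_planted:
                    cells.add((fid, sex, week))
        diff_tables[tissue] = pd.DataFrame(
            rows, columns=["feature_id", "tissue", "sex", "week", "log2fc",
                           "p_value", "adj_p", "mean_fpkm"])
        truth_cells[tissue] = cells
        truth_feats[tissue] = {c[0] for c in cells}

        # trajectories: coupled pairs share a latent 8-point signal
        sign_r = 1.0 if cfg.coupling_r >= 0 else -1.0
        lnc_mat = np.empty((len(lnc_ids), 8))
        peak_mat = np.empty((len(peak_ids), 8))
        marg_sd = float(np.hypot(amp, cfg.noise_sd)) or 1e-6
        peak_rows = {pk: i for i, pk in enumerate(peak_ids)}
        peak_done = np.zeros(len(peak_ids), dtype=bool)
        for i, fid in enumerate(lnc_ids):
            if fid in coupled_lncs:
                latent = rng.normal(0, amp if amp > 0 else 1.0, 8)
                lnc_mat[i] = latent + rng.normal(0, cfg.noise_sd, 8)
                j = peak_rows[peak_of_lnc[fid]]
                peak_mat[j] = sign_r * latent + rng.normal(0, cfg.noise_sd, 8)
                peak_done[j] = True
            else:
                lnc_mat[i] = rng.normal(0, marg_sd, 8)
        for j in np.flatnonzero(~peak_done):
            peak_mat[j] = rng.normal(0, marg_sd, 8)
        lnc_trajs[tissue] = pd.DataFrame(lnc_mat, index=lnc_ids,
                                         columns=TRAJECTORY_GRID)
        peak_trajs[tissue] = pd.DataFrame(peak_mat, index=peak_ids,
                                          columns=TRAJECTORY_GRID)

        # per-sex peak p-values: coupled + background fraction significant
        sig = set(coupled_peaks)
        bg_pool = [p for p in peak_ids if p not in sig]
        n_bg = int(round(cfg.frac_sig_bg_peaks * len(bg_pool)))
        if n_bg:
            sig |= set(rng.choice(bg_pool, size=n_bg, replace=False))
        pm = np.empty(len(peak_ids))
        pf = np.empty(len(peak_ids))
        for j, pk in enumerate(peak_ids):
            if pk in sig:
                pm[j] = 10.0 ** rng.uniform(-12, -5)
                pf[j] = 10.0 ** rng.uniform(-12, -5)
            else:
                pm[j] = rng.uniform(1e-12, 1.0)
                pf[j] = rng.uniform(1e-12, 1.0)
        peak_pvals[tissue] = pd.DataFrame(
            {"peak_id": peak_ids, "p_male": pm, "p_female": pf})
        truth_sig_peaks[tissue] = sig

    truth = SynthTruth(truth_cells, truth_feats, set(coupled_pairs),
                       truth_sig_peaks)
    return diff_tables, lnc_trajs, peak_trajs, peak_pvals, truth


def generate_peak_counts(cfg: SynthConfig, peaks: list[Peak],
                         rng: np.random.Generator,
                         protected: set | None = None
                         ) -> dict[str, np.ndarray]:
    """Raw count rows per peak; a configurable fraction drawn to fail the
    '>= 10 reads in >= 4 samples' gate. Peaks in ``protected`` (coupled
    partners) always draw from the high-coverage regime."""
    protected = protected or set()
    counts = {}
    for p in peaks:
        if p.peak_id not in protected and rng.random() < cfg.frac_low_count:
            lam = rng.uniform(0.2, 3.0)
        else:
            lam = rng.uniform(20.0, 200.0)
        counts[p.peak_id] = rng.poisson(lam, cfg.n_samples)
    return counts


def master_peak_map(raw_peaks: list[Peak], master: list[Peak]
                    ) -> dict[str, str]:
    """Map each raw peak to the master-list peak containing its summit."""
    by_chrom: dict[str, list[Peak]] = {}
    for m in master:
        by_chrom.setdefault(m.chrom, []).append(m)
    starts = {c: np.array([m.interval.start for m in ps])
              for c, ps in by_chrom.items()}
    out = {}
    for rp in raw_peaks:
        ps = by_chrom[rp.chrom]
        i = int(np.searchsorted(starts[rp.chrom], rp.summit, side="right")) - 1
        assert ps[i].interval.start <= rp.summit < ps[i].interval.end
        out[rp.peak_id] = ps[i].peak_id
    return out


def generate_dataset(cfg: SynthConfig) -> SynthDataset:
    """Full deterministic dataset for one configuration.

    Peak-level statistics (counts, per-sex p-values, trajectories) are keyed
    on the master peak list — the trimmed/merged list the pipeline itself
    reconstructs from the emitted raw peak file — so file round-trips are
    exact.
    """
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(3)
    anno_rng = np.random.default_rng(children[0])
    tables_ss = children[1]
    counts_rng = np.random.default_rng(children[2])
    genes, raw_peaks, coupled_raw = generate_annotation(cfg, anno_rng)
    master = genome_io.trim_and_merge_peaks(raw_peaks)
    remap = master_peak_map(raw_peaks, master)
    coupled = {(ln, remap[pk]) for ln, pk in coupled_raw}
    diff, ltraj, ptraj, ppv, truth = generate_diff_tables(
        cfg, genes, master, coupled, tables_ss)
    counts = generate_peak_counts(cfg, master, counts_rng,
                                  protected={pk for _, pk in coupled})
    return SynthDataset(cfg, genes, raw_peaks, master, counts, diff, ltraj,
                        ptraj, ppv, truth)


def write_dataset(ds: SynthDataset, outdir: str) -> dict:
    """Emit every file format the pipeline consumes, plus truth.json."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "gtf": os.path.join(outdir, "genes.gtf"),
        "peaks": os.path.join(outdir, "peaks.narrowPeak"),
        "counts": os.path.join(outdir, "peak_counts.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    genome_io.write_gene_models(ds.genes, paths["gtf"])
    genome_io.write_peaks(ds.raw_peaks, paths["peaks"])
    genome_io.write_peak_counts(ds.peak_counts, paths["counts"])
    ds.truth.to_json(paths["truth"])
    for tissue in ds.config.tissues:
        for label, obj in (
                ("diff", ds.diff_tables[tissue]),
                ("lnc_traj", ds.lnc_trajectories[tissue]),
                ("peak_traj", ds.peak_trajectories[tissue]),
                ("peak_pvalues", ds.peak_pvalues[tissue])):
            path = os.path.join(outdir, f"{tissue}.{label}.tsv")
            paths[f"{tissue}.{label}"] = path
            index = label in ("lnc_traj", "peak_traj")
            obj.to_csv(path, sep="\t", index=index, na_rep=".",
                       float_format="%.10g",
                       index_label="feature_id" if index else None)
    return paths


def generate_sequences(n: int, length_range: tuple[int, int],
                       gc_target: float, seed: int,
                       planted_orf_len: int | None = None
                       ) -> tuple[list[tuple[str, str]], list[tuple]]:
    """Random nucleotide sequences with a target GC fraction.

    Bases are i.i.d. with P(G or C) = ``gc_target``. When
    ``planted_orf_len`` is set (a multiple of 3, >= 9), each sequence gets
    an ORF of that length (ATG..stop, no internal stop) inserted at a
    recorded offset. Returns (records, planted) where records are
    (seq_id, sequence) and planted are (seq_id, offset, nt_len).
    """
    if not 0 < gc_target < 1:
        raise ValueError("gc_target must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    bases = np.array(list("ACGT"))
    probs = np.array([(1 - gc_target) / 2, gc_target / 2, gc_target / 2,
                      (1 - gc_target) / 2])
    non_stop = [c for c in ("".join(t) for t in
                            itertools.product("ACGT", repeat=3))
                if c not in {"TAA", "TAG", "TGA"}]
    records, planted = [], []
    for i in range(n):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(bases, size=L, p=probs))
        sid = f"seq_{i + 1:04d}"
        if planted_orf_len is not None:
            if planted_orf_len % 3 or planted_orf_len < 9:
                raise ValueError("planted_orf_len must be a multiple of 3 >= 9")
            n_mid = planted_orf_len // 3 - 2
            orf = ("ATG"
                   + "".join(non_stop[int(k)] for k in
                             rng.integers(0, len(non_stop), n_mid))
                   + "TAA")
            if L <= len(orf):
                seq = orf
                offset = 0
            else:
                offset = int(rng.integers(0, L - len(orf) + 1))
                seq = seq[:offset] + orf + seq[offset + len(orf):]
            planted.append((sid, offset, planted_orf_len))
        records.append((sid, seq))
    return records, planted


def write_fasta(records: list[tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n")
            for k in range(0, len(seq), 70):
                fh.write(seq[k:k + 70] + "\n")
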