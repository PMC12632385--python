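"""Seeded validation experiments over the synthetic study design.

Each experiment regenerates its inputs from a seed, runs the relevant
pipeline operations, and measures agreement with an independent reference
implementation or with the generator's ground truth. They back both the
test suite and the reproducibility script, and the numbers they return
are computed fresh on every call.
"""

from __future__ import annotations

import filecmp
import os
import tempfile

import numpy as np

from . import chromatin_link, diff_sets, meta_stats, reference
from .pipeline import RunConfig, run_pipeline
from .synthetic_data import (SynthConfig, generate_dataset,
                             generate_sequences)


def _seeds(base_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(base_seed)
    return [int(s) for s in ss.generate_state(n) % (2 ** 31)]


def fisher_oracle_error(n: int = 10_000, seed: int = 0) -> float:
    """Max |p_combined - closed-form chi2(4) tail| over random p-pairs."""
    rng = np.random.default_rng(seed)
    pm = rng.uniform(1e-12, 1.0, n)
    pf = rng.uniform(1e-12, 1.0, n)
    x2, p_comb = meta_stats.fisher_combine(pm, pf)
    oracle = np.array([reference.chi2_df4_sf(x) for x in x2])
    return float(np.max(np.abs(p_comb - oracle)))


def bh_equality_max_diff(n_vectors: int = 100, seed: int = 0,
                         n_max: int = 1000) -> float:
    """Max |bh_adjust - brute-force step-up| over random p-vectors."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        n = int(rng.integers(1, n_max + 1))
        p = rng.uniform(1e-10, 1.0, n)
        diff = np.abs(meta_stats.bh_adjust(p) - reference.bh_stepup(p))
        worst = max(worst, float(diff.max()))
    return worst


def local_pairs_check(seed: int = 0, n_lnc: int = 500, n_peaks: int = 2000,
                      window: int = 500_000) -> dict:
    """Set-compare the windowed sweep against the all-pairs scan."""
    cfg = SynthConfig(n_lnc=n_lnc, n_coding=50, n_peaks=n_peaks,
                      n_tissues=1, seed=seed,
                      chrom_lengths={"chr1": 100_000_000})
    ds = generate_dataset(cfg)
    lncs = ds.lnc_models
    fast = {(p.lnc_id, p.peak_id, p.midpoint_distance)
            for p in chromatin_link.find_local_pairs(lncs, ds.peaks, window)}
    brute = reference.local_pairs_bruteforce(lncs, ds.peaks, window)
    return {"n_pairs": len(fast),
            "n_mismatch": len(fast ^ brute)}


def _coupling_config(seed: int) -> SynthConfig:
    # 20 planted couplings among ~10k local pairs on a 100 Mb chromosome
    return SynthConfig(n_lnc=500, n_coding=50, n_peaks=2000, n_tissues=1,
                       frac_coupled=0.04, coupling_r=0.95, noise_sd=0.1,
                       frac_sig_bg_peaks=0.05, frac_low_count=0.0,
                       chrom_lengths={"chr1": 100_000_000}, seed=seed)


def coupling_recovery(seed: int = 0, n_seeds: int = 20) -> dict:
    """Planted lncRNA-peak coupling recovery through the pair filter.

    A pair passes the filter as the pipeline applies it: its peak is
    training-significant (combined q <= 0.05) and its trajectory
    correlation satisfies r >= 0.5. Reports sensitivity on planted
    couplings, the background full-filter pass rate, and the background
    rate through the r gate alone (all averaged over ``n_seeds`` fresh
    datasets).
    """
    sens, bg_full, bg_r = [], [], []
    n_local = 0
    for s in _seeds(seed, n_seeds):
        ds = generate_dataset(_coupling_config(s))
        tissue = ds.config.tissues[0]
        combined = meta_stats.combine_and_adjust(ds.peak_pvalues[tissue])
        sig = set(combined.loc[combined["q"] <= 0.05, "peak_id"])
        pairs = chromatin_link.find_local_pairs(ds.lnc_models, ds.peaks)
        pairs = chromatin_link.correlate_pairs(
            pairs, ds.lnc_trajectories[tissue], ds.peak_trajectories[tissue])
        coupled = ds.truth.coupled_pairs
        n_local += len(pairs)
        hit = bgf = bgr = nbg = 0
        for p in pairs:
            passes_r = p.r is not None and p.r >= 0.5
            passes = passes_r and p.peak_id in sig
            if (p.lnc_id, p.peak_id) in coupled:
                hit += passes
            else:
                nbg += 1
                bgf += passes
                bgr += passes_r
        sens.append(hit / len(coupled))
        bg_full.append(bgf / nbg)
        bg_r.append(bgr / nbg)
    return {
        "sensitivity": float(np.mean(sens)),
        "background_pass_rate": float(np.mean(bg_full)),
        "background_r_only_rate": float(np.mean(bg_r)),
        "mean_local_pairs": n_local / n_seeds,
        "n_seeds": n_seeds,
    }


def coupling_calibration(seed: int = 0, n_seeds: int = 20) -> dict:
    """Mean realized Pearson r of coupled pairs vs the target."""
    rs = []
    for s in _seeds(seed, n_seeds):
        ds = generate_dataset(_coupling_config(s))
        tissue = ds.config.tissues[0]
        lt, pt = ds.lnc_trajectories[tissue], ds.peak_trajectories[tissue]
        for ln, pk in ds.truth.coupled_pairs:
            rs.append(chromatin_link.correlate_pair(
                lt.loc[ln].to_numpy(), pt.loc[pk].to_numpy()))
    return {"mean_r": float(np.mean(rs)), "target_r": 0.95,
            "n_pairs": len(rs)}


def differential_truth_recovery(seed: int = 0, n_seeds: int = 20) -> dict:
    """Exact recovery of the planted differential set by the raw-p filter."""
    mismatches = 0
    cells = 0
    for s in _seeds(seed, n_seeds):
        cfg = SynthConfig(n_lnc=100, n_coding=100, n_peaks=50, n_tissues=1,
                          seed=s)
        ds = generate_dataset(cfg)
        tissue = cfg.tissues[0]
        records = ds.diff_tables[tissue]
        expressed = diff_sets.filter_expressed(records)
        recs = records[records["feature_id"].isin(expressed)]
        called = diff_sets.call_differential(recs).members
        truth = ds.truth.diff_cells[tissue]
        mismatches += len(called ^ truth)
        cells += len(truth)
    return {"mismatches": mismatches, "truth_cells": cells,
            "n_seeds": n_seeds}


def smorf_oracle_check(seed: int = 0, n_seqs: int = 1000,
                       length_range: tuple = (50, 2000)) -> dict:
    """find_smorfs vs the brute-force pattern scan on random sequences."""
    from . import seq_features
    records, _ = generate_sequences(n_seqs, length_range, 0.5, seed)
    mismatches = 0
    n_orfs = 0
    for sid, seq in records:
        got = {(o.frame, o.start_nt, o.end_nt, o.peptide)
               for o in seq_features.find_smorfs(seq, 30, seq_id=sid)}
        want = reference.smorfs_bruteforce(seq, 30)
        mismatches += len(got ^ want)
        n_orfs += len(want)
    return {"mismatches": mismatches, "n_orfs": n_orfs, "n_seqs": n_seqs}


def triad_dedup_check(seed: int = 0, n_runs: int = 50) -> dict:
    """Per-gene uniqueness and max-score selection vs brute force."""
    violations = 0
    n_triads = 0
    for s in _seeds(seed, n_runs):
        cfg = SynthConfig(n_lnc=40, n_coding=60, n_peaks=150, n_tissues=1,
                          frac_coupled=0.3, seed=s,
                          chrom_lengths={"chr1": 10_000_000})
        ds = generate_dataset(cfg)
        tissue = cfg.tissues[0]
        pairs = chromatin_link.find_local_pairs(ds.lnc_models, ds.peaks)
        pairs = chromatin_link.correlate_pairs(
            pairs, ds.lnc_trajectories[tissue], ds.peak_trajectories[tissue])
        triads = chromatin_link.build_triads(pairs, ds.genes, ds.peaks,
                                             set(), set())
        n_triads += len(triads)
        genes_seen = [t.gene_id for t in triads]
        if len(genes_seen) != len(set(genes_seen)):
            violations += 1
            continue
        # rebuild candidate list and compare winners
        cand = []
        peak_by_id = {p.peak_id: p for p in ds.peaks}
        for p in pairs:
            if p.r is None or p.r < 0.5:
                continue
            hit = chromatin_link.nearest_coding_tss(peak_by_id[p.peak_id],
                                                    ds.genes)
            if hit is None:
                continue
            gid, d = hit
            cand.append((gid, chromatin_link.activity_score(p.r, d), d,
                         p.lnc_id, p.peak_id))
        best = reference.triads_bruteforce(cand)
        got = {(t.gene_id, t.activity_score, t.tss_distance, t.lnc_id,
                t.peak_id) for t in triads}
        want = set(best.values())
        violations += len(got ^ want)
    return {"violations": violations, "n_triads": n_triads, "n_runs": n_runs}


def determinism_check(seed: int = 0) -> dict:
    """Byte-compare two identical pipeline runs' tables and summary."""
    synth = SynthConfig(n_lnc=60, n_coding=120, n_peaks=300, n_tissues=2,
                        seed=seed)
    with tempfile.TemporaryDirectory() as tmp:
        outs = []
        for run in ("a", "b"):
            out = os.path.join(tmp, run)
            run_pipeline(RunConfig(outdir=out, seed=seed, synth=synth))
            outs.append(out)
        differing = []
        for name in sorted(os.listdir(outs[0])):
            if name == "run.log" or not (name.endswith(".tsv")
                                         or name.endswith(".json")
                                         or name.endswith(".bed")
                                         or name.endswith(".fa")):
                continue
            if not filecmp.cmp(os.path.join(outs[0], name),
                               os.path.join(outs[1], name), shallow=False):
                differing.append(name)
        n_compared = sum(1 for n in os.listdir(outs[0])
                         if n != "run.log" and not os.path.isdir(
                             os.path.join(outs[0], n)))
    return {"files_compared": n_compared, "files_differing": len(differing)}


def null_fdr_control(seed: int = 0, n_seeds: int = 50, n: int = 2000,
                     alpha: float = 0.05) -> dict:
    """Fraction of null features with q <= alpha after Fisher + BH."""
    fracs = []
    for s in _seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        pm = rng.uniform(1e-12, 1.0, n)
        pf = rng.uniform(1e-12, 1.0, n)
        _, p_comb = meta_stats.fisher_combine(pm, pf)
        q = meta_stats.bh_adjust(p_comb)
        fracs.append(float((q <= alpha).mean()))
    return {"mean_fraction": float(np.mean(fracs)), "alpha": alpha,
            "n_seeds": n_seeds}
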