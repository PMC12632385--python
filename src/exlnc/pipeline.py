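"""End-to-end orchestration: filter -> differential -> combine -> peaks ->
link -> triads -> sequence features, with a JSON gate-count summary.

Every stage writes deterministic TSV/JSON output (timestamps are confined
to the log), so re-running an identical configuration reproduces
byte-identical result files.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import chromatin_link, diff_sets, genome_io, meta_stats, seq_features
from .genome_io import BIOTYPE_CODING, BIOTYPE_LNCRNA
from .synthetic_data import SynthConfig, generate_dataset, generate_sequences, \
    write_dataset, write_fasta

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage thresholds plus input locations (or a synthetic config)."""

    outdir: str = "exlnc_out"
    fpkm_min: float = 1.0
    p_max: float = 0.01
    lfc_min: float = 1.0
    fdr: float = 0.10
    lfc_min_stringent: float = 0.5
    window: int = 500_000
    r_min: float = 0.5
    peak_fdr: float = 0.05
    min_reads: int = 10
    min_samples: int = 4
    smorf_min_len: int = 30
    scheme: str = "primary"            # primary | stringent
    seed: int = 0
    simulate: bool = True
    synth: SynthConfig | None = None
    inputs: dict = field(default_factory=dict)  # file mode: paths per key

    def __post_init__(self) -> None:
        if self.scheme not in ("primary", "stringent"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.simulate and self.synth is None:
            self.synth = SynthConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        synth = raw.pop("synth", None)
        cfg = cls(**raw)
        if synth is not None:
            cfg.synth = SynthConfig(**synth)
        return cfg

    def thresholds(self) -> dict:
        return {
            "fpkm_min": self.fpkm_min, "p_max": self.p_max,
            "lfc_min": self.lfc_min, "fdr": self.fdr,
            "lfc_min_stringent": self.lfc_min_stringent,
            "window": self.window, "r_min": self.r_min,
            "peak_fdr": self.peak_fdr, "min_reads": self.min_reads,
            "min_samples": self.min_samples,
            "smorf_min_len": self.smorf_min_len, "scheme": self.scheme,
        }


def _validate_inputs(cfg: RunConfig) -> None:
    if cfg.simulate:
        return
    required = {"gtf", "peaks", "counts", "diff_tables", "lnc_trajectories",
                "peak_trajectories", "peak_pvalues"}
    missing = required - set(cfg.inputs)
    if missing:
        raise FileNotFoundError(f"missing input keys: {sorted(missing)}")
    paths = [cfg.inputs["gtf"], cfg.inputs["peaks"], cfg.inputs["counts"]]
    for group in ("diff_tables", "lnc_trajectories", "peak_trajectories",
                  "peak_pvalues"):
        paths.extend(cfg.inputs[group].values())
    for p in paths:
        if not os.path.exists(p):
            raise FileNotFoundError(f"input file not found: {p}")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the summary dict (also written as JSON)."""
    _validate_inputs(config)
    os.makedirs(config.outdir, exist_ok=True)
    log_path = os.path.join(config.outdir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("exlnc")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(cfg: RunConfig) -> dict:
    out = cfg.outdir
    summary: dict = {"thresholds": cfg.thresholds(),
                     "fdr_procedure": meta_stats.FDR_PROCEDURE,
                     "tissues": {}}

    if cfg.simulate:
        ds = generate_dataset(cfg.synth)
        input_dir = os.path.join(out, "inputs")
        write_dataset(ds, input_dir)
        genes = ds.genes
        raw_peaks = ds.raw_peaks
        counts = ds.peak_counts
        diff_tables = ds.diff_tables
        lnc_trajs = ds.lnc_trajectories
        peak_trajs = ds.peak_trajectories
        peak_pvals = ds.peak_pvalues
    else:
        genes = genome_io.read_gene_models(cfg.inputs["gtf"])
        raw_peaks = genome_io.read_peaks(cfg.inputs["peaks"])
        counts = genome_io.read_peak_counts(cfg.inputs["counts"])
        diff_tables = {t: diff_sets.read_diff_table(p)
                       for t, p in cfg.inputs["diff_tables"].items()}
        lnc_trajs = {t: pd.read_csv(p, sep="\t", index_col=0)
                     for t, p in cfg.inputs["lnc_trajectories"].items()}
        peak_trajs = {t: pd.read_csv(p, sep="\t", index_col=0)
                      for t, p in cfg.inputs["peak_trajectories"].items()}
        peak_pvals = {t: pd.read_csv(p, sep="\t")
                      for t, p in cfg.inputs["peak_pvalues"].items()}

    gene_by_id = {g.gene_id: g for g in genes}
    lnc_models = [g for g in genes if g.biotype == BIOTYPE_LNCRNA]

    # ---- peaks: master list + count gate (shared across tissues) ----
    master = genome_io.trim_and_merge_peaks(raw_peaks)
    kept_peaks = genome_io.filter_peaks_by_counts(
        master, counts, cfg.min_reads, cfg.min_samples)
    kept_ids = {p.peak_id for p in kept_peaks}
    logger.info("master peaks: %d, after count filter: %d",
                len(master), len(kept_peaks))
    summary["master_peaks"] = len(master)
    summary["peaks_after_count_filter"] = len(kept_peaks)

    for tissue, records in sorted(diff_tables.items()):
        tsum: dict = {}
        # expression gate, then differential calls
        expressed = diff_sets.filter_expressed(records, cfg.fpkm_min)
        recs = records[records["feature_id"].isin(expressed)].copy()
        recs["adj_p"] = meta_stats.bh_adjust(recs["p_value"].to_numpy())
        lnc_ids_all = {g.gene_id for g in lnc_models}
        lnc_recs = recs[recs["feature_id"].isin(lnc_ids_all)]
        pcg_recs = recs[~recs["feature_id"].isin(lnc_ids_all)]
        primary = diff_sets.call_differential(lnc_recs, cfg.p_max, cfg.lfc_min)
        stringent = diff_sets.call_differential_fdr(
            lnc_recs, cfg.fdr, cfg.lfc_min_stringent)
        delnc = primary if cfg.scheme == "primary" else stringent
        tsum["expressed_features"] = len(expressed)
        tsum["delnc_cells"] = len(delnc.members)
        tsum["unique_delncs"] = len(delnc.unique_features)
        tsum["unique_delncs_stringent"] = len(stringent.unique_features)
        diff_sets.write_diff_set(
            delnc, os.path.join(out, f"{tissue}.delnc.tsv"))

        # sex overlap of unique differential lncRNAs
        by_sex = {s: {m[0] for m in delnc.members if m[1] == s}
                  for s in ("M", "F")}
        ov = diff_sets.sex_overlap_summary(by_sex["M"], by_sex["F"])
        tsum["sex_overlap"] = {
            "shared": len(ov["shared"]), "male_only": len(ov["male_only"]),
            "female_only": len(ov["female_only"]),
            "shared_pct": round(ov["shared_pct"], 4),
        }

        # Z-score trajectory summaries over the differential set, per sex
        if delnc.unique_features:
            lfc = lnc_recs.pivot_table(index="feature_id",
                                       columns=["sex", "week"],
                                       values="log2fc")
            z = diff_sets.zscore_by_feature(lfc)
            tsum["trajectory"] = {}
            for sex in ("M", "F"):
                zt = z[sex]
                ts = diff_sets.trajectory_summary(
                    zt, delnc.unique_features, tissue, sex)
                tsum["trajectory"][sex] = {
                    "mean_z": round(ts.mean_z, 6),
                    "delta_z_w8_w1": round(ts.delta_z_w8_w1, 6),
                }

        # coding-gene direction sets (primary scheme on coding records)
        pcg_diff = diff_sets.call_differential(pcg_recs, cfg.p_max,
                                               cfg.lfc_min)
        mean_lfc = pcg_recs.groupby("feature_id")["log2fc"].mean()
        up = {f for f in pcg_diff.unique_features if mean_lfc.get(f, 0) > 0}
        down = pcg_diff.unique_features - up
        tsum["de_genes_up"] = len(up)
        tsum["de_genes_down"] = len(down)

        # training-significant peaks: Fisher + BH on the count-filtered list
        ppv = peak_pvals[tissue]
        ppv = ppv[ppv["peak_id"].isin(kept_ids)].reset_index(drop=True)
        combined = meta_stats.combine_and_adjust(ppv)
        combined.to_csv(os.path.join(out, f"{tissue}.peak_significance.tsv"),
                        sep="\t", index=False, float_format="%.10g")
        sig_ids = set(combined.loc[combined["q"] <= cfg.peak_fdr, "peak_id"])
        sig_peaks = [p for p in kept_peaks if p.peak_id in sig_ids]
        tsum["significant_peaks"] = len(sig_peaks)
        genome_io.write_peaks(sig_peaks,
                              os.path.join(out, f"{tissue}.sig_peaks.bed"))

        # local pairing, trajectory correlation, triads
        delnc_models = [gene_by_id[f] for f in sorted(delnc.unique_features)
                        if f in gene_by_id]
        pairs = chromatin_link.find_local_pairs(delnc_models, sig_peaks,
                                                cfg.window)
        ltraj, ptraj = lnc_trajs[tissue], peak_trajs[tissue]
        pairs = chromatin_link.correlate_pairs(pairs, ltraj, ptraj)
        pair_df = chromatin_link.pairs_to_frame(pairs)
        pair_df.to_csv(os.path.join(out, f"{tissue}.pairs.tsv"), sep="\t",
                       index=False, na_rep=".", float_format="%.10g")
        triads = chromatin_link.build_triads(pairs, genes, sig_peaks, up,
                                             down, cfg.r_min)
        chromatin_link.triads_to_frame(triads).to_csv(
            os.path.join(out, f"{tissue}.triads.tsv"), sep="\t", index=False,
            float_format="%.10g")
        n_rpass = sum(1 for p in pairs if p.r is not None and p.r >= cfg.r_min)
        tsum["local_pairs"] = len(pairs)
        tsum["pairs_r_pass"] = n_rpass
        tsum["triads"] = len(triads)
        logger.info("%s: %d pairs, %d pass r >= %g, %d triads", tissue,
                    len(pairs), n_rpass, cfg.r_min, len(triads))
        summary["tissues"][tissue] = tsum

    # ---- sequence features (simulated transcript sequences) ----
    if cfg.simulate:
        seq_seed = cfg.synth.seed + 10_007
        lnc_seqs, _ = generate_sequences(60, (300, 2000), 0.42, seq_seed)
        pcg_seqs, _ = generate_sequences(60, (800, 4000), 0.52, seq_seed + 1)
        lnc_fa = os.path.join(out, "lnc_transcripts.fa")
        write_fasta(lnc_seqs, lnc_fa)
        gc_l = [seq_features.gc_content(s) for _, s in lnc_seqs]
        gc_p = [seq_features.gc_content(s) for _, s in pcg_seqs]
        len_l = [len(s) for _, s in lnc_seqs]
        len_p = [len(s) for _, s in pcg_seqs]
        t_gc = seq_features.compare_groups(gc_l, gc_p, "rank")
        t_len = seq_features.compare_groups(len_l, len_p, "rank")
        n_orfs = sum(len(seq_features.find_smorfs(s, cfg.smorf_min_len,
                                                  seq_id=sid))
                     for sid, s in lnc_seqs)
        n_pep = seq_features.build_microprotein_db(
            lnc_fa, os.path.join(out, "microproteins.fa"),
            cfg.smorf_min_len)
        summary["seq_features"] = {
            "gc_test": {"statistic": t_gc.statistic,
                        "p_value": float(f"{t_gc.p_value:.6g}")},
            "length_test": {"statistic": t_len.statistic,
                            "p_value": float(f"{t_len.p_value:.6g}")},
            "smorfs": n_orfs, "microprotein_db_records": n_pep,
        }

    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
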