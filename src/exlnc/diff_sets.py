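"""Differential lncRNA set construction and summaries.

Differential calls operate on per-tissue/sex/week contrast tables (each
training week versus the sex-matched sedentary controls). Two schemes are
supported:

* primary   - raw p <= 0.01 and |log2FC| >= 1, applied to features passing
              the expression gate (mean FPKM >= 1); tuned for sensitivity
              toward low-abundance lncRNAs.
* stringent - BH-adjusted p <= 0.10 and |log2FC| >= 0.5; the exploratory
              high-confidence set.

The inclusive boundaries follow the operational description of the filters;
strict (>, <) variants are available via the ``strict`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

WEEKS = (1, 2, 4, 8)
SEXES = ("M", "F")

#: canonical column order for differential-result tables
DIFF_COLUMNS = [
    "feature_id", "tissue", "sex", "week", "log2fc", "p_value", "adj_p",
    "mean_fpkm",
]


@dataclass
class DiffSet:
    """Members are (feature_id, sex, week) cells passing a scheme's gates."""

    tissue: str
    scheme: str
    members: set[tuple[str, str, int]] = field(default_factory=set)

    @property
    def unique_features(self) -> set[str]:
        return {m[0] for m in self.members}


@dataclass(frozen=True)
class TrajectorySummary:
    tissue: str
    sex: str
    mean_z: float
    delta_z_w8_w1: float


def read_diff_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["."])
    missing = [c for c in DIFF_COLUMNS if c not in df.columns and c != "adj_p"]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if "adj_p" not in df.columns:
        df["adj_p"] = np.nan
    return df


def write_diff_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.10g")


def filter_expressed(records: pd.DataFrame, fpkm_min: float = 1.0,
                     strict: bool = False) -> set[str]:
    """Feature ids whose mean FPKM passes the expression gate.

    Inclusive by default (mean FPKM >= ``fpkm_min``); ``strict=True``
    requires a strictly greater value.
    """
    fpkm = records.groupby("feature_id")["mean_fpkm"].first()
    na = fpkm.index[fpkm.isna()].tolist()
    if na:
        raise ValueError(f"mean_fpkm missing for features: {sorted(na)}")
    mask = fpkm > fpkm_min if strict else fpkm >= fpkm_min
    return set(fpkm.index[mask])


def call_differential(records: pd.DataFrame, p_max: float = 0.01,
                      lfc_min: float = 1.0, strict: bool = False) -> DiffSet:
    """Primary-scheme differential cells: p <= p_max and |log2FC| >= lfc_min.

    ``records`` should already be expression-filtered.
    """
    if strict:
        mask = (records["p_value"] < p_max) & (records["log2fc"].abs() > lfc_min)
    else:
        mask = (records["p_value"] <= p_max) & (records["log2fc"].abs() >= lfc_min)
    tissue = _single_tissue(records)
    members = {
        (r.feature_id, r.sex, int(r.week))
        for r in records[mask].itertuples(index=False)
    }
    return DiffSet(tissue, "primary", members)


def call_differential_fdr(records: pd.DataFrame, fdr: float = 0.10,
                          lfc_min: float = 0.5, strict: bool = False
                          ) -> DiffSet:
    """Stringent-scheme differential cells: adj_p <= fdr and |log2FC| >= lfc_min.

    Requires the ``adj_p`` column to be populated (see
    :func:`exlnc.meta_stats.bh_adjust`, applied within tissue).
    """
    if records["adj_p"].isna().any():
        raise ValueError(
            "adj_p missing; compute it with exlnc.meta_stats.bh_adjust "
            "within tissue before calling the stringent scheme"
        )
    if strict:
        mask = (records["adj_p"] < fdr) & (records["log2fc"].abs() > lfc_min)
    else:
        mask = (records["adj_p"] <= fdr) & (records["log2fc"].abs() >= lfc_min)
    tissue = _single_tissue(records)
    members = {
        (r.feature_id, r.sex, int(r.week))
        for r in records[mask].itertuples(index=False)
    }
    return DiffSet(tissue, "stringent", members)


def _single_tissue(records: pd.DataFrame) -> str:
    tissues = records["tissue"].unique()
    return tissues[0] if len(tissues) == 1 else "multi"


def sex_overlap_summary(male_set: set, female_set: set) -> dict:
    """Shared/sex-exclusive feature counts; shared_pct over the union."""
    shared = male_set & female_set
    union = male_set | female_set
    return {
        "shared": shared,
        "male_only": male_set - female_set,
        "female_only": female_set - male_set,
        "shared_pct": 100.0 * len(shared) / len(union) if union else 0.0,
    }


def zscore_by_feature(expr: pd.DataFrame) -> pd.DataFrame:
    """Standardize each row (feature) to mean 0, sd 1 across columns.

    Zero-variance rows become all-zero rather than NaN.
    """
    mat = expr.to_numpy(dtype=float)
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((mat - mu) / sd, index=expr.index,
                        columns=expr.columns)


def trajectory_summary(z_table: pd.DataFrame, diff_features: set,
                       tissue: str = "", sex: str = "") -> TrajectorySummary:
    """Mean Z and week-8 minus week-1 Z shift over the differential set.

    ``z_table`` is a feature x week matrix of standardized expression with
    the four training weeks as columns.
    """
    sub = z_table.loc[z_table.index.intersection(diff_features)]
    if sub.empty:
        raise ValueError("empty differential set for trajectory summary")
    for w in WEEKS:
        if w not in sub.columns:
            raise ValueError(f"week {w} missing from z_table columns")
    mean_z = float(sub[list(WEEKS)].to_numpy().mean())
    delta = float(sub[8].mean() - sub[1].mean())
    return TrajectorySummary(tissue, sex, mean_z, delta)


def build_cerna_network(mirna_targets: dict[str, set], up_degs: set,
                        lnc_id: str) -> list[tuple[str, str, str]]:
    """Competing-endogenous-RNA edges for one lncRNA.

    Emits lnc->miRNA edges for every miRNA and miRNA->gene edges for targets
    that are upregulated differential coding genes. Edge tuples are
    (source, target, edge_type).
    """
    edges = []
    for mirna in sorted(mirna_targets):
        edges.append((lnc_id, mirna, "lnc-mirna"))
        for gene in sorted(mirna_targets[mirna] & up_degs):
            edges.append((mirna, gene, "mirna-gene"))
    return edges


def write_diff_set(ds: DiffSet, path: str) -> None:
    rows = sorted(ds.members)
    df = pd.DataFrame(rows, columns=["feature_id", "sex", "week"])
    df.insert(1, "tissue", ds.tissue)
    df.insert(2, "scheme", ds.scheme)
    df.to_csv(path, sep="\t", index=False)
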