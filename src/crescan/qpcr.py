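"""qPCR relative-expression analysis for enhancer-deletion experiments.

Implements the 2^-ΔΔCt estimator with multi-gene housekeeping
normalization, one-way ANOVA on ΔCt values with Dunn–Šidák family-wise
correction, and a coarse effect classification (abolished / reduced /
spared) for each assayed gene.

Normalization note: "geometric mean of the housekeeping genes" refers to
the geometric mean of the housekeeping expression quantities 2^-Ct.
Because -log2(geomean_i 2^-Ct_i) = mean_i Ct_i, subtracting the arithmetic
mean of housekeeping Ct values is algebraically the same operation on the
Ct scale; that is what ``delta_ct`` computes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ("sample", "genotype", "gene", "replicate", "ct")


def read_ct_table(path) -> pd.DataFrame:
    """Read a delimited Ct table (CSV or TSV, sniffed) with columns
    sample, genotype, gene, replicate, ct."""
    df = pd.read_csv(path, sep=None, engine="python")
    return validate_ct_table(df)


def validate_ct_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    df = df.loc[:, list(CT_COLUMNS)].copy()
    df["ct"] = pd.to_numeric(df["ct"])
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return df


def delta_ct(table: pd.DataFrame, housekeeping: "list[str]") -> pd.DataFrame:
    """Per-sample, per-gene ΔCt relative to the housekeeping geometric mean.

    Technical replicates are averaged per (sample, gene) first; the
    housekeeping reference per sample is the arithmetic mean of the
    housekeeping genes' Ct values (equivalently, -log2 of the geometric
    mean of their 2^-Ct quantities).  Housekeeping genes themselves get
    ΔCt values too, which is useful as a self-normalization check.
    """
    table = validate_ct_table(table)
    if not housekeeping:
        raise ValueError("at least one housekeeping gene required")
    per = (
        table.groupby(["sample", "genotype", "gene"], sort=True)["ct"]
        .mean()
        .reset_index()
    )
    hk = per[per["gene"].isin(housekeeping)]
    found = hk.groupby("sample")["gene"].nunique()
    all_samples = per["sample"].unique()
    bad = [
        s
        for s in all_samples
        if found.get(s, 0) != len(set(housekeeping))
    ]
    if bad:
        raise ValueError(
            f"samples missing housekeeping measurements: {sorted(map(str, bad))}"
        )
    ref = hk.groupby("sample")["ct"].mean().rename("hk_ct")
    out = per.merge(ref, on="sample")
    out["delta_ct"] = out["ct"] - out["hk_ct"]
    return out[["sample", "genotype", "gene", "delta_ct"]]


@dataclass(frozen=True)
class FoldChangeResult:
    """Relative expression of one gene in one genotype vs the control."""

    gene: str
    genotype: str
    fold: float
    delta_ct_values: tuple[float, ...]
    ddct: float
    p_value: float
    p_adjusted: float
    effect: str  # abolished | reduced | spared


def ddct_fold(dct: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Per (gene, genotype): ΔΔCt = mean ΔCt(genotype) - mean ΔCt(control)
    and fold = 2^-ΔΔCt.  The control group's fold is 1 by construction."""
    if control_group not in set(dct["genotype"]):
        raise ValueError(f"control group {control_group!r} absent from table")
    ctrl = (
        dct[dct["genotype"] == control_group]
        .groupby("gene")["delta_ct"]
        .mean()
        .rename("control_mean_dct")
    )
    missing = set(dct["gene"]) - set(ctrl.index)
    if missing:
        raise ValueError(f"genes absent in control group: {sorted(missing)}")
    grouped = (
        dct.groupby(["gene", "genotype"])["delta_ct"]
        .agg(["mean", list])
        .reset_index()
        .rename(columns={"mean": "mean_dct", "list": "delta_ct_values"})
    )
    grouped = grouped.merge(ctrl, on="gene")
    grouped["ddct"] = grouped["mean_dct"] - grouped["control_mean_dct"]
    grouped["fold"] = 2.0 ** (-grouped["ddct"])
    return grouped[
        ["gene", "genotype", "ddct", "fold", "delta_ct_values", "control_mean_dct"]
    ].sort_values(["gene", "genotype"], ignore_index=True)


def sidak_adjust(p: "float | np.ndarray", family_size: int) -> "float | np.ndarray":
    """Dunn–Šidák family-wise adjustment: p_adj = 1 - (1 - p)^m."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return 1.0 - (1.0 - np.asarray(p, dtype=float)) ** family_size


def anova_dunn_sidak(
    dct: pd.DataFrame, family_size: "int | None" = None
) -> pd.DataFrame:
    """One-way ANOVA across genotypes on per-sample ΔCt, per gene, with
    Dunn–Šidák correction for a family of ``family_size`` comparisons
    (defaults to the number of genes tested).

    Degenerate groups (zero within-group variance) yield p = 1 when group
    means are equal, p = 0 when they differ.
    """
    genes = sorted(dct["gene"].unique())
    m = family_size if family_size is not None else len(genes)
    if m < 1:
        raise ValueError("family_size must be >= 1")
    rows = []
    for gene in genes:
        sub = dct[dct["gene"] == gene]
        groups = [g["delta_ct"].to_numpy() for _, g in sub.groupby("genotype")]
        if len(groups) < 2 or any(len(g) < 2 for g in groups):
            raise ValueError(
                f"gene {gene!r}: need >=2 groups with >=2 observations each"
            )
        if all(np.ptp(g) == 0 for g in groups):
            means = [g[0] for g in groups]
            p = 0.0 if np.ptp(means) > 0 else 1.0
        else:
            p = float(stats.f_oneway(*groups).pvalue)
            if np.isnan(p):
                p = 1.0
        rows.append({"gene": gene, "p_value": p})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = sidak_adjust(out["p_value"].to_numpy(), m)
    out["family_size"] = m
    return out


def classify_effect(
    results: pd.DataFrame,
    fold_abolished: float = 0.05,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Label each (gene, genotype) row: 'abolished' when fold <=
    fold_abolished and significant, 'reduced' when fold < 1 and
    significant, otherwise 'spared'."""
    if not 0 < fold_abolished < 1 or not 0 < alpha < 1:
        raise ValueError("thresholds must be in (0, 1)")

    def label(row):
        sig = row["p_adjusted"] < alpha
        if sig and row["fold"] <= fold_abolished:
            return "abolished"
        if sig and row["fold"] < 1:
            return "reduced"
        return "spared"

    out = results.copy()
    out["effect"] = out.apply(label, axis=1)
    return out


def analyze(
    table: pd.DataFrame,
    housekeeping: "list[str]",
    control_group: str,
    family_size: "int | None" = None,
    fold_abolished: float = 0.05,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full pipeline: ΔCt → ΔΔCt folds → ANOVA + Šidák → effect classes.

    Returns one row per (gene, genotype); the control genotype appears with
    fold 1 and the gene-level adjusted p-value.
    """
    dct = delta_ct(table, housekeeping)
    folds = ddct_fold(dct, control_group)
    tests = anova_dunn_sidak(dct, family_size=family_size)
    merged = folds.merge(tests, on="gene")
    return classify_effect(merged, fold_abolished=fold_abolished, alpha=alpha)
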