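"""Module activation scoring in independent cohorts.

Validation data are z-scored per gene against the cohort's normal/healthy
samples, z_gs = (x_gs - mu_gN) / (sigma_gN + offset), with a population-SD
convention and an optional additive offset for small normal groups.  A
module's single-modality activation score in sample *s* is the signed
average

    score_ms = (1/|m|) * sum_{g in m} Sign(t_g) * z_gs

over the discovery-significant module genes present, with Sign(t_g) the
direction of the discovery t-statistic.  When both DNAm and RNA are
available the joint variant uses the mean absolute z-divergence
|z^(M) - z^(R)| over the discovery-significant, anti-correlated genes; the
DNAm z-score SD is offset-calibrated genome-wide to match the RNA z-score
SD.  Group separation is evaluated by one-tailed Wilcoxon rank-sum and AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats


@dataclass
class ModuleSignature:
    """Discovery-derived gene signs (+1/-1) for one module and modality."""

    module_id: str
    signs: pd.Series  # gene -> +1/-1, discovery-significant genes only

    def __post_init__(self) -> None:
        if (self.signs == 0).any():
            raise ValueError("signature signs must be nonzero")


def signature_from_stats(
    module_members,
    stats: pd.DataFrame,
    modality: str = "dnam",
    module_id: str = "M1",
    fdr_thresh: float = 0.05,
    anticorrelated_only: bool = False,
) -> ModuleSignature:
    """Build a modality signature from discovery statistics.

    ``modality`` selects the t/fdr columns ("dnam" → t_dm/dm_fdr, "rna" →
    t_de/de_fdr).  Only discovery-significant genes carry signs;
    ``anticorrelated_only`` additionally requires opposite DNAm/expression
    directions with both significant (the joint-score signature).
    """
    tcol, fcol = ("t_dm", "dm_fdr") if modality == "dnam" else ("t_de", "de_fdr")
    sub = stats.loc[[g for g in module_members if g in stats.index]]
    keep = sub[fcol] < fdr_thresh
    if anticorrelated_only:
        keep &= (
            (sub["dm_fdr"] < fdr_thresh)
            & (sub["de_fdr"] < fdr_thresh)
            & (np.sign(sub["t_dm"]) == -np.sign(sub["t_de"]))
            & (sub["t_dm"] != 0)
        )
    sub = sub[keep]
    signs = np.sign(sub[tcol]).astype(int)
    signs = signs[signs != 0]
    return ModuleSignature(module_id=module_id, signs=signs)


def zscore_vs_normals(
    matrix: pd.DataFrame, normal_ids, offset: float = 0.0
) -> pd.DataFrame:
    """z-score each gene against the normal samples (population SD)."""
    normal_ids = [s for s in normal_ids if s in matrix.columns]
    if len(normal_ids) < 2:
        raise ValueError("need >=2 normal samples for z-scoring")
    mu = matrix[normal_ids].mean(axis=1)
    sd = matrix[normal_ids].std(axis=1, ddof=0)
    denom = sd + offset
    keep = denom > 0
    if (~keep).any():
        warnings.warn(
            f"dropping {int((~keep).sum())} gene(s) with zero normal SD "
            "and zero offset",
            stacklevel=2,
        )
    z = matrix.loc[keep].sub(mu[keep], axis=0).div(denom[keep], axis=0)
    return z


def fem_score_signed(z: pd.DataFrame, sig: ModuleSignature) -> pd.DataFrame:
    """Signed-average module score per sample.

    Returns a DataFrame (sample_id, module_id, score, n_genes_used) or
    raises if no signature gene is present.
    """
    genes = sig.signs.index.intersection(z.index)
    if len(genes) == 0:
        raise ValueError(f"module {sig.module_id}: no signature gene present")
    s = sig.signs.loc[genes].to_numpy(dtype=float)
    scores = (z.loc[genes].to_numpy(dtype=float) * s[:, None]).mean(axis=0)
    return pd.DataFrame(
        {
            "sample_id": z.columns,
            "module_id": sig.module_id,
            "score": scores,
            "n_genes_used": len(genes),
        }
    )


@dataclass
class OffsetCalibration:
    gamma_offset: float
    achieved_sd: float
    target_sd: float
    clamped: bool = False


def calibrate_offset(
    meth: pd.DataFrame,
    normal_ids,
    target_sd: float,
    tol: float = 1e-6,
) -> OffsetCalibration:
    """Find the SD offset making genome-wide DNAm z-score SD hit a target.

    The offset enters the z denominator, so the genome-wide z SD is a
    strictly decreasing function of it; the root is found by bisection.  If
    the SD at zero offset is already at or below the target the offset is
    clamped to 0 with a warning.
    """

    def sd_at(gamma: float) -> float:
        z = zscore_vs_normals(meth, normal_ids, offset=gamma)
        v = z.to_numpy(dtype=float).ravel()
        if not np.isfinite(v).all():
            raise ValueError("non-finite z-scores during calibration")
        return float(np.std(v))

    sd0 = sd_at(0.0)
    if sd0 <= target_sd:
        if sd0 < target_sd:
            warnings.warn(
                "z-score SD at zero offset already below target; offset "
                "clamped to 0",
                stacklevel=2,
            )
        return OffsetCalibration(0.0, sd0, target_sd, clamped=sd0 < target_sd)
    hi = 1.0
    while sd_at(hi) > target_sd:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError("offset calibration failed to bracket target")
    gamma = optimize.brentq(
        lambda g: sd_at(g) - target_sd, 0.0, hi, xtol=tol, rtol=8.9e-16
    )
    return OffsetCalibration(float(gamma), sd_at(gamma), target_sd)


def fem_score_joint(
    z_meth: pd.DataFrame, z_rna: pd.DataFrame, sig: ModuleSignature
) -> pd.DataFrame:
    """Joint DNAm+RNA divergence score: mean |z_M - z_R| over the signature."""
    samples = z_meth.columns.intersection(z_rna.columns)
    if len(samples) == 0:
        raise ValueError("no common samples between modalities")
    genes = sig.signs.index.intersection(z_meth.index).intersection(z_rna.index)
    if len(genes) == 0:
        raise ValueError(f"module {sig.module_id}: no signature gene present")
    d = np.abs(
        z_meth.loc[genes, samples].to_numpy(dtype=float)
        - z_rna.loc[genes, samples].to_numpy(dtype=float)
    )
    return pd.DataFrame(
        {
            "sample_id": samples,
            "module_id": sig.module_id,
            "score": d.mean(axis=0),
            "n_genes_used": len(genes),
        }
    )


def fem_score_scrna(
    logexpr: pd.DataFrame,
    sig: ModuleSignature,
    normal_cells,
    min_var_genes: int = 5,
) -> pd.DataFrame | None:
    """Per-cell signed score, gated on signature-gene variability.

    Signature genes must vary across the scored cells; with fewer than
    ``min_var_genes`` variable genes the module is unscoreable (returns
    None).  z-scoring uses the normal cells as reference.
    """
    normal_cells = [c for c in normal_cells if c in logexpr.columns]
    if len(normal_cells) < 2:
        raise ValueError("need >=2 normal cells")
    genes = sig.signs.index.intersection(logexpr.index)
    variable = [
        g for g in genes if logexpr.loc[g].to_numpy(dtype=float).var() > 0
    ]
    if len(variable) < min_var_genes:
        warnings.warn(
            f"module {sig.module_id}: only {len(variable)} variable "
            f"signature genes (<{min_var_genes}); unscoreable",
            stacklevel=2,
        )
        return None
    z = zscore_vs_normals(logexpr.loc[variable], normal_cells)
    return fem_score_signed(
        z, ModuleSignature(sig.module_id, sig.signs.loc[z.index])
    )


def evaluate_scores(
    scores: pd.DataFrame,
    groups: pd.Series,
    positive_group,
    exact_n: int = 25,
) -> dict:
    """One-tailed Wilcoxon rank-sum and AUC for case-vs-rest separation.

    Alternative: the positive group has larger scores.  AUC = U/(n1*n2)
    (ties count one half).  The exact null distribution is used below a
    combined n of ``exact_n`` when there are no ties.
    """
    g = groups.reindex(scores["sample_id"]).to_numpy()
    pos = scores.loc[g == positive_group, "score"].to_numpy(dtype=float)
    neg = scores.loc[g != positive_group, "score"].to_numpy(dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both groups must be non-empty")
    n = len(pos) + len(neg)
    has_ties = len(np.unique(np.concatenate([pos, neg]))) < n
    method = "exact" if (n < exact_n and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(pos, neg, alternative="greater", method=method)
    auc = float(res.statistic) / (len(pos) * len(neg))
    return {
        "wilcoxon_p": float(res.pvalue),
        "auc": auc,
        "n_pos": len(pos),
        "n_neg": len(neg),
    }


def score_with_covariate_adjustment(
    scores: pd.DataFrame,
    groups: pd.Series,
    covariate: pd.Series,
    positive_group,
) -> dict:
    """Group effect on score adjusted for a per-sample covariate (OLS)."""
    ids = scores["sample_id"]
    y = scores["score"].to_numpy(dtype=float)
    g = (groups.reindex(ids).to_numpy() == positive_group).astype(float)
    c = covariate.reindex(ids).to_numpy(dtype=float)
    if np.isnan(c).any():
        raise ValueError("covariate missing for some samples")
    if np.std(c) == 0:
        warnings.warn(
            "constant covariate; reduces to unadjusted test", stacklevel=2
        )
        X = sm.add_constant(g)
    else:
        X = sm.add_constant(np.column_stack([g, c]))
    fit = sm.OLS(y, X).fit()
    return {"t": float(fit.tvalues[1]), "p": float(fit.pvalues[1])}
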