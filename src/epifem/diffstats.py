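"""Cell-fraction-adjusted differential statistics.

The workhorse is an empirical-Bayes moderated t-statistic: per-gene ordinary
least squares of the measurement on group plus covariates, with residual
variances shrunk toward a common prior fitted by moments matching on the log
residual variances (scaled inverse-chi-square prior with hyperparameters
``d0`` and ``s0^2``).  The moderated t for gene *g* is

    t_g = b_g / (u * s_tilde_g),      s_tilde_g^2 = (d0 s0^2 + d s_g^2)/(d0 + d)

with ``u`` the unscaled coefficient standard deviation from the design and
``d`` the residual degrees of freedom; p-values use a t-distribution on
``d0 + d`` degrees of freedom and are corrected by Benjamini–Hochberg.

Cell-type-specific differential methylation uses the fraction × disease
interaction model: with cell-type fractions ``f_k`` summing to one per
sample, fit  ``beta ~ sum_k f_k + sum_k f_k * case``  without a global
intercept; the interaction coefficients estimate the within-cell-type
disease effect and are tested per cell type.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

FRACTION_SUM_TOL = 1e-6


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


@dataclass
class VariancePrior:
    """Fitted scaled-inverse-chi-square prior on residual variances."""

    df_prior: float  # d0; may be inf
    var_prior: float  # s0^2


def fit_variance_prior(s2: np.ndarray, df_resid: float) -> VariancePrior:
    """Moments-matching fit of (d0, s0^2) on log residual variances.

    Genes with zero residual variance are excluded from estimation.  With
    fewer than 10 informative genes the fit is unreliable; the caller falls
    back to ordinary t in that case.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if len(s2) < 2:
        return VariancePrior(df_prior=0.0, var_prior=float(np.mean(s2)) if len(s2) else 1.0)
    d = df_resid
    e = np.log(s2) - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, d / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(emean)
    return VariancePrior(df_prior=float(d0), var_prior=float(s0_sq))


def _squeeze_var(s2: np.ndarray, df_resid: float, prior: VariancePrior) -> np.ndarray:
    if not np.isfinite(prior.df_prior):
        return np.full_like(s2, prior.var_prior)
    if prior.df_prior == 0:
        return s2
    return (prior.df_prior * prior.var_prior + df_resid * s2) / (
        prior.df_prior + df_resid
    )


def _ols_sweep(Y: np.ndarray, X: np.ndarray):
    """OLS of every row of Y (genes × samples) on shared design X.

    Returns (coef, s2, stdev_unscaled, df_resid); coef is genes × p.
    """
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    df_resid = n - p
    if df_resid <= 0:
        raise ValueError(f"zero residual degrees of freedom (n={n}, p={p})")
    xtx_inv = np.linalg.inv(X.T @ X)
    coef = Y @ X @ xtx_inv  # genes × p
    resid = Y - coef @ X.T
    s2 = np.einsum("ij,ij->i", resid, resid) / df_resid
    stdev_unscaled = np.sqrt(np.diag(xtx_inv))
    return coef, s2, stdev_unscaled, df_resid


def moderated_t(
    matrix: pd.DataFrame,
    groups: pd.Series,
    covariates: pd.DataFrame | None = None,
    cnv: pd.DataFrame | None = None,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated t-statistics of group effect per gene.

    Parameters
    ----------
    matrix
        genes × samples measurements (promoter betas or log expression).
    groups
        per-sample labels; must contain exactly two levels, the
        lexicographically larger one (e.g. ``case`` vs ``normal`` ordered by
        the convention normal=0/case=1) is coded 1.  Pass a Series of
        {"normal", "case"} or {0, 1}.
    covariates
        samples × covariate values (e.g. epithelial and fibroblast
        fractions), added to the design.
    cnv
        optional genes × samples per-gene copy-number covariate; triggers a
        per-gene design.
    prior_df
        None → estimate d0 by moments; 0 → ordinary (unmoderated) t.

    Returns
    -------
    DataFrame indexed by gene with columns t, p, fdr, coef, df_total.
    """
    samples = matrix.columns
    g = _encode_groups(groups.reindex(samples))
    counts = pd.Series(g).value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("need >=2 samples in each of two groups")

    cols = [np.ones(len(samples)), g.astype(float)]
    names = ["intercept", "group"]
    if covariates is not None:
        cov = covariates.reindex(samples)
        if cov.isna().any().any():
            raise ValueError("covariates missing for some samples")
        for c in cov.columns:
            cols.append(cov[c].to_numpy(dtype=float))
            names.append(str(c))
    X = np.column_stack(cols)
    Y = matrix.to_numpy(dtype=float)

    if cnv is None:
        coef_all, s2, stdev_unscaled, df_resid = _ols_sweep(Y, X)
        coef = coef_all[:, 1]
        u = stdev_unscaled[1]
        u_vec = np.full(len(coef), u)
    else:
        cnv = cnv.reindex(index=matrix.index, columns=samples)
        if cnv.isna().any().any():
            raise ValueError("CNV covariate missing for some genes/samples")
        coef = np.empty(len(matrix))
        s2 = np.empty(len(matrix))
        u_vec = np.empty(len(matrix))
        df_arr = np.empty(len(matrix))
        C = cnv.to_numpy(dtype=float)
        for i in range(len(matrix)):
            # a constant CNV row carries no information; drop it so the
            # fit reduces exactly to the unadjusted model
            Xi = X if np.ptp(C[i]) == 0 else np.column_stack([X, C[i]])
            ci, s2i, ui, df_i = _ols_sweep(Y[i][None, :], Xi)
            coef[i], s2[i], u_vec[i], df_arr[i] = ci[0, 1], s2i[0], ui[1], df_i
        df_resid = float(np.median(df_arr))

    if prior_df is None:
        if len(matrix) < 10:
            warnings.warn(
                "fewer than 10 genes: falling back to ordinary t", stacklevel=2
            )
            prior = VariancePrior(df_prior=0.0, var_prior=1.0)
        else:
            prior = fit_variance_prior(s2, df_resid)
    elif prior_df == 0:
        prior = VariancePrior(df_prior=0.0, var_prior=1.0)
    else:
        prior = VariancePrior(
            df_prior=float(prior_df),
            var_prior=fit_variance_prior(s2, df_resid).var_prior,
        )

    s2_post = _squeeze_var(s2, df_resid, prior)
    df_total = df_resid + (prior.df_prior if np.isfinite(prior.df_prior) else 1e6)

    constant = s2_post <= 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} gene(s) with zero residual variance; "
            "t set to 0, p to 1",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(constant, 0.0, coef / (u_vec * np.sqrt(s2_post)))
    p = np.where(constant, 1.0, 2.0 * stats.t.sf(np.abs(t), df_total))
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"t": t, "p": p, "fdr": fdr, "coef": coef, "df_total": df_total},
        index=matrix.index,
    )


def _encode_groups(groups: pd.Series) -> np.ndarray:
    if groups.isna().any():
        raise ValueError("group label missing for some samples")
    vals = groups.unique()
    if set(vals) <= {0, 1}:
        return groups.to_numpy(dtype=float)
    if set(vals) == {"normal", "case"}:
        return (groups == "case").to_numpy(dtype=float)
    if len(vals) != 2:
        raise ValueError(f"expected two group levels, got {list(vals)}")
    # deterministic: lexicographically larger level coded 1
    hi = sorted(map(str, vals))[1]
    return (groups.astype(str) == hi).to_numpy(dtype=float)


def compute_gene_stats(
    meth: pd.DataFrame,
    expr: pd.DataFrame,
    sheet,
    fractions: pd.DataFrame | None,
    network,
    prior_df: float | None = None,
    fdr_thresh: float = 0.05,
) -> pd.DataFrame:
    """Aligned differential DNAm and expression statistics per network gene.

    The gene universe is the intersection of the network node set with the
    genes measured in both modalities; the two modalities may cover
    different sample sets (fractions are subset per modality).  Columns:
    t_dm, p_dm, dm_fdr, t_de, p_de, de_fdr, dm_sig, de_sig.
    """
    genes = sorted(set(network.nodes()) & set(meth.index) & set(expr.index))
    if not genes:
        raise ValueError("no overlap between network and measured genes")
    n_net = network.number_of_nodes()
    dropped = n_net - len(genes)
    if dropped:
        logger.info("dropped %d network genes missing a modality", dropped)
    if len(genes) < 0.5 * n_net:
        warnings.warn(
            f"only {len(genes)}/{n_net} network genes covered by both "
            "modalities",
            stacklevel=2,
        )

    def _one(matrix):
        sub = matrix.loc[genes]
        samples = sub.columns
        cov = None
        if fractions is not None:
            avail = samples.intersection(fractions.index)
            if len(avail) < len(samples):
                logger.info(
                    "%d samples lack fraction estimates; restricting",
                    len(samples) - len(avail),
                )
                sub = sub[avail]
                samples = avail
            cov = _fraction_covariates(fractions.loc[samples])
        grp = sheet.groups().reindex(samples)
        return moderated_t(sub, grp, covariates=cov, prior_df=prior_df)

    dm = _one(meth)
    de = _one(expr)
    out = pd.DataFrame(
        {
            "t_dm": dm["t"],
            "p_dm": dm["p"],
            "dm_fdr": dm["fdr"],
            "t_de": de["t"],
            "p_de": de["p"],
            "de_fdr": de["fdr"],
        },
        index=pd.Index(genes, name="gene"),
    )
    out["dm_sig"] = out["dm_fdr"] < fdr_thresh
    out["de_sig"] = out["de_fdr"] < fdr_thresh
    return out


def _fraction_covariates(fractions: pd.DataFrame) -> pd.DataFrame:
    """Drop one fraction column (the last) — they sum to one, so including
    all three with an intercept would be collinear."""
    return fractions.iloc[:, :-1]


def cnv_robustness(
    stats_unadj: pd.DataFrame, stats_cnv_adj: pd.DataFrame, genes
) -> pd.DataFrame:
    """Compare unadjusted vs CNV-adjusted t over a gene set.

    Returns the paired t's plus .attrs['pearson_r'] and
    .attrs['sign_concordance'].
    """
    genes = [g for g in genes if g in stats_unadj.index]
    missing = set(genes) - set(stats_cnv_adj.index)
    if missing:
        raise ValueError(f"CNV-adjusted stats missing genes: {sorted(missing)[:5]}")
    a = stats_unadj.loc[genes, "t"].to_numpy()
    b = stats_cnv_adj.loc[genes, "t"].to_numpy()
    out = pd.DataFrame({"t_unadj": a, "t_cnv_adj": b}, index=genes)
    if len(genes) > 1 and np.std(a) > 0 and np.std(b) > 0:
        out.attrs["pearson_r"] = float(np.corrcoef(a, b)[0, 1])
    else:
        out.attrs["pearson_r"] = np.nan
    out.attrs["sign_concordance"] = float(np.mean(np.sign(a) == np.sign(b)))
    return out


def celltype_specific_dmg(
    meth: pd.DataFrame,
    groups: pd.Series,
    fractions: pd.DataFrame,
    fdr_thresh: float = 0.05,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Cell-type-specific differentially methylated genes.

    Interaction model without global intercept:
    ``beta_g ~ sum_k f_k + sum_k f_k * case``.  The interaction coefficient
    for cell type *k* is the disease-associated methylation change within
    that cell type; each is t-tested with empirical-Bayes variance shrinkage
    and BH-corrected across genes per cell type.

    Returns a DataFrame with per-cell-type columns ``coef_<ct>``, ``t_<ct>``,
    ``p_<ct>``, ``fdr_<ct>``, ``sig_<ct>``.
    """
    samples = meth.columns
    fr = fractions.reindex(samples)
    if fr.isna().any().any():
        raise ValueError("fractions missing for some samples")
    if fr.shape[1] < 3:
        raise ValueError("need fractions for >=3 cell types")
    sums = fr.sum(axis=1)
    if (np.abs(sums - 1.0) > FRACTION_SUM_TOL).any():
        bad = sums.index[np.abs(sums - 1.0) > FRACTION_SUM_TOL][0]
        raise ValueError(f"fractions for sample {bad!r} do not sum to 1")
    g = _encode_groups(groups.reindex(samples))

    F = fr.to_numpy(dtype=float)
    X = np.column_stack([F, F * g[:, None]])
    k = fr.shape[1]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "interaction design is rank deficient (fractions constant or "
            "collinear with group)"
        )
    Y = meth.to_numpy(dtype=float)
    coef, s2, stdev_unscaled, df_resid = _ols_sweep(Y, X)

    if prior_df == 0 or len(meth) < 10:
        prior = VariancePrior(df_prior=0.0, var_prior=1.0)
    else:
        prior = fit_variance_prior(s2, df_resid)
    s2_post = _squeeze_var(s2, df_resid, prior)
    df_total = df_resid + (prior.df_prior if np.isfinite(prior.df_prior) else 1e6)

    out = pd.DataFrame(index=meth.index)
    for j, ct in enumerate(fr.columns):
        b = coef[:, k + j]
        u = stdev_unscaled[k + j]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(s2_post > 0, b / (u * np.sqrt(s2_post)), 0.0)
        p = np.where(s2_post > 0, 2.0 * stats.t.sf(np.abs(t), df_total), 1.0)
        fdr = multipletests(p, method="fdr_bh")[1]
        out[f"coef_{ct}"] = b
        out[f"t_{ct}"] = t
        out[f"p_{ct}"] = p
        out[f"fdr_{ct}"] = fdr
        out[f"sig_{ct}"] = fdr < fdr_thresh
    return out
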