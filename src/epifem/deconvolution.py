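"""Reference-based cell-type deconvolution of DNAm profiles.

A DNAm reference matrix is built from purified cell-type profiles by
one-vs-rest differential methylation: for each cell type, CpGs passing both
an FDR threshold and an absolute difference-in-mean-beta threshold against
the pooled remaining types are selected; the reference value for each marker
CpG is its mean beta within each cell type.

Fractions in a bulk sample are then estimated by robust partial
correlations (RPC): a robust linear regression (Huber loss, tuning constant
1.345) of the sample's betas over the reference CpGs onto the reference
profiles, with intercept; negative coefficients are truncated to zero and
the rest renormalized to sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .diffstats import moderated_t


@dataclass
class ReferenceMatrix:
    """Marker CpGs × cell types mean-beta reference with provenance."""

    values: pd.DataFrame  # cpg × cell type
    provenance: pd.Series  # cpg → comma-joined comparisons that selected it

    @property
    def cell_types(self):
        return list(self.values.columns)

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out["selected_by"] = self.provenance.reindex(out.index)
        out.to_csv(path, index_label="cpg_id")

    @classmethod
    def from_csv(cls, path) -> "ReferenceMatrix":
        df = pd.read_csv(path, index_col=0)
        prov = df.pop("selected_by")
        return cls(values=df, provenance=prov)


def build_reference_matrix(
    pure: pd.DataFrame,
    labels: pd.Series,
    fdr_thresh: float = 0.05,
    delta_thresh: float | dict = 0.9,
) -> ReferenceMatrix:
    """Select marker CpGs from purified profiles and build the reference.

    Parameters
    ----------
    pure
        CpGs × purified samples beta matrix.
    labels
        cell-type label per purified sample; >=2 samples per type, >=3 types.
    fdr_thresh
        BH FDR cutoff for each one-vs-rest comparison.
    delta_thresh
        absolute difference-in-mean-beta cutoff; a scalar, or a dict keyed
        by cell type so individual comparisons can be relaxed (e.g. 0.875
        instead of 0.9 for one comparison).
    """
    labels = labels.reindex(pure.columns)
    if labels.isna().any():
        raise ValueError("cell-type label missing for some purified samples")
    types = sorted(labels.unique())
    if len(types) < 3:
        raise ValueError("need >=3 cell types to build a reference")
    counts = labels.value_counts()
    if counts.min() < 2:
        raise ValueError("need >=2 purified samples per cell type")
    if not isinstance(delta_thresh, dict):
        delta_thresh = {t: float(delta_thresh) for t in types}

    selected: dict[str, list] = {}
    for ct in types:
        is_ct = (labels == ct).astype(int)
        tab = moderated_t(pure, is_ct)
        mean_ct = pure.loc[:, labels == ct].mean(axis=1)
        mean_rest = pure.loc[:, labels != ct].mean(axis=1)
        delta = (mean_ct - mean_rest).abs()
        hits = pure.index[(tab["fdr"] < fdr_thresh) & (delta > delta_thresh[ct])]
        if len(hits) == 0:
            raise ValueError(
                f"comparison {ct!r} vs rest selected 0 CpGs "
                f"(fdr<{fdr_thresh}, |delta|>{delta_thresh[ct]})"
            )
        selected[ct] = list(hits)

    cpgs = sorted(set().union(*selected.values()))
    values = pd.DataFrame(
        {ct: pure.loc[cpgs, labels == ct].mean(axis=1) for ct in types},
        index=pd.Index(cpgs, name="cpg_id"),
    )
    prov = pd.Series(
        {
            cpg: ",".join(ct for ct in types if cpg in set(selected[ct]))
            for cpg in cpgs
        },
        name="selected_by",
    )
    return ReferenceMatrix(values=values, provenance=prov)


def estimate_fractions_rpc(
    beta: pd.DataFrame, ref: ReferenceMatrix, huber_t: float = 1.345
) -> pd.DataFrame:
    """Estimate per-sample cell-type fractions by robust regression.

    Returns samples × cell types fractions in [0,1] summing to 1.
    """
    common = ref.values.index.intersection(beta.index)
    frac_present = len(common) / len(ref.values.index)
    if frac_present < 0.5:
        raise ValueError(
            f"only {frac_present:.0%} of reference CpGs present in data"
        )
    if frac_present < 0.9:
        warnings.warn(
            f"only {frac_present:.0%} of reference CpGs present", stacklevel=2
        )
    X = sm.add_constant(ref.values.loc[common].to_numpy(dtype=float))
    out = {}
    for s in beta.columns:
        y = beta.loc[common, s].to_numpy(dtype=float)
        fit = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=huber_t)).fit()
        w = np.maximum(fit.params[1:], 0.0)
        total = w.sum()
        if total <= 0:
            raise ValueError(f"sample {s!r} not representable by reference")
        out[s] = w / total
    return pd.DataFrame(out, index=ref.cell_types).T.rename_axis("sample_id")
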