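"""Model/Results front-end for the discovery pipeline.

``FEMAnalysis`` bundles the discovery inputs (gene-level promoter
methylation, log expression, sample sheet, gene network and optional
cell-type fractions); ``fit()`` runs cell-fraction-adjusted differential
statistics, integrated-statistic edge weighting and spin-glass module
growth with Monte-Carlo testing, returning a ``FEMResults`` that carries
the per-gene statistics, the modules with their modularities and MC
p-values, and scoring helpers for validation cohorts.
"""

from __future__ import annotations

import pandas as pd

from . import diffstats, modules as mod, scoring
from .io import GeneMethMatrix, SampleSheet
from .modules import SpinGlassConfig, WeightedNetwork


class FEMAnalysis:
    """Functional-epigenetic-module discovery model.

    Parameters
    ----------
    meth
        gene-level promoter betas (GeneMethMatrix or genes × samples frame).
    expr
        genes × samples log expression (sample set may differ from meth).
    sheet
        SampleSheet with normal/case group labels.
    network
        undirected gene network (networkx Graph).
    fractions
        optional samples × cell-type fraction estimates used as covariates.
    config
        SpinGlassConfig for module growth and MC testing.
    """

    def __init__(self, meth, expr, sheet: SampleSheet, network,
                 fractions: pd.DataFrame | None = None,
                 config: SpinGlassConfig | None = None):
        self.meth = meth.values if isinstance(meth, GeneMethMatrix) else meth
        self.expr = expr
        self.sheet = sheet
        self.network = network
        self.fractions = fractions
        self.config = config or SpinGlassConfig()

    @classmethod
    def from_dataframes(cls, meth, expr, groups: pd.Series, network, **kw):
        sheet = SampleSheet(pd.DataFrame({"group": groups}))
        return cls(meth, expr, sheet, network, **kw)

    def fit(self, prior_df: float | None = None) -> "FEMResults":
        stats = diffstats.compute_gene_stats(
            self.meth, self.expr, self.sheet, self.fractions, self.network,
            prior_df=prior_df, fdr_thresh=self.config.fdr_thresh,
        )
        stats = mod.add_integrated_statistic(stats)
        wnet = WeightedNetwork(self.network, stats["t_int"])
        fem_modules = mod.infer_modules(wnet, stats, self.config)
        return FEMResults(self, stats, wnet, fem_modules)


class FEMResults:
    """Fitted module-discovery results."""

    def __init__(self, model: FEMAnalysis, gene_stats: pd.DataFrame,
                 wnet: WeightedNetwork, fem_modules: list):
        self.model = model
        self.gene_stats = gene_stats
        self.weighted_network = wnet
        self.modules = fem_modules

    def summary(self) -> pd.DataFrame:
        """Per-module table: seed, size, modularity, MC p and flag counts."""
        rows = []
        for i, m in enumerate(self.modules):
            f = m.flags
            rows.append(
                {
                    "module_id": f"M{i + 1}",
                    "seed": m.seed,
                    "size": m.size,
                    "modularity": m.modularity,
                    "mc_p": m.mc_p,
                    "n_DM": int(f["DM"].sum()) if f is not None else 0,
                    "n_DR": int(f["DR"].sum()) if f is not None else 0,
                    "n_DM_DR": int(f["DM_DR"].sum()) if f is not None else 0,
                    "n_anticorrelated": int(f["anticorrelated"].sum())
                    if f is not None
                    else 0,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "module_id", "seed", "size", "modularity", "mc_p",
                "n_DM", "n_DR", "n_DM_DR", "n_anticorrelated",
            ],
        )

    def signatures(self, modality: str = "dnam",
                   anticorrelated_only: bool = False) -> list:
        """Discovery signatures (per-gene signs) for every module."""
        sigs = []
        for i, m in enumerate(self.modules):
            try:
                sigs.append(
                    scoring.signature_from_stats(
                        m.members, self.gene_stats, modality=modality,
                        module_id=f"M{i + 1}",
                        fdr_thresh=self.model.config.fdr_thresh,
                        anticorrelated_only=anticorrelated_only,
                    )
                )
            except ValueError:
                continue
        return sigs

    def score_cohort(self, matrix: pd.DataFrame, normal_ids,
                     modality: str = "dnam", offset: float = 0.0) -> pd.DataFrame:
        """Signed-average module scores for an independent cohort."""
        z = scoring.zscore_vs_normals(matrix, normal_ids, offset=offset)
        frames = []
        for sig in self.signatures(modality=modality):
            if len(sig.signs.index.intersection(z.index)) == 0:
                continue
            frames.append(scoring.fem_score_signed(z, sig))
        if not frames:
            raise ValueError("no module scoreable in this cohort")
        return pd.concat(frames, ignore_index=True)
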