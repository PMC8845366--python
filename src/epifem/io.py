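"""Readers, writers and gene-level promoter summarization.

Matrices are probe/gene × sample tables (TSV or CSV, gzip transparent).
Probe annotations map Illumina-style probes to gene symbols and promoter
region classes (TSS200, 1stExon, TSS1500); DNAm is summarized to genes with
strict region precedence: TSS200 probes if any exist, else 1stExon probes,
else TSS1500 probes, averaging within the chosen class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Promoter region classes in strict precedence order.
REGION_PRECEDENCE = ("TSS200", "1stExon", "TSS1500")

_REGION_ALIASES = {
    "TSS200": "TSS200",
    "1STEXON": "1stExon",
    "FIRSTEXON": "1stExon",
    "1ST_EXON": "1stExon",
    "TSS1500": "TSS1500",
}


class ValidationError(ValueError):
    """Raised when an input file violates a declared invariant."""


@dataclass
class ProbeAnnotation:
    """Probe → gene mapping with promoter region class.

    One row per (probe, gene) pair; a probe annotated to several genes
    appears once per gene and contributes to each independently.
    """

    table: pd.DataFrame  # columns: probe_id, gene, region_class

    def __post_init__(self) -> None:
        required = {"probe_id", "gene", "region_class"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"annotation missing columns: {sorted(missing)}")
        norm = (
            self.table["region_class"]
            .astype(str)
            .str.upper()
            .map(_REGION_ALIASES)
        )
        if norm.isna().any():
            bad = self.table.loc[norm.isna(), "region_class"].unique()[:5]
            raise ValidationError(f"unknown region_class values: {list(bad)}")
        self.table = self.table.assign(region_class=norm.values)

    @property
    def genes(self) -> np.ndarray:
        return self.table["gene"].unique()


@dataclass
class SampleSheet:
    """Per-sample group labels (and optional ordered stage / CNV covariates)."""

    table: pd.DataFrame  # index: sample_id; columns: group [, stage]
    cnv: pd.DataFrame | None = None  # genes × samples, optional

    def __post_init__(self) -> None:
        if "group" not in self.table.columns:
            raise ValidationError("sample sheet requires a 'group' column")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def groups(self) -> pd.Series:
        return self.table["group"]


def _read_table(path) -> pd.DataFrame:
    sep = "," if str(path).rstrip(".gz").endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def read_beta_matrix(path) -> pd.DataFrame:
    """Read a probe × sample DNAm beta matrix and validate it.

    Values must lie in [0, 1] with no missing entries; probe ids must be
    unique.  Returns a probes × samples DataFrame.
    """
    df = _read_table(path)
    return validate_beta_matrix(df)


def validate_beta_matrix(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique()[:5]
        raise ValidationError(f"duplicate probe ids: {list(dups)}")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise ValidationError(
            f"missing beta for probe {df.index[r]!r}, sample {df.columns[c]!r}; "
            "impute upstream before loading"
        )
    bad = (values < 0) | (values > 1)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValidationError(
            f"beta value {values[r, c]} out of [0,1] at probe "
            f"{df.index[r]!r}, sample {df.columns[c]!r}"
        )
    return df.astype(float)


def read_expr_matrix(path) -> pd.DataFrame:
    """Read a gene × sample log-expression matrix (finite values required)."""
    df = _read_table(path).astype(float)
    if not np.isfinite(df.to_numpy()).all():
        raise ValidationError("expression matrix contains non-finite values")
    if df.index.has_duplicates:
        raise ValidationError("duplicate gene ids in expression matrix")
    return df


def read_probe_annotation(path) -> ProbeAnnotation:
    sep = "," if str(path).rstrip(".gz").endswith(".csv") else "\t"
    return ProbeAnnotation(pd.read_csv(path, sep=sep))


def read_sample_sheet(path, cnv_path=None) -> SampleSheet:
    cnv = _read_table(cnv_path) if cnv_path is not None else None
    return SampleSheet(_read_table(path), cnv=cnv)


def read_network(path) -> nx.Graph:
    """Read an undirected gene network from a 2-column edge list.

    A 3-column SIF dialect (gene, interaction, gene) is accepted with the
    middle column ignored.  Self-loops are dropped and duplicate edges
    collapsed; counts of both are logged.
    """
    edges = []
    n_self = 0
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for line_no, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 2:
                raise ValidationError(
                    f"{path}:{line_no}: expected >=2 columns, got {len(parts)}"
                )
            a, b = (parts[0], parts[2]) if len(parts) >= 3 else (parts[0], parts[1])
            if a == b:
                n_self += 1
                continue
            edges.append((a, b))
    g = nx.Graph()
    g.add_edges_from(edges)
    if n_self:
        logger.info("dropped %d self-loops", n_self)
    if g.number_of_edges() == 0:
        logger.warning("network %s has no edges", path)
    return g


def write_network(g: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{a}\t{b}\n")


def write_matrix(df: pd.DataFrame, path, index_label: str = "id") -> None:
    sep = "," if str(path).rstrip(".gz").endswith(".csv") else "\t"
    df.to_csv(path, sep=sep, index_label=index_label)


@dataclass
class GeneMethMatrix:
    """Gene-level promoter methylation with summarization provenance."""

    values: pd.DataFrame  # genes × samples, betas in [0,1]
    provenance: pd.DataFrame = field(default=None)  # gene, region_class, n_probes


def summarize_promoter_methylation(
    beta: pd.DataFrame, annotation: ProbeAnnotation
) -> GeneMethMatrix:
    """Summarize probe betas to one promoter value per gene.

    For each gene the mean is taken over its TSS200 probes present in the
    matrix; if the gene has none, over its 1stExon probes; if none of those
    either, over its TSS1500 probes.  Genes with no annotated probe in the
    matrix are omitted.
    """
    ann = annotation.table
    ann = ann[ann["probe_id"].isin(beta.index)]
    if ann.empty:
        raise ValidationError("annotation covers no probe of the beta matrix")

    rows, prov = [], []
    for gene, sub in ann.groupby("gene", sort=True):
        for region in REGION_PRECEDENCE:
            probes = sub.loc[sub["region_class"] == region, "probe_id"]
            if len(probes):
                rows.append(
                    pd.Series(
                        beta.loc[probes].mean(axis=0), name=gene
                    )
                )
                prov.append((gene, region, len(probes)))
                break
    values = pd.DataFrame(rows)
    values.index.name = "gene"
    provenance = pd.DataFrame(
        prov, columns=["gene", "region_class", "n_probes"]
    ).set_index("gene")
    return GeneMethMatrix(values=values, provenance=provenance)
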