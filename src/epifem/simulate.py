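"""Synthetic data with known ground truth for the whole pipeline.

The generator emulates the statistical structure the method assumes:

* a scale-free (preferential-attachment) gene network with planted
  connected modules whose internal edges are densified;
* case/control cohorts whose observed promoter betas are cell-type
  mixtures (epithelial / fibroblast / immune) with Dirichlet fractions,
  planted modules deregulated in the epithelial compartment only, with
  promoter DNAm and expression shifted in opposite directions
  (anti-correlated deregulation); betas are kept in (0,1) by adding noise
  on the logit scale; gene betas are exploded to Illumina-style probes
  (2 TSS200 + 1 1stExon + 1 TSS1500 by default) to exercise the
  summarization precedence;
* purified cell-type profiles with planted marker CpGs at a large beta
  difference;
* saliva-like staged cohorts whose epithelial fraction rises with disease
  stage and where one designated module shifts with stage in the
  epithelial compartment;
* dropout-laden single-cell log-expression for four simulated patients.

Everything is deterministic under a fixed ``rng_seed``; per-operation
child generators keep the streams independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import ProbeAnnotation, SampleSheet

CELL_TYPES = ("epithelial", "fibroblast", "immune")
STAGES = ("N", "NDBE", "HGD", "C")


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic benchmark (defaults are the
    reference conditions used throughout the tests)."""

    rng_seed: int = 0
    # network
    n_genes: int = 1000
    attachment: int = 3  # preferential-attachment edges per new node
    module_sizes: tuple = (15, 20, 30)
    module_density: float = 0.35  # internal edge density of planted modules
    # effects
    delta_beta: float = 0.3  # epithelial-compartment DNAm shift in cases
    log_fc: float = 1.0  # expression shift magnitude in cases
    anticorrelated: bool = True
    # cohort
    n_cases: int = 50
    n_controls: int = 50
    dirichlet_alpha: tuple = (4.0, 2.0, 2.0)
    fixed_fractions: tuple | None = None  # overrides Dirichlet when set
    beta_noise_sd: float = 0.05  # beta-scale SD, realized logit-normally
    expr_noise_sd: float = 0.5
    probe_jitter_sd: float = 0.02
    probes_per_gene: tuple = (("TSS200", 2), ("1stExon", 1), ("TSS1500", 1))
    include_marker_cpgs: bool = True
    with_cnv: bool = False
    # purified profiles
    n_per_type: int = 6
    markers_per_type: int = 50
    n_background_cpgs: int = 500
    marker_high: float = 0.975
    marker_low: float = 0.025
    pure_noise_sd: float = 0.02
    # saliva
    stage_sizes: tuple = (65, 33, 14, 51)
    stage_epi_base: float = 0.15
    stage_epi_slope: float = 0.07  # epithelial-fraction increase per stage
    saliva_delta_beta: float = 0.25  # full-stage epithelial DNAm shift
    # single cell
    n_patients: int = 4
    normal_cells_per_patient: int = 112
    be_cells_per_patient: int = 147
    dropout: float = 0.6
    scrna_effect: float = 1.5

    def validate(self) -> None:
        if self.n_genes < 50:
            raise ValueError("n_genes must be >= 50")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("planted module sizes exceed n_genes")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0,1)")


@dataclass
class GroundTruth:
    """Everything needed to score recovery without re-reading the config."""

    modules: list = field(default_factory=list)  # list of gene lists
    module_directions: list = field(default_factory=list)  # +1 hyper / -1 hypo
    effects: pd.DataFrame | None = None  # gene -> delta_beta, log_fc
    fractions: pd.DataFrame | None = None  # samples × cell types
    marker_cpgs: dict | None = None  # cell type -> list of CpG ids

    def to_json_dict(self) -> dict:
        return {
            "modules": [list(m) for m in self.modules],
            "module_directions": list(self.module_directions),
            "effects": self.effects.to_dict() if self.effects is not None else None,
            "fractions": self.fractions.to_dict() if self.fractions is not None else None,
            "marker_cpgs": self.marker_cpgs,
        }


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.rng_seed), stream])


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def simulate_network(cfg: SimulationConfig) -> tuple[nx.Graph, GroundTruth]:
    """Preferential-attachment network with planted densified modules."""
    cfg.validate()
    rng = _rng(cfg, 1)
    g = nx.barabasi_albert_graph(
        cfg.n_genes, cfg.attachment, seed=int(rng.integers(2**31))
    )
    names = _gene_names(cfg.n_genes)
    g = nx.relabel_nodes(g, dict(enumerate(names)))

    blocked: set = set()  # planted members plus a 1-hop buffer, so planted
    modules = []          # modules are node-disjoint AND non-adjacent
    order = sorted(g.nodes())
    for size in cfg.module_sizes:
        # BFS from a random unblocked start to carve a connected subset
        for _ in range(200):
            start = order[int(rng.integers(len(order)))]
            if start in blocked:
                continue
            members, frontier = [start], [start]
            seen = {start}
            while frontier and len(members) < size:
                node = frontier.pop(0)
                for nb in sorted(g.neighbors(node)):
                    if nb not in seen and nb not in blocked and len(members) < size:
                        seen.add(nb)
                        members.append(nb)
                        frontier.append(nb)
            if len(members) == size:
                break
        else:
            raise RuntimeError("could not carve a connected planted module")
        blocked.update(members)
        for m in members:
            blocked.update(g.neighbors(m))
        # densify internal edges up to the target density, connecting the
        # least-internally-connected pairs first so the module is an evenly
        # knit hotspot rather than two dense halves joined by a thin bridge
        target = int(cfg.module_density * size * (size - 1) / 2)
        mset = set(members)
        indeg = {m: sum(1 for nb in g.neighbors(m) if nb in mset) for m in members}
        current = sum(indeg.values()) // 2
        for _ in range(max(0, target - current)):
            pairs = [
                (a, b)
                for i, a in enumerate(members)
                for b in members[i + 1:]
                if not g.has_edge(a, b)
            ]
            if not pairs:
                break
            key = rng.random(len(pairs))
            best = min(
                range(len(pairs)),
                key=lambda k: (indeg[pairs[k][0]] + indeg[pairs[k][1]], key[k]),
            )
            a, b = pairs[best]
            g.add_edge(a, b)
            indeg[a] += 1
            indeg[b] += 1
        modules.append(sorted(members))

    truth = GroundTruth(
        modules=modules,
        module_directions=[1 if i % 2 == 0 else -1 for i in range(len(modules))],
    )
    return g, truth


def _beta_noise(rng, mean_beta: np.ndarray, sd_beta: float) -> np.ndarray:
    """Logit-normal noise with an approximate beta-scale SD (delta method)."""
    if sd_beta == 0:
        return mean_beta
    m = np.clip(mean_beta, 1e-4, 1 - 1e-4)
    sd_logit = np.minimum(sd_beta / (m * (1 - m)), 3.0)
    return expit(logit(m) + rng.normal(0.0, 1.0, m.shape) * sd_logit)


def simulate_cohort(net: nx.Graph, truth: GroundTruth, cfg: SimulationConfig) -> dict:
    """Case/control cohort: probe-level DNAm mixture + expression.

    Returns dict with keys beta (probes × samples), annotation, expr
    (genes × samples), sheet, fractions (true, samples × cell types), cnv
    (or None), and updates ``truth`` with effects and fractions.
    """
    cfg.validate()
    rng = _rng(cfg, 2)
    genes = sorted(net.nodes())
    n_s = cfg.n_controls + cfg.n_cases
    samples = [f"N{i:03d}" for i in range(cfg.n_controls)] + [
        f"C{i:03d}" for i in range(cfg.n_cases)
    ]
    is_case = np.array([0] * cfg.n_controls + [1] * cfg.n_cases)

    if cfg.fixed_fractions is not None:
        fr = np.tile(np.asarray(cfg.fixed_fractions, dtype=float), (n_s, 1))
    else:
        fr = rng.dirichlet(cfg.dirichlet_alpha, size=n_s)
    fractions = pd.DataFrame(fr, index=samples, columns=list(CELL_TYPES))

    # per-gene, per-cell-type baseline betas (logit-normal around 0.25)
    base_logit = rng.normal(logit(0.25), 1.0, size=len(genes))
    ct_offsets = rng.normal(0.0, 0.5, size=(len(genes), len(CELL_TYPES)))
    beta_ct = expit(base_logit[:, None] + ct_offsets)  # genes × cell types
    _midrange_planted_baselines(beta_ct, genes, truth, rng)

    # planted effects: epithelial compartment only, anti-correlated expression
    delta = pd.Series(0.0, index=genes)
    lfc = pd.Series(0.0, index=genes)
    for members, direction in zip(truth.modules, truth.module_directions):
        delta.loc[members] = direction * cfg.delta_beta
        lfc.loc[members] = (
            -direction * cfg.log_fc if cfg.anticorrelated else direction * cfg.log_fc
        )
    truth.effects = pd.DataFrame({"delta_beta": delta, "log_fc": lfc})
    truth.fractions = fractions

    epi = beta_ct[:, 0][:, None] + delta.to_numpy()[:, None] * is_case[None, :]
    epi = np.clip(epi, 0.01, 0.99)
    mean_beta = (
        fr[:, 0][None, :] * epi
        + fr[:, 1][None, :] * beta_ct[:, 1][:, None]
        + fr[:, 2][None, :] * beta_ct[:, 2][:, None]
    )
    gene_beta = _beta_noise(rng, mean_beta, cfg.beta_noise_sd)

    # explode to probes with region classes and probe-level jitter
    probe_rows, ann_rows, probe_ids = [], [], []
    for gi, gene in enumerate(genes):
        k = 0
        for region, count in cfg.probes_per_gene:
            for _ in range(count):
                pid = f"{gene}_p{k}"
                probe_ids.append(pid)
                ann_rows.append((pid, gene, region))
                probe_rows.append(
                    _beta_noise(rng, gene_beta[gi], cfg.probe_jitter_sd)
                )
                k += 1
    beta = pd.DataFrame(probe_rows, index=probe_ids, columns=samples)
    annotation = ProbeAnnotation(
        pd.DataFrame(ann_rows, columns=["probe_id", "gene", "region_class"])
    )

    if cfg.include_marker_cpgs:
        marker_beta, marker_truth = _marker_cpg_mixture(rng, fr, cfg)
        marker_beta.columns = samples
        beta = pd.concat([beta, marker_beta])
        truth.marker_cpgs = marker_truth

    # expression: baseline + case effect + Gaussian noise
    expr_base = rng.normal(5.0, 1.0, size=len(genes))
    expr = (
        expr_base[:, None]
        + lfc.to_numpy()[:, None] * is_case[None, :]
        + rng.normal(0.0, cfg.expr_noise_sd, size=(len(genes), n_s))
    )
    expr = pd.DataFrame(expr, index=genes, columns=samples)

    sheet = SampleSheet(
        pd.DataFrame(
            {"group": np.where(is_case == 1, "case", "normal")}, index=samples
        )
    )
    cnv = None
    if cfg.with_cnv:
        cnv = pd.DataFrame(
            rng.normal(0.0, 1.0, size=(len(genes), n_s)),
            index=genes,
            columns=samples,
        )
    return {
        "beta": beta,
        "annotation": annotation,
        "expr": expr,
        "sheet": sheet,
        "fractions": fractions,
        "cnv": cnv,
    }


def _midrange_planted_baselines(beta_ct, genes, truth: GroundTruth, rng) -> None:
    """Give planted genes mid-range epithelial baselines (in place).

    A planted shift of ±delta_beta must be realizable without hitting the
    [0,1] boundary; promoters whose methylation actually changes in disease
    sit away from the extremes, so planted genes draw their epithelial
    baseline from U(0.35, 0.55).
    """
    if not truth.modules:
        return
    pos = {g: i for i, g in enumerate(genes)}
    planted = sorted(set().union(*(set(m) for m in truth.modules)))
    idx = [pos[g] for g in planted]
    beta_ct[idx, 0] = rng.uniform(0.35, 0.55, size=len(idx))


def _marker_archetypes(cfg: SimulationConfig) -> pd.DataFrame:
    """Mean beta of each marker CpG in each cell type.

    Half of each type's markers are hypermethylated in their own type and
    hypomethylated in the rest, the other half the reverse (as in real
    array references); per-CpG extremes jitter around
    (marker_high, marker_low), keeping the reference well conditioned.
    """
    rng = _rng(cfg, 6)  # fixed stream: identical across cohort/pure calls
    span_hi = min(0.995 - cfg.marker_high, 0.01)
    span_lo = min(cfg.marker_low - 0.005, 0.02)
    rows, idx = [], []
    for t, ct in enumerate(CELL_TYPES):
        for i in range(cfg.markers_per_type):
            idx.append(f"cg_{ct}_{i:03d}")
            hi = cfg.marker_high + rng.uniform(-span_hi, span_hi)
            lows = [cfg.marker_low + rng.uniform(-span_lo, span_lo) for _ in range(2)]
            row = []
            for k in range(3):
                row.append(hi if k == t else lows.pop())
            if i % 2 == 1:  # hypomethylated-in-own-type marker
                row = [1.0 - v for v in row]
            rows.append(row)
    return pd.DataFrame(rows, index=idx, columns=list(CELL_TYPES))


def _marker_cpg_mixture(rng, fr: np.ndarray, cfg: SimulationConfig):
    arch = _marker_archetypes(cfg)
    mean = arch.to_numpy() @ fr.T  # cpgs × samples
    vals = np.clip(mean + rng.normal(0.0, cfg.pure_noise_sd, mean.shape), 0.0, 1.0)
    marker_truth = {
        ct: [f"cg_{ct}_{i:03d}" for i in range(cfg.markers_per_type)]
        for ct in CELL_TYPES
    }
    return pd.DataFrame(vals, index=arch.index), marker_truth


def simulate_pure_profiles(cfg: SimulationConfig):
    """Purified cell-type profiles with planted marker CpGs.

    Returns (beta, labels, truth): CpGs × purified samples, per-sample cell
    type labels, and a GroundTruth listing the planted markers.
    """
    if cfg.n_per_type < 2:
        raise ValueError("need >=2 samples per cell type")
    rng = _rng(cfg, 3)
    arch = _marker_archetypes(cfg)
    bg = pd.DataFrame(
        np.tile(rng.uniform(0.2, 0.8, size=cfg.n_background_cpgs)[:, None], 3),
        index=[f"cg_bg_{i:04d}" for i in range(cfg.n_background_cpgs)],
        columns=list(CELL_TYPES),
    )
    profile = pd.concat([arch, bg])
    cols, labels = [], []
    vals = []
    for ct in CELL_TYPES:
        for j in range(cfg.n_per_type):
            cols.append(f"{ct}_{j}")
            labels.append(ct)
            vals.append(
                np.clip(
                    profile[ct].to_numpy()
                    + rng.normal(0.0, cfg.pure_noise_sd, len(profile)),
                    0.0,
                    1.0,
                )
            )
    beta = pd.DataFrame(np.array(vals).T, index=profile.index, columns=cols)
    labels = pd.Series(labels, index=cols, name="cell_type")
    truth = GroundTruth(
        marker_cpgs={
            ct: [f"cg_{ct}_{i:03d}" for i in range(cfg.markers_per_type)]
            for ct in CELL_TYPES
        }
    )
    return beta, labels, truth


def simulate_saliva_cohort(net: nx.Graph, truth: GroundTruth, cfg: SimulationConfig) -> dict:
    """Surrogate-tissue (saliva-like) staged cohort.

    Epithelial fraction rises with disease stage; the first planted module's
    promoter betas shift with stage in the epithelial compartment only.
    Marker CpGs for deconvolution are included in the beta matrix.

    Returns dict with gene_beta (genes × samples, gene-level promoter
    betas), beta (marker CpGs + gene rows), sheet (staged), fractions.
    """
    cfg.validate()
    rng = _rng(cfg, 4)
    genes = sorted(net.nodes())
    samples, stages = [], []
    for stage, n in zip(STAGES, cfg.stage_sizes):
        for i in range(n):
            samples.append(f"{stage}{i:03d}")
            stages.append(stage)
    stage_idx = np.array([STAGES.index(s) for s in stages])

    epi_mean = np.clip(
        cfg.stage_epi_base + cfg.stage_epi_slope * stage_idx, 0.02, 0.9
    )
    conc = 30.0
    fr = np.empty((len(samples), 3))
    for i, em in enumerate(epi_mean):
        rest = 1.0 - em
        alpha = np.array([em, 0.1 * rest, 0.9 * rest]) * conc
        fr[i] = rng.dirichlet(alpha)
    fractions = pd.DataFrame(fr, index=samples, columns=list(CELL_TYPES))

    base_logit = rng.normal(logit(0.25), 1.0, size=len(genes))
    ct_offsets = rng.normal(0.0, 0.5, size=(len(genes), 3))
    beta_ct = expit(base_logit[:, None] + ct_offsets)
    _midrange_planted_baselines(beta_ct, genes, truth, rng)

    module = truth.modules[0] if truth.modules else []
    direction = truth.module_directions[0] if truth.modules else 1
    delta = pd.Series(0.0, index=genes)
    delta.loc[module] = direction * cfg.saliva_delta_beta
    stage_frac = stage_idx / (len(STAGES) - 1)

    epi = beta_ct[:, 0][:, None] + delta.to_numpy()[:, None] * stage_frac[None, :]
    epi = np.clip(epi, 0.01, 0.99)
    mean_beta = (
        fr[:, 0][None, :] * epi
        + fr[:, 1][None, :] * beta_ct[:, 1][:, None]
        + fr[:, 2][None, :] * beta_ct[:, 2][:, None]
    )
    gene_beta = pd.DataFrame(
        _beta_noise(rng, mean_beta, cfg.beta_noise_sd), index=genes, columns=samples
    )
    marker_beta, _ = _marker_cpg_mixture(rng, fr, cfg)
    marker_beta.columns = samples
    beta = pd.concat([marker_beta, gene_beta])

    sheet = SampleSheet(
        pd.DataFrame(
            {
                "group": np.where(stage_idx == 0, "normal", "case"),
                "stage": stages,
            },
            index=samples,
        )
    )
    return {
        "gene_beta": gene_beta,
        "beta": beta,
        "sheet": sheet,
        "fractions": fractions,
        "module": list(module),
        "direction": direction,
    }


def simulate_scrna(genes, signature_genes, cfg: SimulationConfig) -> dict:
    """Single-cell log-expression with planted signature shift and dropout.

    BE-like cells shift the designated signature genes down (promoter
    hypermethylation / underexpression archetype) by ``scrna_effect``;
    entries are zeroed by Bernoulli dropout.

    Returns dict with logexpr (genes × cells), cells (DataFrame: patient,
    tissue), and the effect direction per signature gene.
    """
    cfg.validate()
    rng = _rng(cfg, 5)
    genes = sorted(genes)
    signature_genes = [g for g in signature_genes if g in set(genes)]
    cells, patient, tissue = [], [], []
    for p in range(cfg.n_patients):
        for i in range(cfg.normal_cells_per_patient):
            cells.append(f"P{p + 1}_N_{i:03d}")
            patient.append(f"P{p + 1}")
            tissue.append("normal")
        for i in range(cfg.be_cells_per_patient):
            cells.append(f"P{p + 1}_BE_{i:03d}")
            patient.append(f"P{p + 1}")
            tissue.append("BE")
    is_be = np.array([t == "BE" for t in tissue], dtype=float)

    base = rng.normal(2.0, 0.8, size=len(genes))
    pat_shift = rng.normal(0.0, 0.2, size=cfg.n_patients)
    pat_idx = np.array([int(p[1:]) - 1 for p in patient])
    effect = pd.Series(0.0, index=genes)
    effect.loc[signature_genes] = -cfg.scrna_effect

    x = (
        base[:, None]
        + pat_shift[pat_idx][None, :]
        + effect.to_numpy()[:, None] * is_be[None, :]
        + rng.normal(0.0, 0.6, size=(len(genes), len(cells)))
    )
    x = np.maximum(x, 0.0)
    if cfg.dropout > 0:
        keep = rng.random(x.shape) >= cfg.dropout
        x = x * keep
    logexpr = pd.DataFrame(x, index=genes, columns=cells)
    cell_info = pd.DataFrame({"patient": patient, "tissue": tissue}, index=cells)
    return {"logexpr": logexpr, "cells": cell_info, "effect": effect}


def config_to_dict(cfg: SimulationConfig) -> dict:
    return asdict(cfg)
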