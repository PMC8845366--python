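"""Functional epigenetic module discovery on a gene network.

Each gene carries differential-methylation and differential-expression
t-statistics (t_dm, t_de).  The integrated statistic

    t_int = {H(t_dm) H(-t_de) + H(-t_dm) H(t_de)} * |t_dm - t_de|

(H the Heaviside step with H(0) = 0) is nonnegative and nonzero only when
the two statistics point in opposite directions — the promoter
hypermethylation/underexpression (or hypo/over) pattern the method targets.
Edges are weighted by the mean integrated statistic of their endpoints,

    w_gh = 0.5 * (t_int(g) + t_int(h)),

and modules are grown greedily from high-t_int seed genes by minimizing the
spin-glass Hamiltonian

    E(S) = - sum_{g<h in S} (w_gh - gamma * p_gh),   p_gh = w_g. w_h. / (2W),

where w_g. is the weighted degree, W the total edge weight and gamma the
resolution parameter (default 0.5, which empirically yields modules of
10–100 genes).  At each step the adjacent gene giving the largest energy
decrease is added; growth stops when no addition decreases the energy.
Significance is assessed by Monte-Carlo permutation of the gene statistics
over the network (topology fixed), comparing the module's size-normalized
modularity (-E/|S|) to its permutation null.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)


def integrated_statistic(t_dm: float, t_de: float) -> float:
    """Integrated anti-correlation statistic for one gene.

    Zero when the signs agree or either statistic is zero; otherwise
    |t_dm - t_de|.
    """
    if not (np.isfinite(t_dm) and np.isfinite(t_de)):
        raise ValueError("integrated statistic requires finite inputs")
    h = lambda x: 1.0 if x > 0 else 0.0  # H(0) := 0
    ind = h(t_dm) * h(-t_de) + h(-t_dm) * h(t_de)
    return ind * abs(t_dm - t_de)


def add_integrated_statistic(stats: pd.DataFrame) -> pd.DataFrame:
    """Vectorized t_int column from t_dm / t_de columns."""
    t_dm = stats["t_dm"].to_numpy(dtype=float)
    t_de = stats["t_de"].to_numpy(dtype=float)
    if not (np.isfinite(t_dm).all() and np.isfinite(t_de).all()):
        raise ValueError("non-finite t-statistics")
    opposite = ((t_dm > 0) & (t_de < 0)) | ((t_dm < 0) & (t_de > 0))
    out = stats.copy()
    out["t_int"] = np.where(opposite, np.abs(t_dm - t_de), 0.0)
    return out


@dataclass
class SpinGlassConfig:
    """Parameters of module growth and Monte-Carlo testing."""

    gamma: float = 0.5
    n_seeds: int = 100
    size_min: int = 10
    size_max: int = 100
    mc_runs: int = 1000
    alpha: float = 0.05
    rng_seed: int = 0
    jaccard_dedup: float = 0.5
    fdr_thresh: float = 0.05  # member DM/DR flag threshold
    prune_frac: float = 0.5  # prune bar as fraction of module modularity
    min_stat_frac: float = 0.5  # member t_int bar as fraction of module mean
    merge_overlap: float = 0.5  # overlap coefficient above which fragments merge
    null_calibration: str = "grown"  # "grown" (selection-aware) or "fixed"

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.size_min > self.size_max:
            raise ValueError("size_min > size_max")
        if self.mc_runs < 100:
            raise ValueError("mc_runs must be >= 100")


class WeightedNetwork:
    """Gene network with integrated-statistic edge weights.

    Caches the sparse adjacency, node t_int vector, weighted degrees and
    total weight W for fast energy evaluation.
    """

    def __init__(self, graph: nx.Graph, t_int: pd.Series):
        self.nodes = sorted(graph.nodes())
        self.index = {g: i for i, g in enumerate(self.nodes)}
        missing = [g for g in self.nodes if g not in t_int.index]
        if missing:
            logger.info(
                "%d network genes without statistics get t_int = 0",
                len(missing),
            )
        t = t_int.reindex(self.nodes).fillna(0.0)
        if (t < 0).any():
            raise ValueError("t_int must be nonnegative")
        self.t_int = t.to_numpy(dtype=float)
        self.adj = nx.to_scipy_sparse_array(
            graph, nodelist=self.nodes, format="csr", dtype=float
        )
        self.adj.data[:] = 1.0  # topology only; weights derived from t_int
        self.degree = np.asarray(self.adj.sum(axis=1)).ravel()
        self._refresh()
        self.graph = graph

    def _refresh(self) -> None:
        # w_g. = sum_h w_gh = 0.5 * (deg_g * t_g + sum_{h in N(g)} t_h)
        self.wdegree = 0.5 * (self.degree * self.t_int + self.adj @ self.t_int)
        self.W = 0.5 * float(self.degree @ self.t_int)

    def edge_weight(self, g: str, h: str) -> float:
        return 0.5 * (self.t_int[self.index[g]] + self.t_int[self.index[h]])

    def neighbors(self, g: str):
        i = self.index[g]
        return [self.nodes[j] for j in self.adj.indices[self.adj.indptr[i]:self.adj.indptr[i + 1]]]


@dataclass
class FemModule:
    """A discovered module: connected gene set grown from one seed."""

    seed: str
    members: tuple
    energy: float
    modularity: float
    mc_p: float | None = None
    energy_trace: list = field(default_factory=list)
    flags: pd.DataFrame | None = None

    @property
    def size(self) -> int:
        return len(self.members)


def module_energy(members, wnet: WeightedNetwork, gamma: float) -> float:
    """Full Hamiltonian energy of a gene set (lower = denser/heavier)."""
    idx = []
    for g in members:
        if g not in wnet.index:
            raise ValueError(f"gene {g!r} not in network")
        idx.append(wnet.index[g])
    idx = np.array(sorted(idx), dtype=int)
    if len(idx) < 2:
        return 0.0
    sub = wnet.adj[idx][:, idx]
    t_sub = wnet.t_int[idx]
    indeg = np.asarray(sub.sum(axis=1)).ravel()
    edge_sum = 0.5 * float(indeg @ t_sub)  # sum over internal edges of w_gh
    wd = wnet.wdegree[idx]
    pair_sum = 0.5 * (wd.sum() ** 2 - (wd**2).sum())
    null = gamma * pair_sum / (2.0 * wnet.W) if wnet.W > 0 else 0.0
    return -(edge_sum - null)


def grow_module(seed: str, wnet: WeightedNetwork, cfg: SpinGlassConfig) -> FemModule:
    """Deterministic greedy growth from a seed gene.

    At each step every gene adjacent to the current module is evaluated by
    its incremental energy change and the gene with the largest decrease is
    added (ties broken lexicographically).  Growth stops when the best
    candidate's energy gain no longer raises the size-normalized
    modularity -E/|S|.  Because every edge weight is the average of its
    endpoint statistics, a gene adjacent to a high-statistic member always
    offers *some* energy decrease, so a pure energy-decrease stop would
    flood the network; the modularity bar keeps the module a hotspot of
    high edge-weight density.  Energy still strictly decreases at every
    accepted step.  A post-growth prune pass (bar ``prune_frac`` times the
    modularity) strips low-contribution members admitted early while the
    modularity was still ramping up.
    """
    if seed not in wnet.index:
        raise ValueError(f"seed {seed!r} not in network")
    gamma = cfg.gamma
    W = wnet.W
    members = {seed}
    sum_wdeg = wnet.wdegree[wnet.index[seed]]
    energy = 0.0
    trace = [0.0]
    # boundary gene -> sum of edge weights to current members
    nbr_w = {}
    for h in wnet.neighbors(seed):
        nbr_w[h] = wnet.edge_weight(seed, h)

    while nbr_w:
        best_gene, best_delta = None, np.inf
        for g in sorted(nbr_w):
            i = wnet.index[g]
            null = gamma * wnet.wdegree[i] * sum_wdeg / (2.0 * W) if W > 0 else 0.0
            delta = -(nbr_w[g] - null)
            if delta < best_delta - 1e-15:
                best_gene, best_delta = g, delta
        # accept only if the size-normalized modularity increases:
        # (-E + gain)/(n+1) > -E/n  <=>  gain > current modularity
        bar = -energy / len(members)
        if best_gene is None or -best_delta <= bar or best_delta >= 0:
            break
        members.add(best_gene)
        energy += best_delta
        trace.append(energy)
        sum_wdeg += wnet.wdegree[wnet.index[best_gene]]
        del nbr_w[best_gene]
        for h in wnet.neighbors(best_gene):
            if h in members:
                continue
            nbr_w[h] = nbr_w.get(h, 0.0) + wnet.edge_weight(best_gene, h)

    members = _stat_filter(members, seed, wnet, cfg.min_stat_frac)
    energy = module_energy(members, wnet, gamma)
    members, energy = _prune_module(
        members, seed, wnet, gamma, energy, cfg.prune_frac
    )
    mod = -energy / len(members)
    return FemModule(
        seed=seed,
        members=tuple(sorted(members)),
        energy=energy,
        modularity=mod,
        energy_trace=trace,
    )


def _stat_filter(members: set, seed: str, wnet: WeightedNetwork,
                 frac: float) -> set:
    """Drop members whose own integrated statistic is negligible.

    Because edge weights average the endpoint statistics, a zero-statistic
    gene adjacent to two hot members is energetically indistinguishable
    from a weak genuine member; its own t_int is not.  Members (never the
    seed) with t_int below ``frac`` times the module's mean t_int are
    removed iteratively; the connected component containing the seed is
    returned.
    """
    t = {g: wnet.t_int[wnet.index[g]] for g in members}
    while len(t) > 1:
        mean_t = float(np.mean(list(t.values())))
        drop = [g for g in t if g != seed and t[g] < frac * mean_t]
        if not drop:
            break
        for g in drop:
            del t[g]
    keep = set(t)
    comp = {seed}
    stack = [seed]
    while stack:
        u = stack.pop()
        for h in wnet.neighbors(u):
            if h in keep and h not in comp:
                comp.add(h)
                stack.append(h)
    return comp


def _prune_module(members: set, seed: str, wnet: WeightedNetwork,
                  gamma: float, energy: float, accept_frac: float = 1.0):
    """Local-search refinement after growth.

    Iteratively removes the member whose marginal energy contribution falls
    below ``accept_frac`` times the module's modularity (the mirror image
    of the acceptance rule), never the seed and never disconnecting the
    module.  Strips low-contribution hitchhikers that additions-only growth
    cannot distinguish from weak genuine members.
    """
    W = wnet.W
    while len(members) > 2:
        sum_wdeg = sum(wnet.wdegree[wnet.index[g]] for g in members)
        modularity = -energy / len(members)
        worst, worst_gain = None, accept_frac * modularity
        for v in sorted(members):
            if v == seed:
                continue
            i = wnet.index[v]
            w_in = sum(
                wnet.edge_weight(v, u) for u in wnet.neighbors(v) if u in members
            )
            null = (
                gamma * wnet.wdegree[i] * (sum_wdeg - wnet.wdegree[i]) / (2.0 * W)
                if W > 0
                else 0.0
            )
            gain = w_in - null  # v's contribution to -E
            if gain < worst_gain - 1e-15 and _connected_without(members, v, wnet):
                worst, worst_gain = v, gain
        if worst is None:
            break
        members = members - {worst}
        energy += worst_gain
    return members, energy


def _connected_without(members: set, v: str, wnet: WeightedNetwork) -> bool:
    rest = members - {v}
    start = next(iter(rest))
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for h in wnet.neighbors(u):
            if h in rest and h not in seen:
                seen.add(h)
                stack.append(h)
    return len(seen) == len(rest)


def _module_seed_int(base_seed: int, seed_gene: str) -> int:
    h = hashlib.md5(seed_gene.encode()).hexdigest()
    return (int(base_seed) ^ int(h[:8], 16)) % (2**31)


def mc_significance(
    module: FemModule,
    wnet: WeightedNetwork,
    cfg: SpinGlassConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo p-value for a module's modularity.

    Node statistics are permuted uniformly over the whole network (topology
    fixed), edge weights re-derived, and the module's modularity recomputed
    on its fixed membership; p = (1 + #{modularity >= observed}) /
    (1 + mc_runs).
    """
    if not module.members:
        raise ValueError("empty module")
    if rng is None:
        rng = np.random.default_rng(_module_seed_int(cfg.rng_seed, module.seed))
    idx = np.array(sorted(wnet.index[g] for g in module.members), dtype=int)
    sub = wnet.adj[idx][:, idx]
    indeg = np.asarray(sub.sum(axis=1)).ravel()  # internal degrees, fixed
    deg = wnet.degree
    A = wnet.adj
    size = len(idx)
    gamma = cfg.gamma

    def _modularity(t):
        Wp = 0.5 * float(deg @ t)
        edge_sum = 0.5 * float(indeg @ t[idx])
        if Wp > 0:
            wd = 0.5 * (deg[idx] * t[idx] + (A[idx] @ t))
            pair = 0.5 * (wd.sum() ** 2 - (wd**2).sum())
            null = gamma * pair / (2.0 * Wp)
        else:
            null = 0.0
        return (edge_sum - null) / size  # = -E/|S|

    obs = _modularity(wnet.t_int)
    hits = 0
    t = wnet.t_int
    for _ in range(cfg.mc_runs):
        perm = rng.permutation(len(t))
        if _modularity(t[perm]) >= obs:
            hits += 1
    return (1 + hits) / (1 + cfg.mc_runs)


def _permuted_view(wnet: WeightedNetwork, t_perm: np.ndarray) -> WeightedNetwork:
    """Lightweight WeightedNetwork sharing topology with permuted stats."""
    view = WeightedNetwork.__new__(WeightedNetwork)
    view.nodes = wnet.nodes
    view.index = wnet.index
    view.adj = wnet.adj
    view.degree = wnet.degree
    view.graph = wnet.graph
    view.t_int = t_perm
    view._refresh()
    return view


def null_grown_modularity(
    wnet: WeightedNetwork,
    cfg: SpinGlassConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Selection-aware permutation null for module modularity.

    For each run the node statistics are permuted over the network
    (topology fixed) and a module is *grown* from that permutation's
    top-statistic seed; its modularity is one null draw.  Comparing an
    observed module's modularity to this distribution accounts for the
    fact that observed modules were themselves grown to maximize
    modularity — the fixed-membership permutation test ignores that
    selection and is anti-conservative for grown modules.
    """
    if rng is None:
        rng = np.random.default_rng(int(cfg.rng_seed) % (2**31))
    out = np.empty(cfg.mc_runs)
    t = wnet.t_int
    for r in range(cfg.mc_runs):
        view = _permuted_view(wnet, t[rng.permutation(len(t))])
        seed = view.nodes[int(np.argmax(view.t_int))]
        out[r] = grow_module(seed, view, cfg).modularity
    return out


def annotate_members(module: FemModule, stats: pd.DataFrame, fdr_thresh: float) -> FemModule:
    """Per-member DM / DR / DM&DR / anticorrelated flags from discovery stats."""
    rows = []
    for g in module.members:
        if g in stats.index:
            s = stats.loc[g]
            dm = bool(s["dm_fdr"] < fdr_thresh)
            dr = bool(s["de_fdr"] < fdr_thresh)
            anti = dm and dr and np.sign(s["t_dm"]) == -np.sign(s["t_de"]) != 0
        else:
            dm = dr = anti = False
        rows.append((g, dm, dr, dm and dr, anti))
    module.flags = pd.DataFrame(
        rows, columns=["gene", "DM", "DR", "DM_DR", "anticorrelated"]
    ).set_index("gene")
    return module


def _jaccard(a, b) -> float:
    a, b = set(a), set(b)
    return len(a & b) / len(a | b)


def _merge_fragments(
    grown: list[FemModule], wnet: WeightedNetwork, cfg: SpinGlassConfig
) -> list[FemModule]:
    """Merge grown modules that are fragments of one hotspot.

    Growth from different seeds inside the same hotspot can stop at
    different subsets; modules whose overlap coefficient
    |A∩B|/min(|A|,|B|) exceeds ``merge_overlap`` are clustered
    (transitively), replaced by their pruned union, and the cluster's
    lowest-energy seed is kept as the representative seed.
    """
    # deduplicate identical member sets first
    uniq: dict[tuple, FemModule] = {}
    for m in grown:
        if m.members not in uniq or m.energy < uniq[m.members].energy:
            uniq[m.members] = m
    frags = sorted(uniq.values(), key=lambda m: (m.energy, m.seed))
    n = len(frags)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    sets = [set(m.members) for m in frags]
    for i in range(n):
        for j in range(i + 1, n):
            ov = len(sets[i] & sets[j]) / min(len(sets[i]), len(sets[j]))
            if ov > cfg.merge_overlap:
                parent[find(i)] = find(j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    merged = []
    for idxs in clusters.values():
        rep = min((frags[i] for i in idxs), key=lambda m: (m.energy, m.seed))
        if len(idxs) == 1:
            merged.append(rep)
            continue
        union = set().union(*(sets[i] for i in idxs))
        union = _stat_filter(union, rep.seed, wnet, cfg.min_stat_frac)
        energy = module_energy(union, wnet, cfg.gamma)
        members, energy = _prune_module(
            union, rep.seed, wnet, cfg.gamma, energy, cfg.prune_frac
        )
        merged.append(
            FemModule(
                seed=rep.seed,
                members=tuple(sorted(members)),
                energy=energy,
                modularity=-energy / len(members),
                energy_trace=rep.energy_trace,
            )
        )
    return sorted(merged, key=lambda m: (m.energy, m.seed))


def infer_modules(
    wnet: WeightedNetwork,
    stats: pd.DataFrame,
    cfg: SpinGlassConfig,
) -> list[FemModule]:
    """Full module inference: seed, grow, size-filter, MC-test, deduplicate.

    Seeds are the top ``cfg.n_seeds`` genes by t_int (positive only; ties
    broken lexicographically).  Grown modules outside
    [size_min, size_max] are dropped; survivors are MC-tested and kept at
    mc_p < alpha; overlapping modules (Jaccard > jaccard_dedup) are
    deduplicated keeping the lower-energy one.  Members are annotated with
    DM/DR/DM&DR/anticorrelated flags from the discovery statistics.
    """
    order = sorted(
        (g for g in wnet.nodes if wnet.t_int[wnet.index[g]] > 0),
        key=lambda g: (-wnet.t_int[wnet.index[g]], g),
    )
    seeds = order[: cfg.n_seeds]
    if len(seeds) < cfg.n_seeds:
        logger.info("only %d genes with positive t_int available as seeds", len(seeds))

    grown = [grow_module(s, wnet, cfg) for s in seeds]
    grown = _merge_fragments(grown, wnet, cfg)
    sized = [m for m in grown if cfg.size_min <= m.size <= cfg.size_max]
    logger.info(
        "%d/%d grown modules within size range [%d, %d]",
        len(sized), len(grown), cfg.size_min, cfg.size_max,
    )
    if cfg.null_calibration == "grown":
        null = null_grown_modularity(wnet, cfg) if sized else np.empty(0)
        for m in sized:
            m.mc_p = (1 + int((null >= m.modularity - 1e-12).sum())) / (
                1 + cfg.mc_runs
            )
    else:
        for m in sized:
            m.mc_p = mc_significance(m, wnet, cfg)
    signif = [m for m in sized if m.mc_p < cfg.alpha]

    kept: list[FemModule] = []
    for m in sorted(signif, key=lambda m: (m.energy, m.seed)):
        if all(_jaccard(m.members, k.members) <= cfg.jaccard_dedup for k in kept):
            kept.append(m)
    if not kept:
        logger.info(
            "no significant modules (grown=%d, size-filtered=%d, signif=0)",
            len(grown), len(sized),
        )
    for m in kept:
        annotate_members(m, stats, cfg.fdr_thresh)
    return kept


def modules_to_frame(modules: list[FemModule]) -> pd.DataFrame:
    """Long-format table: module_id, seed, gene and member flags."""
    rows = []
    for i, m in enumerate(modules):
        for g in m.members:
            f = m.flags.loc[g] if m.flags is not None else None
            rows.append(
                {
                    "module_id": f"M{i + 1}",
                    "seed": m.seed,
                    "gene": g,
                    "modularity": m.modularity,
                    "mc_p": m.mc_p,
                    "DM": bool(f["DM"]) if f is not None else False,
                    "DR": bool(f["DR"]) if f is not None else False,
                    "DM_DR": bool(f["DM_DR"]) if f is not None else False,
                    "anticorrelated": bool(f["anticorrelated"]) if f is not None else False,
                }
            )
    return pd.DataFrame(rows)


def write_gmt(modules: list[FemModule], path) -> None:
    with open(path, "w") as fh:
        for i, m in enumerate(modules):
            fh.write("\t".join([f"M{i + 1}_{m.seed}", m.seed, *m.members]) + "\n")
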