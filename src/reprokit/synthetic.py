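"""Seeded synthetic data with planted ground truth.

Emulates the study design the pipeline targets: duplicate donor
fibroblast samples, duplicate samples at 24/48/72 h post-transduction
with progressively growing planted effects, and duplicate iPS-like and
ES-like pluripotent samples; detection p-values coupled to the planted
expressed/unexpressed state; a co-expression compendium with a planted
seed-gene module; and interaction networks with planted source->sink
shortest paths.  Every generator is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .network import InteractionNetwork

DEFAULT_GROUPS = (
    ("donor", 2), ("t24", 2), ("t48", 2), ("t72", 2), ("iPS", 2), ("ES", 2),
)

#: log2 intensity of an expressed probe (population mean) and of background
_EXPRESSED_MEAN = 8.0
_EXPRESSED_SD = 1.5
_BACKGROUND_LEVEL = 5.0


@dataclass(frozen=True)
class SyntheticExpressionSpec:
    """Parameters of the synthetic duplicate-design time course.

    ``effect_log2fc`` is the planted log2 fold change at the first time
    point; each successive time point multiplies it by ``effect_growth``
    (the pluripotent groups carry the final time point's effect).
    ``activation_fractions`` give, per time point, the fraction of the
    planted pluripotency probes already detectable; fibroblast probes
    are switched off at the same pace.  ``emt_probes`` are planted for
    progressive down-regulation with per-state magnitudes
    ``emt_state_effects`` scaled by per-probe ``emt_weights``.
    """

    n_probes: int = 2000
    groups: tuple[tuple[str, int], ...] = DEFAULT_GROUPS
    de_fraction: float = 0.05
    effect_log2fc: float = 1.0
    effect_growth: float = 1.5
    noise_sd: float = 0.25
    pluri_on_genes: int = 100
    fibro_off_genes: int = 100
    activation_fractions: tuple[float, ...] = (0.1, 0.3, 0.6)
    emt_probes: tuple[str, ...] = ()
    emt_state_effects: tuple[float, ...] = (0.3, 0.8, 1.6, 3.0, 3.5)
    emt_weights: tuple[float, ...] = ()
    line_offset_sd: float = 0.0
    probe_ids: tuple[str, ...] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes <= 0:
            raise ValueError("n_probes must be positive")
        if not self.groups:
            raise ValueError("groups must be non-empty")
        for frac in (self.de_fraction, *self.activation_fractions):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if any(b < a for a, b in zip(self.activation_fractions,
                                     self.activation_fractions[1:])):
            raise ValueError("activation_fractions must be non-decreasing")
        if min(self.pluri_on_genes, self.fibro_off_genes) < 0:
            raise ValueError("planted set counts must be >= 0")
        if self.probe_ids and len(self.probe_ids) != self.n_probes:
            raise ValueError("probe_ids length must equal n_probes")
        n_time = len(self.time_groups())
        if len(self.activation_fractions) != n_time:
            raise ValueError("need one activation fraction per time point")
        if self.emt_weights and len(self.emt_weights) != len(self.emt_probes):
            raise ValueError("emt_weights must match emt_probes")

    def donor_group(self) -> str:
        return self.groups[0][0]

    def time_groups(self) -> list[str]:
        return [g for g, _ in self.groups if g.startswith("t")]

    def pluripotent_groups(self) -> list[str]:
        donor = self.donor_group()
        times = set(self.time_groups())
        return [g for g, _ in self.groups if g != donor and g not in times]

    def contrasts(self) -> list[str]:
        return [g for g, _ in self.groups[1:]]


@dataclass
class SyntheticTruth:
    """Ground truth of all plantings, keyed by probe id."""

    de_status: pd.DataFrame            # probe x contrast, "up"/"down"/"null"
    pluripotency_probes: pd.Index
    fibroblast_probes: pd.Index
    expressed: pd.DataFrame            # probe x group planted detection state
    emt_probes: pd.Index = field(default_factory=lambda: pd.Index([]))
    emt_weights: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def _detection_p(rng: np.random.Generator, expressed: np.ndarray) -> np.ndarray:
    """Detection p-values coupled to the planted state: expressed states
    draw Uniform(0, 0.009], unexpressed draw Uniform(0.02, 1)."""
    p = rng.uniform(0.02, 1.0, size=expressed.shape)
    on = rng.uniform(0.0, 0.009, size=expressed.shape)
    return np.where(expressed, np.maximum(on, 1e-12), p)


def simulate_expression(spec: SyntheticExpressionSpec) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate a log2 expression matrix plus its planted ground truth.

    Planted differential probes (half up, half down) differ from the
    donor mean by ``effect_log2fc * effect_growth**i`` at time point *i*;
    pluripotent groups carry the last time point's effect.  Detection
    p-values follow the planted expressed/unexpressed state of each
    probe-group combination.  Identical specs give identical output.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_probes
    probes = pd.Index(spec.probe_ids if spec.probe_ids
                      else [f"P{i:06d}" for i in range(n)], name="probe_id")
    groups_flat: list[str] = []
    samples: list[str] = []
    for g, k in spec.groups:
        for r in range(k):
            groups_flat.append(g)
            samples.append(f"{g}-{chr(ord('a') + r)}")
    group_series = pd.Series(groups_flat, index=samples, name="group")
    group_names = [g for g, _ in spec.groups]
    donor = spec.donor_group()
    times = spec.time_groups()
    pluri_groups = spec.pluripotent_groups()
    contrasts = spec.contrasts()

    for pid in spec.emt_probes:
        if pid not in probes:
            raise ValueError(f"emt probe {pid!r} not among generated probe ids")

    # --- assign probe classes (disjoint) ---------------------------------
    emt_idx = probes.get_indexer(list(spec.emt_probes))
    free = np.setdiff1d(np.arange(n), emt_idx)
    rng.shuffle(free)
    n_pluri, n_fibro = spec.pluri_on_genes, spec.fibro_off_genes
    n_de = int(round(spec.de_fraction * n))
    if n_pluri + n_fibro + n_de > free.size:
        raise ValueError("planted sets exceed available probes")
    pluri_idx = np.sort(free[:n_pluri])
    fibro_idx = np.sort(free[n_pluri:n_pluri + n_fibro])
    de_idx = np.sort(free[n_pluri + n_fibro:n_pluri + n_fibro + n_de])
    up_idx = de_idx[: n_de // 2]
    down_idx = de_idx[n_de // 2:]

    # --- planted detection state per probe x group -----------------------
    expressed = pd.DataFrame(True, index=probes, columns=group_names)
    expressed.iloc[pluri_idx, :] = False
    for g in pluri_groups:
        expressed.iloc[pluri_idx, expressed.columns.get_loc(g)] = True
    expressed.iloc[fibro_idx, :] = False
    expressed.iloc[fibro_idx, expressed.columns.get_loc(donor)] = True
    for t_i, g in enumerate(times):
        col = expressed.columns.get_loc(g)
        k_on = int(round(spec.activation_fractions[t_i] * n_pluri))
        expressed.iloc[pluri_idx[:k_on], col] = True
        k_off = int(round(spec.activation_fractions[t_i] * n_fibro))
        expressed.iloc[fibro_idx[k_off:], col] = True  # first k_off switched off

    # --- planted effects per probe x group (log2 offsets from donor) -----
    delta = pd.DataFrame(0.0, index=probes, columns=group_names)
    n_time = len(times)
    for c_i, g in enumerate(contrasts):
        t_i = times.index(g) if g in times else n_time - 1
        eff = spec.effect_log2fc * spec.effect_growth ** t_i
        delta.iloc[up_idx, delta.columns.get_loc(g)] = eff
        delta.iloc[down_idx, delta.columns.get_loc(g)] = -eff
    if len(spec.emt_probes):
        w = np.asarray(spec.emt_weights if spec.emt_weights
                       else np.ones(len(spec.emt_probes)))
        for c_i, g in enumerate(contrasts):
            delta.iloc[emt_idx, delta.columns.get_loc(g)] -= (
                spec.emt_state_effects[c_i] * w
            )

    # --- assemble intensities -------------------------------------------
    mu = rng.normal(_EXPRESSED_MEAN, _EXPRESSED_SD, size=n)
    intens = np.empty((n, len(samples)))
    detect = np.empty_like(intens)
    line_offsets = {s: (rng.normal(0.0, spec.line_offset_sd)
                        if spec.line_offset_sd > 0 and group_series[s] in pluri_groups
                        else 0.0) for s in samples}
    for j, s in enumerate(samples):
        g = group_series[s]
        on = expressed[g].to_numpy()
        level = np.where(on, mu + delta[g].to_numpy(), _BACKGROUND_LEVEL)
        noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else 0.0
        intens[:, j] = level + noise + line_offsets[s]
        detect[:, j] = _detection_p(rng, on)

    matrix = ExpressionMatrix(
        pd.DataFrame(intens, index=probes, columns=samples),
        pd.DataFrame(detect, index=probes, columns=samples),
        group_series,
    )

    status = pd.DataFrame("null", index=probes, columns=contrasts)
    status.iloc[up_idx, :] = "up"
    status.iloc[down_idx, :] = "down"
    truth = SyntheticTruth(
        de_status=status,
        pluripotency_probes=probes[pluri_idx],
        fibroblast_probes=probes[fibro_idx],
        expressed=expressed,
        emt_probes=probes[np.sort(emt_idx)] if len(emt_idx) else pd.Index([]),
        emt_weights=pd.Series(
            np.asarray(spec.emt_weights if spec.emt_weights else np.ones(len(emt_idx))),
            index=probes[emt_idx]) if len(emt_idx) else pd.Series(dtype=float),
    )
    return matrix, truth


def simulate_compendium(n_genes: int, n_samples: int, seed_module,
                        module_correlation: float, rng_seed: int,
                        gene_ids=None, module_loadings=None) -> pd.DataFrame:
    """Expression compendium with one planted co-expressed module.

    Module genes load on a shared standard-normal latent factor with
    loading sqrt(module_correlation) (or per-gene ``module_loadings``),
    so within-module pairwise correlation is ~module_correlation; genes
    outside the module are independent noise.  Returns genes x samples.
    """
    if not 0.0 <= module_correlation <= 1.0:
        raise ValueError("module_correlation must lie in [0, 1]")
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    rng = np.random.default_rng(rng_seed)
    genes = pd.Index(gene_ids if gene_ids is not None
                     else [f"G{i:05d}" for i in range(n_genes)], name="gene")
    missing = [g for g in seed_module if g not in genes]
    if missing:
        raise ValueError(f"seed module genes not in universe: {missing[:5]}")
    factor = rng.normal(size=n_samples)
    X = rng.normal(size=(n_genes, n_samples))
    pos = genes.get_indexer(list(seed_module))
    if module_loadings is None:
        lam = np.full(len(pos), math.sqrt(module_correlation))
    else:
        lam = np.sqrt(np.asarray(module_loadings, dtype=float))
        if lam.size != len(pos):
            raise ValueError("module_loadings must match seed_module length")
    X[pos, :] = lam[:, None] * factor[None, :] + np.sqrt(1 - lam[:, None] ** 2) * X[pos, :]
    return pd.DataFrame(X, index=genes,
                        columns=[f"S{j:03d}" for j in range(n_samples)])


def simulate_network(n_nodes: int, edge_prob: float, sources, sinks,
                     planted_paths, rng_seed: int,
                     allow_shortcuts: bool = False) -> InteractionNetwork:
    """Random mixed graph with planted source->sink shortest paths.

    Planted path edges are undirected (ppi).  Background ppi edges are
    added independently with probability ``edge_prob`` but (unless
    ``allow_shortcuts``) an edge that would shorten any planted pair's
    shortest distance below the planted path length is rejected.
    """
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError("edge_prob must lie in [0, 1]")
    sources, sinks = list(sources), list(sinks)
    if set(sources) & set(sinks):
        raise ValueError("sources and sinks must be disjoint")
    rng = np.random.default_rng(rng_seed)
    named = list(dict.fromkeys([*sources, *sinks,
                                *[n for p in planted_paths for n in p]]))
    nodes = named + [f"N{i:03d}" for i in range(max(0, n_nodes - len(named)))]
    nodes = nodes[:max(n_nodes, len(named))]
    node_set = set(nodes)
    for path in planted_paths:
        if path[0] not in sources or path[-1] not in sinks:
            raise ValueError(f"planted path endpoints must be declared source/sink: {path}")
        for v in path:
            if v not in node_set:
                raise ValueError(f"planted path references unknown node {v!r}")

    edges: list[tuple[str, str, str]] = []
    seen = set()

    def add(a, b, etype="ppi"):
        key = frozenset((a, b))
        if a != b and key not in seen:
            seen.add(key)
            edges.append((a, etype, b))

    for path in planted_paths:
        for a, b in zip(path, path[1:]):
            add(a, b)

    planted_len = {(p[0], p[-1]): len(p) - 1 for p in planted_paths}
    roles = {**{s: "source" for s in sources}, **{t: "sink" for t in sinks}}
    net = InteractionNetwork.from_edges(edges, roles, nodes=nodes)

    candidates = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]
                  if frozenset((a, b)) not in seen]
    draws = rng.uniform(size=len(candidates))
    for (a, b), u in zip(candidates, draws):
        if u >= edge_prob:
            continue
        trial = InteractionNetwork.from_edges(edges + [(a, "ppi", b)], roles, nodes=nodes)
        if not allow_shortcuts:
            g = trial.traversal_graph()
            import networkx as nx
            shortcut = False
            for (s, t), plen in planted_len.items():
                try:
                    if nx.shortest_path_length(g, s, t) < plen:
                        shortcut = True
                        break
                except nx.NetworkXNoPath:
                    continue
            if shortcut:
                continue
        seen.add(frozenset((a, b)))
        edges.append((a, "ppi", b))
    return InteractionNetwork.from_edges(edges, roles, nodes=nodes)


@dataclass
class EmtScenario:
    """Coordinated EMT fixture: a time course whose planted suppression
    ordering matches the compendium module's co-expression ordering."""

    matrix: ExpressionMatrix
    truth: SyntheticTruth
    compendium: pd.DataFrame
    seeds: list[str]
    module: list[str]


def simulate_emt_timecourse(n_probes: int = 2000, n_seeds: int = 36,
                            n_module_extra: int = 24,
                            loading_range: tuple[float, float] = (0.95, 0.35),
                            weight_range: tuple[float, float] = (1.6, 0.4),
                            n_compendium_samples: int = 200,
                            emt_state_effects: tuple[float, ...] = (0.2, 1.05, 1.7, 2.3, 3.6),
                            noise_sd: float = 0.25,
                            de_fraction: float = 0.12,
                            background_log2fc: float = 1.0,
                            background_growth: float = 1.0,
                            pluri_on_genes: int = 0, fibro_off_genes: int = 0,
                            activation_fractions: tuple[float, ...] = (0.1, 0.3, 0.6),
                            rng_seed: int = 0) -> EmtScenario:
    """Generate a compendium + time course sharing one latent EMT module.

    Module genes get descending latent-factor loadings (so the seed
    ranking orders them by loading) and planted per-state down-regulation
    proportional to the same ordering, making the down-regulation
    ranking progressively converge on the co-expression ranking as the
    planted effects grow over 24/48/72 h and the pluripotent states.
    """
    rng = np.random.default_rng(rng_seed)
    probes = [f"G{i:05d}" for i in range(n_probes)]
    n_module = n_seeds + n_module_extra
    module_idx = rng.choice(n_probes, size=n_module, replace=False)
    module = [probes[i] for i in np.sort(module_idx)]
    loadings = np.linspace(*loading_range, n_module)
    weights = np.linspace(*weight_range, n_module)
    seed_pick = np.sort(rng.choice(n_module, size=n_seeds, replace=False))
    seeds = [module[i] for i in seed_pick]

    compendium = simulate_compendium(
        n_probes, n_compendium_samples, module,
        module_correlation=float(np.mean(loadings)),
        rng_seed=int(rng.integers(2 ** 31)),
        gene_ids=probes, module_loadings=loadings,
    )
    spec = SyntheticExpressionSpec(
        n_probes=n_probes,
        probe_ids=tuple(probes),
        de_fraction=de_fraction,
        effect_log2fc=background_log2fc,
        effect_growth=background_growth,
        noise_sd=noise_sd,
        pluri_on_genes=pluri_on_genes, fibro_off_genes=fibro_off_genes,
        activation_fractions=activation_fractions,
        emt_probes=tuple(module),
        emt_state_effects=emt_state_effects,
        emt_weights=tuple(weights),
        rng_seed=int(rng.integers(2 ** 31)),
    )
    matrix, truth = simulate_expression(spec)
    return EmtScenario(matrix, truth, compendium, seeds, module)
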