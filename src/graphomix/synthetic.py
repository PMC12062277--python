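"""Synthetic multi-omics cohorts with graph-structured correlation.

Generates two-modality cohorts that mimic the structure of brain multi-omics
case/control studies: unequal feature counts, partial sample overlap
(complete samples plus single-modality groups), case:control imbalance, and
a planted subset of predictive features shared across modalities.

Noise model: i.i.d. standard Gaussian node noise diffused one step over the
symmetric-normalized adjacency and mixed with the i.i.d. component at weight
``within_graph_corr``, giving adjacency-linked feature correlation.  Planted
case/control mean shifts are added after smoothing, so only the planted
nodes carry signal.  For complete samples the planted nodes shared between
modalities draw from a common latent at weight ``cross_modality_corr``.

All randomness flows through one generator seeded per call; runs with
identical arguments are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

from .cohort import CohortDataset, write_feature_table, write_metadata
from .priors import ModalityGraphSpec, save_graph

__all__ = ["SimulationConfig", "generate_prior_graph", "generate_cohort",
           "generate_null_cohort", "write_cohort", "DEFAULT_MODALITIES"]

DEFAULT_MODALITIES = ("rna", "protein")


@dataclass(frozen=True)
class SimulationConfig:
    n_samples_complete: int = 300
    n_samples_mod1_only: int = 100
    n_samples_mod2_only: int = 50
    n_nodes_per_modality: tuple[int, int] = (100, 100)
    n_informative: int = 10
    effect_size: float = 2.0
    within_graph_corr: float = 0.4
    cross_modality_corr: float = 0.5
    case_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self):
        counts = (self.n_samples_complete, self.n_samples_mod1_only,
                  self.n_samples_mod2_only, self.n_informative,
                  *self.n_nodes_per_modality)
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.n_informative > min(self.n_nodes_per_modality):
            raise ValueError("n_informative exceeds the smallest modality size")
        for rho in (self.within_graph_corr, self.cross_modality_corr):
            if not (0 <= rho < 1):
                raise ValueError("correlations must lie in [0, 1)")
        if not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must lie in (0, 1)")


def _symbols(n: int) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(n)]


def generate_prior_graph(n_nodes: int, model: str = "scale_free",
                         seed: int = 0) -> ModalityGraphSpec:
    """A simple, undirected, connected prior graph with synthetic symbols.

    Models: ``scale_free`` (preferential attachment, m=2), ``community_sbm``
    (4-block stochastic block model, disconnected components bridged), and
    ``path``.  Deterministic given ``seed``.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if model == "path":
        g = nx.path_graph(n_nodes)
    elif model == "scale_free":
        m = min(2, n_nodes - 1)
        g = nx.barabasi_albert_graph(n_nodes, m, seed=seed)
    elif model == "community_sbm":
        k = min(4, n_nodes)
        sizes = [n_nodes // k] * k
        sizes[0] += n_nodes - sum(sizes)
        p_in, p_out = 0.25, 0.01
        probs = [[p_in if i == j else p_out for j in range(k)] for i in range(k)]
        g = nx.stochastic_block_model(sizes, probs, seed=seed)
        g = nx.Graph(g)  # drop block metadata, keep simple
        comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
        for a, b in zip(comps[:-1], comps[1:]):
            g.add_edge(min(a), min(b))  # bridge components deterministically
    else:
        raise ValueError(f"unknown graph model: {model!r}")
    g.remove_edges_from(nx.selfloop_edges(g))
    mapping = dict(zip(sorted(g.nodes()), _symbols(n_nodes)))
    g = nx.relabel_nodes(g, mapping)
    return ModalityGraphSpec.from_networkx(g, name=f"{model}-{n_nodes}",
                                           node_order=_symbols(n_nodes))


def _smoothed_noise(rng: np.random.Generator, n: int,
                    graph: ModalityGraphSpec, rho: float) -> np.ndarray:
    eta = rng.standard_normal((n, graph.n_nodes))
    if rho == 0:
        return eta
    return (1.0 - rho) * eta + rho * (eta @ graph.normalized_adjacency().T)


def generate_cohort(cfg: SimulationConfig,
                    graphs: dict[str, ModalityGraphSpec] | None = None,
                    modality_names: tuple[str, str] = DEFAULT_MODALITIES,
                    ) -> CohortDataset:
    """Simulate a two-modality cohort; see the module docstring for the model.

    The returned dataset carries the planted feature symbols in the
    ``informative`` attribute (``{modality: [symbols]}``).
    """
    rng = np.random.default_rng(cfg.seed)
    if graphs is None:
        graphs = {
            modality_names[0]: generate_prior_graph(
                cfg.n_nodes_per_modality[0], "scale_free", seed=cfg.seed),
            modality_names[1]: generate_prior_graph(
                cfg.n_nodes_per_modality[1], "scale_free", seed=cfg.seed + 1),
        }
    names = list(graphs)
    if len(names) != 2:
        raise ValueError("exactly two modality graphs are required")
    for name, want in zip(names, cfg.n_nodes_per_modality):
        if graphs[name].n_nodes != want:
            raise ValueError(
                f"graph for {name!r} has {graphs[name].n_nodes} nodes, "
                f"config says {want}")

    n_total = (cfg.n_samples_complete + cfg.n_samples_mod1_only
               + cfg.n_samples_mod2_only)
    labels = (rng.random(n_total) < cfg.case_fraction).astype(int)
    sample_ids = [f"S{i + 1:05d}" for i in range(n_total)]

    group = np.array(
        ["complete"] * cfg.n_samples_complete
        + [f"{names[0]}_only"] * cfg.n_samples_mod1_only
        + [f"{names[1]}_only"] * cfg.n_samples_mod2_only)
    masks = {names[0]: group != f"{names[1]}_only",
             names[1]: group != f"{names[0]}_only"}

    shared = [s for s in graphs[names[0]].feature_ids
              if s in set(graphs[names[1]].feature_ids)]
    pool = shared if len(shared) >= cfg.n_informative else \
        graphs[names[0]].feature_ids
    informative = sorted(rng.choice(pool, size=cfg.n_informative,
                                    replace=False).tolist())

    complete_idx = np.flatnonzero(group == "complete")
    latent = rng.standard_normal((len(complete_idx), cfg.n_informative))

    features, feat_ids = {}, {}
    for name in names:
        g = graphs[name]
        X = _smoothed_noise(rng, n_total, g, cfg.within_graph_corr)
        col = {s: j for j, s in enumerate(g.feature_ids)}
        inf_cols = [col[s] for s in informative if s in col]
        if cfg.cross_modality_corr > 0 and inf_cols:
            rho = cfg.cross_modality_corr
            take = [j for j, s in enumerate(informative) if s in col]
            X[np.ix_(complete_idx, inf_cols)] = (
                np.sqrt(rho) * latent[:, take]
                + np.sqrt(1 - rho) * X[np.ix_(complete_idx, inf_cols)])
        X[:, inf_cols] += cfg.effect_size * labels[:, None]
        X[~masks[name]] = np.nan
        features[name] = X
        feat_ids[name] = list(g.feature_ids)

    import pandas as pd
    meta = pd.DataFrame({"label": labels, "group": group}, index=sample_ids)
    ds = CohortDataset(sample_ids=sample_ids, labels=labels,
                       modality_features=features, modality_masks=masks,
                       feature_ids=feat_ids, metadata=meta)
    ds.informative = {name: [s for s in informative
                             if s in set(feat_ids[name])] for name in names}
    ds.graphs = graphs
    return ds


def generate_null_cohort(cfg: SimulationConfig, graphs=None,
                         modality_names: tuple[str, str] = DEFAULT_MODALITIES,
                         ) -> CohortDataset:
    """Same generative process with the planted effect forced to zero."""
    return generate_cohort(replace(cfg, effect_size=0.0), graphs=graphs,
                           modality_names=modality_names)


def write_cohort(ds: CohortDataset, outdir):
    """Write features/metadata TSVs plus graphs (edge-list TSV and GraphML)."""
    import os
    os.makedirs(outdir, exist_ok=True)
    for name in ds.modalities:
        present = np.flatnonzero(ds.modality_masks[name])
        write_feature_table(
            os.path.join(outdir, f"features_{name}.tsv"),
            [ds.sample_ids[i] for i in present],
            ds.feature_ids[name], ds.modality_features[name][present])
    meta = ds.metadata
    if meta is None:
        import pandas as pd
        meta = pd.DataFrame({"label": ds.labels}, index=ds.sample_ids)
    write_metadata(os.path.join(outdir, "metadata.tsv"), meta)
    for name, g in getattr(ds, "graphs", {}).items():
        save_graph(g, os.path.join(outdir, f"graph_{name}.tsv"),
                   fmt="edge_list_tsv",
                   node_order_path=os.path.join(outdir, f"nodes_{name}.txt"))
        save_graph(g, os.path.join(outdir, f"graph_{name}.graphml"), fmt="graphml")
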