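"""Synthetic knowledge graphs, attributes, and screens with a planted signal.

The generator emulates the statistical structure of real screen data on which
the method rests: genes whose perturbation affects a phenotype tend to sit
close to the phenotype's target nodes in the interaction graph. Each
non-target gene's positive-label probability is a nonincreasing function of
its shortest-path distance to the nearest target (``rate_at_distance``), and
screen FDR values are drawn so that label 1 <=> FDR < 0.1 holds exactly
(positives ~ U(0, 0.1), negatives ~ U(0.1, 1)).

GO annotations can be drawn with community structure (genes near the targets
share a term pool) so GO-feature ablations have signal to find; switching
``go_community`` off makes all node attributes label-independent, planting
signal exclusively in the relation features.

All output files are byte-identical given the same config and seed, and
parse cleanly through the kgraph and labels readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from perturbgraph.kgraph import Phenotype, write_phenotype
from perturbgraph.taxonomy import default_taxonomy


@dataclass(frozen=True)
class SynthConfig:
    n_genes: int = 300
    edge_model: str = "erdos_renyi"  # or 'scale_free'
    er_p: float = 0.03
    ba_m: int = 3
    channel_probs: dict = field(
        default_factory=lambda: {"E": 0.5, "D": 0.35, "T": 0.6}
    )
    score_low: float = 0.4
    score_high: float = 1.0
    n_targets: int = 2
    rate_at_distance: dict = field(default_factory=lambda: {1: 0.8, 2: 0.4, 3: 0.1})
    rate_default: float = 0.02  # applies beyond the largest mapped distance
    n_go_terms: int = 48
    go_annotation_prob: float = 0.9
    go_mean_terms: float = 4.0
    go_community: bool = True
    loc_mean_terms: float = 2.0
    abundance_mu: float = 1.0
    abundance_sigma: float = 1.0
    abundance_missing_rate: float = 0.1
    seed: int = 7

    def __post_init__(self) -> None:
        probs = [*self.channel_probs.values(), self.go_annotation_prob, self.rate_default]
        probs += list(self.rate_at_distance.values())
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        ds = sorted(self.rate_at_distance)
        rates = [self.rate_at_distance[d] for d in ds] + [self.rate_default]
        if any(a < b for a, b in zip(rates, rates[1:])):
            raise ValueError("rate_at_distance must be nonincreasing in distance")


@dataclass
class SynthDataset:
    """File paths plus ground truth for one generated world."""

    edges: Path
    abundance: Path
    localization: Path
    go: Path
    screens: dict[str, Path]  # phenotype name -> screen TSV
    phenotype_files: dict[str, Path]
    phenotypes: dict[str, Phenotype]
    truth: dict[str, "np.ndarray | object"]  # phenotype name -> truth DataFrame


def _gene_names(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(n)]


def _build_graph(cfg: SynthConfig, rng: np.random.Generator) -> nx.Graph:
    gseed = int(rng.integers(0, 2**31 - 1))
    if cfg.edge_model == "erdos_renyi":
        g = nx.gnp_random_graph(cfg.n_genes, cfg.er_p, seed=gseed)
    elif cfg.edge_model == "scale_free":
        g = nx.barabasi_albert_graph(cfg.n_genes, cfg.ba_m, seed=gseed)
    else:
        raise ValueError(f"unknown edge model {cfg.edge_model!r}")
    g = nx.relabel_nodes(g, dict(enumerate(_gene_names(cfg.n_genes))))
    # isolated genes cannot round-trip through an edge list and would be
    # excluded from every instance set anyway; drop them from the world
    g.remove_nodes_from(list(nx.isolates(g)))
    return g


def _pick_targets(g: nx.Graph, k: int, rng: np.random.Generator, exclude=()) -> list[str]:
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), sorted(c)[0]))
    pool = sorted(set(comps[0]) - set(exclude)) if comps else []
    degs = np.array([g.degree[n] for n in pool])
    cand = [n for n, d in zip(pool, degs) if d >= max(1, np.median(degs))]
    if len(cand) < k:
        cand = pool
    if len(cand) < k:
        raise ValueError(f"not enough nodes to pick {k} targets")
    return sorted(str(t) for t in rng.choice(cand, size=k, replace=False))


def _distances(g: nx.Graph, targets) -> dict[str, int]:
    dist: dict[str, int] = {}
    for t in targets:
        for n, d in nx.single_source_shortest_path_length(g, t).items():
            if n not in dist or d < dist[n]:
                dist[n] = d
    return dist


def _rate(cfg: SynthConfig, d: int | None) -> float:
    if d is None:
        return cfg.rate_default
    return cfg.rate_at_distance.get(d, cfg.rate_default)


def _write_edges(g: nx.Graph, cfg: SynthConfig, rng: np.random.Generator, path: Path) -> None:
    lines = ["protein1\tprotein2\texperimental\tdatabase\ttextmining\tcombined_score"]
    order = ["E", "D", "T"]
    cp = np.array([cfg.channel_probs[c] for c in order])
    for u, v in sorted((tuple(sorted(e)) for e in g.edges())):
        present = rng.random(3) < cp
        if not present.any():
            # guarantee a nonempty channel set, biased by the channel probs
            present[rng.choice(3, p=cp / cp.sum())] = True
        score = rng.uniform(cfg.score_low, cfg.score_high)
        flags = "\t".join(str(int(b)) for b in present)
        lines.append(f"{u}\t{v}\t{flags}\t{score:.6f}")
    path.write_text("\n".join(lines) + "\n")


def _write_attributes(
    genes: list[str],
    cfg: SynthConfig,
    rng: np.random.Generator,
    dist: dict[str, int],
    abundance: Path,
    localization: Path,
    go: Path,
) -> None:
    ab_lines = ["gene\trna_cell_line\trna_cell_type\tprotein_cell_type"]
    for gname in genes:
        vals = []
        for _ in range(3):
            v = rng.lognormal(cfg.abundance_mu, cfg.abundance_sigma)
            vals.append("" if rng.random() < cfg.abundance_missing_rate else f"{v:.4f}")
        ab_lines.append(f"{gname}\t" + "\t".join(vals))
    abundance.write_text("\n".join(ab_lines) + "\n")

    tax = default_taxonomy()
    loc_lines = ["gene\tcompartment"]
    for gname in genes:
        k = 1 + rng.poisson(max(0.0, cfg.loc_mean_terms - 1))
        terms = rng.choice(tax.terms, size=min(k, len(tax.terms)), replace=False)
        for t in sorted(terms):
            loc_lines.append(f"{gname}\t{t}")
    localization.write_text("\n".join(loc_lines) + "\n")

    terms = [f"GO:{i:07d}" for i in range(1, cfg.n_go_terms + 1)]
    third = cfg.n_go_terms // 3
    near_pool, far_pool, shared = terms[:third], terms[third : 2 * third], terms[2 * third :]
    go_lines = ["gene\tgo_id"]
    for gname in genes:
        if rng.random() >= cfg.go_annotation_prob:
            continue
        if cfg.go_community:
            d = dist.get(gname)
            pool = (near_pool if d is not None and d <= 2 else far_pool) + shared
        else:
            pool = terms
        k = 1 + rng.poisson(max(0.0, cfg.go_mean_terms - 1))
        chosen = rng.choice(pool, size=min(k, len(pool)), replace=False)
        for t in sorted(chosen):
            go_lines.append(f"{gname}\t{t}")
    go.write_text("\n".join(go_lines) + "\n")


def _write_screen(
    genes: list[str],
    targets: set[str],
    cfg: SynthConfig,
    rng: np.random.Generator,
    dist: dict[str, int],
    screen_id: str,
    path: Path,
):
    """Draw labels ~ Bernoulli(rate(d)) and FDRs consistent with them; return truth rows."""
    import pandas as pd

    rows = []
    for gname in genes:
        if gname in targets:
            continue
        d = dist.get(gname)
        label = int(rng.random() < _rate(cfg, d))
        fdr = rng.uniform(0.0, 0.1) if label else rng.uniform(0.1, 1.0)
        rows.append((gname, d, label, fdr))
    truth = pd.DataFrame(rows, columns=["gene", "distance", "label", "fdr"])
    lines = ["gene\tscreen_id\tstat\tstat_kind"]
    for r in truth.itertuples(index=False):
        lines.append(f"{r.gene}\t{screen_id}\t{r.fdr:.6f}\tfdr")
    path.write_text("\n".join(lines) + "\n")
    return truth


def generate(cfg: SynthConfig, out_dir, phenotype_name: str = "synthetic") -> SynthDataset:
    """Generate one graph + attributes + screen + phenotype under ``cfg``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    g = _build_graph(cfg, rng)
    targets = _pick_targets(g, cfg.n_targets, rng)
    if all(g.degree[t] == 0 for t in targets) and cfg.rate_default == 0 and not any(
        cfg.rate_at_distance.values()
    ):
        raise ValueError("degenerate config: isolated targets with all-zero rates")
    dist = _distances(g, targets)

    edges = out / "edges.tsv"
    abundance = out / "abundance.tsv"
    localization = out / "localization.tsv"
    go = out / "go.tsv"
    screen = out / f"screen_{phenotype_name}.tsv"
    pheno_file = out / f"phenotype_{phenotype_name}.yaml"

    genes = sorted(g.nodes)
    _write_edges(g, cfg, rng, edges)
    _write_attributes(genes, cfg, rng, dist, abundance, localization, go)
    truth = _write_screen(genes, set(targets), cfg, rng, dist, f"screen_{phenotype_name}", screen)
    phenotype = Phenotype(name=phenotype_name, targets=frozenset(targets))
    write_phenotype(phenotype, pheno_file)

    return SynthDataset(
        edges=edges,
        abundance=abundance,
        localization=localization,
        go=go,
        screens={phenotype_name: screen},
        phenotype_files={phenotype_name: pheno_file},
        phenotypes={phenotype_name: phenotype},
        truth={phenotype_name: truth},
    )


def generate_paired(cfg: SynthConfig, out_dir, n_phenotypes: int = 2) -> SynthDataset:
    """Multiple phenotypes with disjoint target sets on one shared graph.

    All phenotypes follow the same planted distance-decay rule, giving a
    shared mechanism a transfer experiment can exploit.
    """
    if n_phenotypes < 2:
        raise ValueError("need at least 2 phenotypes; use generate() for one")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    g = _build_graph(cfg, rng)
    if g.number_of_nodes() < n_phenotypes * cfg.n_targets:
        raise ValueError("not enough nodes for disjoint target sets")

    edges = out / "edges.tsv"
    _write_edges(g, cfg, rng, edges)
    genes = sorted(g.nodes)

    used: set[str] = set()
    target_sets = []
    for _ in range(n_phenotypes):
        t = _pick_targets(g, cfg.n_targets, rng, exclude=used)
        used |= set(t)
        target_sets.append(t)

    # node attributes are shared; GO communities keyed to the first phenotype
    dist0 = _distances(g, target_sets[0])
    abundance = out / "abundance.tsv"
    localization = out / "localization.tsv"
    go = out / "go.tsv"
    _write_attributes(genes, cfg, rng, dist0, abundance, localization, go)

    screens, pheno_files, phenos, truths = {}, {}, {}, {}
    for i, targets in enumerate(target_sets):
        name = f"synthetic_{chr(ord('A') + i)}"
        dist = _distances(g, targets)
        screen = out / f"screen_{name}.tsv"
        truths[name] = _write_screen(genes, set(targets), cfg, rng, dist, f"screen_{name}", screen)
        screens[name] = screen
        pheno = Phenotype(name=name, targets=frozenset(targets))
        pheno_files[name] = out / f"phenotype_{name}.yaml"
        write_phenotype(pheno, pheno_files[name])
        phenos[name] = pheno

    return SynthDataset(
        edges=edges,
        abundance=abundance,
        localization=localization,
        go=go,
        screens=screens,
        phenotype_files=pheno_files,
        phenotypes=phenos,
        truth=truths,
    )
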