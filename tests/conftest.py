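"""Shared fixtures: hand-built graphs, brute-force path oracles, and
session-scoped synthetic worlds reused by the heavier end-to-end tests."""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from perturbgraph import labels as lab
from perturbgraph.features import FeatureMatrix, assemble_matrix
from perturbgraph.go_embed import GoEmbedding, build_go_graph, embed_go_graph
from perturbgraph.kgraph import KnowledgeGraph, Phenotype, read_attribute_tables, read_edge_table
from perturbgraph.synthgen import SynthConfig, generate, generate_paired


def make_kg(edges, attrs=None) -> KnowledgeGraph:
    """Build a KnowledgeGraph from (u, v, channels, score) tuples."""
    kg = KnowledgeGraph()
    for u, v, ch, s in edges:
        kg.add_interaction(u, v, ch, s)
    for gene, at in (attrs or {}).items():
        if gene not in kg:
            kg.add_gene(gene)
        kg.set_attrs(gene, at)
    return kg


@pytest.fixture
def triangle_kg() -> KnowledgeGraph:
    """Triangle g-u (E, 0.9), g-v (D, 0.5), u-v (T, 0.9)."""
    return make_kg(
        [
            ("g", "u", {"E"}, 0.9),
            ("g", "v", {"D"}, 0.5),
            ("u", "v", {"T"}, 0.9),
        ]
    )


def random_kg(seed: int, n: int = 10, p: float = 0.35) -> KnowledgeGraph:
    """Random graph with random channels and scores, for oracle comparisons."""
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    kg = KnowledgeGraph()
    for i in range(n):
        kg.add_gene(f"n{i:02d}")
    for u, v in g.edges():
        ch = {c for c in "EDT" if rng.random() < 0.5} or {"T"}
        kg.add_interaction(f"n{u:02d}", f"n{v:02d}", ch, float(rng.uniform(0.1, 1.0)))
    return kg


# -- brute-force path oracle ----------------------------------------------


def dfs_simple_paths(kg: KnowledgeGraph, source: str, target: str, max_len: int):
    """Exhaustive DFS over simple paths of 1..max_len edges, independent of
    the feature module's enumeration."""
    out = []

    def walk(path):
        cur = path[-1]
        if cur == target and len(path) > 1:
            out.append(tuple(path))
            return
        if len(path) - 1 >= max_len:
            return
        for nbr in sorted(kg.g.neighbors(cur)):
            if nbr not in path:
                walk(path + [nbr])

    walk([source])
    return out


def oracle_path_features(kg: KnowledgeGraph, source: str, targets, max_len: int):
    """Recompute every path-derived relation feature by brute force."""
    paths = []
    for t in sorted(set(targets) - {source}):
        paths.extend(dfs_simple_paths(kg, source, t, max_len))
    ngrams: dict[str, int] = {}
    best_conf, best_invdeg, shortest = 0.0, 0.0, None
    for p in paths:
        gram, conf = "", 1.0
        for u, v in zip(p, p[1:]):
            ch = kg.channels(u, v)
            gram += "E" if "E" in ch else ("D" if "D" in ch else "T")
            conf *= kg.score(u, v)
        ngrams[gram] = ngrams.get(gram, 0) + 1
        best_conf = max(best_conf, conf)
        invdeg = 1.0
        for u in p[1:]:
            invdeg /= kg.degree(u)
        best_invdeg = max(best_invdeg, invdeg)
        if shortest is None or len(p) - 1 < shortest:
            shortest = len(p) - 1
    return {
        "paths": sorted(paths),
        "ngrams": ngrams,
        "best_conf": best_conf,
        "best_invdeg": best_invdeg,
        "shortest": shortest,
        "count": len(paths),
    }


# -- session-scoped synthetic worlds --------------------------------------


@dataclass
class World:
    kg: KnowledgeGraph
    phenotype: Phenotype
    table: pd.DataFrame
    embedding: GoEmbedding
    fmatrix: FeatureMatrix
    truth: pd.DataFrame
    dataset: object


def _build_world(ds, name: str, seed: int = 7) -> World:
    kg = read_edge_table(ds.edges)
    read_attribute_tables(ds.abundance, ds.localization, ds.go, kg)
    ph = ds.phenotypes[name]
    table = lab.pool_labels(lab.read_screen_table(ds.screens[name]), kg, ph)
    table = lab.add_target_instances(table, ph)
    table = lab.make_folds(table, "stratified", 5, seed=seed)
    gg = build_go_graph(kg, k=20)
    emb = embed_go_graph(gg, dim=64, seed=seed)
    fm = assemble_matrix(kg, ph, table, emb)
    return World(kg, ph, table, emb, fm, ds.truth[name], ds)


@pytest.fixture(scope="session")
def planted_world(tmp_path_factory) -> World:
    """The default planted-signal world: n=300 ER graph, 2 targets, seed 7."""
    ds = generate(SynthConfig(), tmp_path_factory.mktemp("planted"))
    return _build_world(ds, next(iter(ds.phenotypes)))


@pytest.fixture(scope="session")
def paired_worlds(tmp_path_factory) -> tuple[World, World]:
    """Two phenotypes with disjoint targets sharing one graph and one planted rule."""
    ds = generate_paired(SynthConfig(), tmp_path_factory.mktemp("paired"))
    names = sorted(ds.phenotypes)
    kg = read_edge_table(ds.edges)
    read_attribute_tables(ds.abundance, ds.localization, ds.go, kg)
    gg = build_go_graph(kg, k=20)
    emb = embed_go_graph(gg, dim=64, seed=7)
    worlds = []
    for name in names:
        ph = ds.phenotypes[name]
        table = lab.pool_labels(lab.read_screen_table(ds.screens[name]), kg, ph)
        table = lab.add_target_instances(table, ph)
        table = lab.make_folds(table, "stratified", 5, seed=7)
        fm = assemble_matrix(kg, ph, table, emb)
        worlds.append(World(kg, ph, table, emb, fm, ds.truth[name], ds))
    return tuple(worlds)


@pytest.fixture(scope="session")
def relation_only_world(tmp_path_factory) -> World:
    """Single-target world with label-independent node attributes: the planted
    signal lives exclusively in the relation features."""
    cfg = SynthConfig(go_community=False, n_targets=1)
    ds = generate(cfg, tmp_path_factory.mktemp("relonly"))
    return _build_world(ds, next(iter(ds.phenotypes)))
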