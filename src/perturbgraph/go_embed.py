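"""GO-annotation gene graph and embedded gene representations.

Genes are linked by functional similarity: the Jaccard index of their GO
annotation sets. For each annotated gene we keep directed edges to its top-k
most similar genes, then learn a low-dimensional embedding of the resulting
directed graph with node2vec-style biased random walks and a skip-gram model
with negative sampling. Genes without GO annotations are excluded from the
graph; their embedding is the all-zero vector with a presence bit of 0.

The skip-gram trainer is implemented here in numpy (minibatched SGD with
``np.add.at`` accumulation) so the embedding is fully deterministic given a
seed and has no heavyweight dependencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from perturbgraph.kgraph import KnowledgeGraph


def jaccard(annotations_u, annotations_v) -> float:
    """Jaccard index |Nu ∩ Nv| / |Nu ∪ Nv|; 0 when both sets are empty."""
    u, v = set(annotations_u), set(annotations_v)
    union = len(u | v)
    if union == 0:
        return 0.0
    return len(u & v) / union


def build_go_graph(graph: KnowledgeGraph, k: int = 20) -> nx.DiGraph:
    """Directed top-k Jaccard-similarity graph over GO-annotated genes.

    For each gene u with a nonempty annotation set, add edges u -> v to the k
    genes with the highest nonzero J(u, v), weighted by J. Ties are broken by
    lexicographic gene id so construction is deterministic.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    genes = [g for g in graph.nodes if graph.attrs(g).go_terms]
    go = nx.DiGraph()
    go.add_nodes_from(genes)
    if len(genes) < 2:
        return go

    terms = sorted({t for g in genes for t in graph.attrs(g).go_terms})
    tidx = {t: i for i, t in enumerate(terms)}
    rows, cols = [], []
    for i, g in enumerate(genes):
        for t in graph.attrs(g).go_terms:
            rows.append(i)
            cols.append(tidx[t])
    M = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(genes), len(terms))
    )
    inter = (M @ M.T).toarray()
    sizes = np.asarray(M.sum(axis=1)).ravel()
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore"):
        J = np.where(union > 0, inter / union, 0.0)
    np.fill_diagonal(J, 0.0)

    for i, g in enumerate(genes):
        cand = np.flatnonzero(J[i] > 0)
        # sort by (-J, gene id) for a deterministic top-k
        order = sorted(cand, key=lambda j: (-J[i, j], genes[j]))
        for j in order[:k]:
            go.add_edge(g, genes[j], weight=float(J[i, j]))
    return go


@dataclass
class GoEmbedding:
    """Per-gene embedded representation with a graph-presence indicator."""

    vectors: dict[str, np.ndarray]
    dim: int
    _zero: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._zero = np.zeros(self.dim)

    def present(self, gene: str) -> int:
        return int(gene in self.vectors)

    def vector(self, gene: str) -> np.ndarray:
        """Embedding vector; all-zero for genes absent from the GO graph."""
        return self.vectors.get(gene, self._zero)

    def to_tsv(self, path) -> None:
        rows = []
        for gene in sorted(self.vectors):
            rows.append([gene, 1, *self.vectors[gene]])
        cols = ["gene", "present", *[f"v{i + 1}" for i in range(self.dim)]]
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GoEmbedding":
        df = pd.read_csv(path, sep="\t", dtype={"gene": str})
        dim = df.shape[1] - 2
        vecs = {
            r[0]: np.asarray(r[2:], dtype=float)
            for r in df.itertuples(index=False)
            if int(r[1]) == 1
        }
        return cls(vectors=vecs, dim=dim)


def _simulate_walks(
    go_graph: nx.DiGraph,
    rng: np.random.Generator,
    n_walks: int,
    walk_length: int,
    p: float,
    q: float,
) -> list[list[int]]:
    """node2vec biased walks along directed edges, as lists of node indices.

    The return parameter p discourages (p > 1) or encourages (p < 1)
    immediately revisiting the previous node; the in-out parameter q biases
    toward (q < 1) or away from (q > 1) nodes not adjacent from the previous
    node. Walks stop early at nodes with no out-edges.
    """
    nodes = sorted(go_graph.nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    succ: list[np.ndarray] = []
    wts: list[np.ndarray] = []
    succ_sets: list[set[int]] = []
    for g in nodes:
        nbrs = sorted(go_graph.successors(g))
        succ.append(np.array([idx[v] for v in nbrs], dtype=int))
        w = np.array([go_graph.edges[g, v].get("weight", 1.0) for v in nbrs])
        wts.append(w / w.sum() if len(w) else w)
        succ_sets.append({idx[v] for v in nbrs})

    walks: list[list[int]] = []
    unbiased = p == 1.0 and q == 1.0
    for _ in range(n_walks):
        for start in rng.permutation(len(nodes)):
            walk = [int(start)]
            while len(walk) < walk_length:
                cur = walk[-1]
                nbrs = succ[cur]
                if len(nbrs) == 0:
                    break
                if unbiased or len(walk) == 1:
                    probs = wts[cur]
                else:
                    prev = walk[-2]
                    w = wts[cur].copy()
                    for j, x in enumerate(nbrs):
                        if x == prev:
                            w[j] /= p
                        elif x not in succ_sets[prev]:
                            w[j] /= q
                    probs = w / w.sum()
                walk.append(int(rng.choice(nbrs, p=probs)))
            walks.append(walk)
    return walks


def _train_skipgram(
    walks: list[list[int]],
    n_vocab: int,
    dim: int,
    window: int,
    negative: int,
    epochs: int,
    lr: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Skip-gram with negative sampling over walk corpora; returns input vectors."""
    centers, contexts = [], []
    counts = np.zeros(n_vocab)
    for walk in walks:
        for i, c in enumerate(walk):
            counts[c] += 1
            lo, hi = max(0, i - window), min(len(walk), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(c)
                    contexts.append(walk[j])
    centers = np.asarray(centers, dtype=int)
    contexts = np.asarray(contexts, dtype=int)
    if len(centers) == 0:
        return np.zeros((n_vocab, dim))

    noise = counts**0.75
    noise /= noise.sum()

    W_in = (rng.random((n_vocab, dim)) - 0.5) / dim
    W_out = np.zeros((n_vocab, dim))
    n_pairs = len(centers)
    batch = 1024
    total_steps = max(1, epochs * ((n_pairs + batch - 1) // batch))
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for s in range(0, n_pairs, batch):
            sel = order[s : s + batch]
            c, o = centers[sel], contexts[sel]
            neg = rng.choice(n_vocab, size=(len(sel), negative), p=noise)
            eta = lr * max(1e-4 / lr, 1.0 - step / total_steps)
            step += 1

            v_c = W_in[c]  # (B, d)
            u_o = W_out[o]  # (B, d)
            u_n = W_out[neg]  # (B, K, d)

            logit_pos = np.clip(np.sum(v_c * u_o, axis=1), -30, 30)
            logit_neg = np.clip(np.einsum("bd,bkd->bk", v_c, u_n), -30, 30)
            s_pos = 1.0 / (1.0 + np.exp(-logit_pos))  # sigma(v.u)
            s_neg = 1.0 / (1.0 + np.exp(-logit_neg))

            g_pos = (s_pos - 1.0)[:, None]  # d/du_o
            g_neg = s_neg[:, :, None]  # d/du_n
            grad_c = g_pos * u_o + np.einsum("bk,bkd->bd", s_neg, u_n)

            np.add.at(W_in, c, -eta * grad_c)
            np.add.at(W_out, o, -eta * g_pos * v_c)
            np.add.at(
                W_out.reshape(-1, dim),
                neg.ravel(),
                -eta * (g_neg * v_c[:, None, :]).reshape(-1, dim),
            )
    return W_in


def embed_go_graph(
    go_graph: nx.DiGraph,
    dim: int = 64,
    seed: int = 0,
    n_walks: int = 10,
    walk_length: int = 30,
    p: float = 1.0,
    q: float = 1.0,
    window: int = 5,
    negative: int = 5,
    epochs: int = 2,
    lr: float = 0.025,
) -> GoEmbedding:
    """Learn a ``dim``-dimensional embedding of every GO-graph gene.

    Deterministic given ``seed``. Raises on an empty graph; genes not in
    ``go_graph`` are represented downstream by the zero vector with
    presence bit 0 (see :class:`GoEmbedding`).
    """
    if go_graph.number_of_nodes() == 0:
        raise ValueError("cannot embed an empty GO graph")
    rng = np.random.default_rng(seed)
    nodes = sorted(go_graph.nodes)
    walks = _simulate_walks(go_graph, rng, n_walks, walk_length, p, q)
    W = _train_skipgram(walks, len(nodes), dim, window, negative, epochs, lr, rng)
    return GoEmbedding(vectors={g: W[i].copy() for i, g in enumerate(nodes)}, dim=dim)
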