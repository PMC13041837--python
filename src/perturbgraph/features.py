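"""Instance feature assembly: x(g,P) = [source | source-target relation | target].

Each instance pairs a perturbed source gene g with a phenotype P (a set of
target nodes). Three blocks are concatenated:

* source node features n(g): 3 cellular-abundance values with companion
  measured-indicator bits, 41 hierarchical subcellular-localization bits, and
  the 64-dim GO embedding with a presence bit (112 columns);
* relation features e(g->P): evidence n-gram counts over all simple paths up
  to a maximum length, best path confidence (product of combined scores),
  shortest-path thermometer bits, path count and existence, max inverse
  degree product over paths, RWR diffusion scores of g under target seeding,
  and localization/GO cosine and abundance-difference similarities;
* target node features n(P): n(g)-style features aggregated over the targets
  (averages for real-valued blocks, OR for binary blocks).

Every column carries two group tags used by the ablation experiments: a
subgraph tag in {source, target, st_relation} and an evidence tag in
{abundance, localization, go, ppi}. Min-max scaling is fitted on training
rows only; test values are clipped into [0, 1].
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from perturbgraph import diffusion
from perturbgraph.go_embed import GoEmbedding
from perturbgraph.kgraph import KnowledgeGraph, Phenotype, strongest_channel

_ABUND_FIELDS = ("rna_cell_line", "rna_cell_type", "protein_cell_type")


@dataclass(frozen=True)
class FeaturesConfig:
    max_len: int = 3  # maximum simple-path length for relation features
    sim_agg: str = "max"  # 'max' or 'mean' similarity aggregation over targets
    log_abundance: bool = True  # log1p-transform abundances before use
    rwr_alphas: tuple[float, ...] = (0.2, 0.4, 0.6)

    def __post_init__(self) -> None:
        if self.max_len < 1:
            raise ValueError("max_len must be >= 1")
        if self.sim_agg not in ("max", "mean"):
            raise ValueError(f"sim_agg must be 'max' or 'mean', got {self.sim_agg!r}")


@dataclass(frozen=True)
class NodeFeatureVector:
    """Fixed-layout node features for one gene or an aggregate over targets."""

    abundance: np.ndarray  # (3,) values, missing imputed to 0
    measured: np.ndarray  # (3,) indicator bits (fractions after aggregation)
    localization: np.ndarray  # (41,) ancestor-closed bits
    go: np.ndarray  # (dim,) embedding
    go_present: float

    def concat(self) -> np.ndarray:
        return np.concatenate(
            [self.abundance, self.measured, self.localization, self.go, [self.go_present]]
        )


def node_features(
    graph: KnowledgeGraph, gene: str, embedding: GoEmbedding, config: FeaturesConfig | None = None
) -> NodeFeatureVector:
    """Node feature vector for one gene.

    Missing abundances are imputed to 0 with the companion measured bit set
    to 0, so "missing" and "measured zero" stay distinguishable.
    """
    config = config or FeaturesConfig()
    if gene not in graph:
        raise KeyError(gene)
    at = graph.attrs(gene)
    ab, meas = np.zeros(3), np.zeros(3)
    for i, f in enumerate(_ABUND_FIELDS):
        v = getattr(at, f)
        if v is not None:
            ab[i] = np.log1p(v) if config.log_abundance else v
            meas[i] = 1.0
    loc = np.array([float(t in at.localizations) for t in graph.taxonomy.terms])
    return NodeFeatureVector(
        abundance=ab,
        measured=meas,
        localization=loc,
        go=np.asarray(embedding.vector(gene), dtype=float),
        go_present=float(embedding.present(gene)),
    )


def aggregate_targets(vectors: list[NodeFeatureVector]) -> NodeFeatureVector:
    """Aggregate per-target node vectors into one phenotype-level vector.

    Real-valued blocks (abundance, GO embedding) are element-wise averaged;
    binary blocks (localization, GO presence) are element-wise OR-ed.
    """
    if not vectors:
        raise ValueError("cannot aggregate an empty target list")
    return NodeFeatureVector(
        abundance=np.mean([v.abundance for v in vectors], axis=0),
        measured=np.mean([v.measured for v in vectors], axis=0),
        localization=np.max([v.localization for v in vectors], axis=0),
        go=np.mean([v.go for v in vectors], axis=0),
        go_present=float(max(v.go_present for v in vectors)),
    )


# -- path-based relation features -----------------------------------------


def enumerate_paths(graph: KnowledgeGraph, source: str, target: str, max_len: int):
    """All simple paths from source to target with 1..max_len edges."""
    if source == target:
        raise ValueError("source equals target; use the identity convention instead")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if source not in graph or target not in graph:
        return []
    return [tuple(p) for p in nx.all_simple_paths(graph.g, source, target, cutoff=max_len)]


def evidence_ngram(path, graph: KnowledgeGraph) -> str:
    """Per-edge strongest evidence channel (E > D > T) concatenated along the path."""
    out = []
    for u, v in zip(path, path[1:]):
        if not graph.g.has_edge(u, v):
            raise ValueError(f"consecutive path nodes {u!r}, {v!r} are not adjacent")
        out.append(strongest_channel(graph.channels(u, v)))
    return "".join(out)


def all_ngrams(max_len: int) -> list[str]:
    """All evidence n-grams of length 1..max_len in deterministic order."""
    out = []
    for length in range(1, max_len + 1):
        out.extend("".join(t) for t in itertools.product("EDT", repeat=length))
    return out


def _paths_to_targets(graph, source, targets, max_len):
    for t in sorted(targets):
        if t == source:
            continue
        for p in enumerate_paths(graph, source, t, max_len):
            yield p


def ngram_count_features(graph: KnowledgeGraph, source: str, targets, max_len: int) -> dict[str, int]:
    """Raw n-gram occurrence counts over all (path, target) pairs."""
    counts = dict.fromkeys(all_ngrams(max_len), 0)
    for p in _paths_to_targets(graph, source, targets, max_len):
        counts[evidence_ngram(p, graph)] += 1
    return counts


def best_path_confidence(graph: KnowledgeGraph, source: str, targets, max_len: int) -> float:
    """Max over paths of the product of edge combined scores; 0 when no path."""
    best = 0.0
    for p in _paths_to_targets(graph, source, targets, max_len):
        conf = 1.0
        for u, v in zip(p, p[1:]):
            conf *= graph.score(u, v)
        best = max(best, conf)
    return best


def max_inverse_degree_product(graph: KnowledgeGraph, source: str, targets, max_len: int) -> float:
    """Max over paths (u1..uk) of prod_{i=2..k} 1/degree(ui); 0 when no path."""
    best = 0.0
    for p in _paths_to_targets(graph, source, targets, max_len):
        prod = 1.0
        for u in p[1:]:
            prod /= graph.degree(u)
        best = max(best, prod)
    return best


def topology_features(graph: KnowledgeGraph, source: str, targets, max_len: int):
    """(thermometer bits, path_count, path_exists) for the source vs the targets.

    The thermometer has max_len bits; bit i is set iff the shortest path
    length s over all targets satisfies s <= i+1. No path within max_len
    yields all-zero bits, count 0, exists 0.
    """
    paths = list(_paths_to_targets(graph, source, targets, max_len))
    count = len(paths)
    thermo = np.zeros(max_len)
    if count:
        s = min(len(p) - 1 for p in paths)
        thermo = (np.arange(1, max_len + 1) >= s).astype(float)
    return thermo, count, int(count > 0)


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def similarity_features(
    source_vec: NodeFeatureVector, target_vecs: list[NodeFeatureVector], agg: str = "max"
):
    """(loc_cos, go_cos, abundance_diff, abundance_absdiff) vs the targets.

    Cosines are computed per target over the localization and GO blocks, then
    aggregated by max or mean; abundance differences are taken against the
    aggregated target abundance. A zero-norm block has cosine 0.
    """
    if not target_vecs:
        raise ValueError("empty target list")
    aggfun = np.max if agg == "max" else np.mean
    loc_cos = float(aggfun([_cosine(source_vec.localization, t.localization) for t in target_vecs]))
    go_cos = float(aggfun([_cosine(source_vec.go, t.go) for t in target_vecs]))
    tgt = aggregate_targets(target_vecs)
    diff = source_vec.abundance - tgt.abundance
    return loc_cos, go_cos, diff, np.abs(diff)


# -- matrix assembly -------------------------------------------------------


@dataclass
class MinMaxScaler:
    """Per-column min-max scaling fitted on training rows; test clipped to [0,1].

    A constant column maps to 0 everywhere. Stored bounds allow an exact
    inverse transform of non-constant columns.
    """

    lo: pd.Series | None = None
    hi: pd.Series | None = None

    def fit(self, train: pd.DataFrame) -> "MinMaxScaler":
        self.lo = train.min(axis=0)
        self.hi = train.max(axis=0)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        span = (self.hi - self.lo).replace(0.0, np.nan)
        out = (X - self.lo) / span
        return out.fillna(0.0).clip(0.0, 1.0)

    def fit_transform(self, train: pd.DataFrame) -> pd.DataFrame:
        return self.fit(train).transform(train)


@dataclass
class FeatureMatrix:
    """Raw (unscaled) instance features with per-column group tags."""

    X: pd.DataFrame
    subgraph_tags: dict[str, str]  # column -> source | target | st_relation
    evidence_tags: dict[str, str]  # column -> abundance | localization | go | ppi
    config: FeaturesConfig = field(default_factory=FeaturesConfig)

    def columns_by_tag(self, subgraph: str | None = None, evidence: str | None = None) -> list[str]:
        cols = []
        for c in self.X.columns:
            if subgraph is not None and self.subgraph_tags[c] != subgraph:
                continue
            if evidence is not None and self.evidence_tags[c] != evidence:
                continue
            cols.append(c)
        return cols

    def to_tsv(self, path, sidecar_yaml=None) -> None:
        self.X.to_csv(path, sep="\t", index=False)
        if sidecar_yaml is not None:
            import yaml

            meta = {
                "columns": list(self.X.columns),
                "subgraph_tags": self.subgraph_tags,
                "evidence_tags": self.evidence_tags,
            }
            with open(sidecar_yaml, "w") as fh:
                yaml.safe_dump(meta, fh)

    @classmethod
    def from_tsv(cls, path, sidecar_yaml) -> "FeatureMatrix":
        import yaml

        X = pd.read_csv(path, sep="\t", float_precision="round_trip")
        with open(sidecar_yaml) as fh:
            meta = yaml.safe_load(fh)
        X = X[meta["columns"]]
        return cls(
            X=X,
            subgraph_tags=meta["subgraph_tags"],
            evidence_tags=meta["evidence_tags"],
        )


def _layout(config: FeaturesConfig, go_dim: int):
    """Column names + tags; a pure function of config, identical across phenotypes."""
    cols: list[tuple[str, str, str]] = []  # (name, subgraph, evidence)

    def node_block(prefix: str, tag: str):
        for f in _ABUND_FIELDS:
            cols.append((f"{prefix}_{f}", tag, "abundance"))
        for f in _ABUND_FIELDS:
            cols.append((f"{prefix}_measured_{f}", tag, "abundance"))
        for i in range(41):
            cols.append((f"{prefix}_loc_{i}", tag, "localization"))
        for i in range(go_dim):
            cols.append((f"{prefix}_go_{i}", tag, "go"))
        cols.append((f"{prefix}_go_present", tag, "go"))

    node_block("src", "source")
    for s in all_ngrams(config.max_len):
        cols.append((f"rel_ngram_{s}", "st_relation", "ppi"))
    cols.append(("rel_best_path_confidence", "st_relation", "ppi"))
    for i in range(1, config.max_len + 1):
        cols.append((f"rel_sp_le_{i}", "st_relation", "ppi"))
    cols.append(("rel_path_count", "st_relation", "ppi"))
    cols.append(("rel_path_exists", "st_relation", "ppi"))
    cols.append(("rel_max_inv_degree_product", "st_relation", "ppi"))
    for a in config.rwr_alphas:
        cols.append((f"rel_rwr_a{a}", "st_relation", "ppi"))
    cols.append(("rel_loc_cos", "st_relation", "localization"))
    cols.append(("rel_go_cos", "st_relation", "go"))
    for f in _ABUND_FIELDS:
        cols.append((f"rel_abund_diff_{f}", "st_relation", "abundance"))
    for f in _ABUND_FIELDS:
        cols.append((f"rel_abund_absdiff_{f}", "st_relation", "abundance"))
    node_block("tgt", "target")
    return cols


def _relation_row(graph, source, targets, node_vecs, config, rwr_by_alpha, idx):
    """Relation feature values for one (source, target-set) pair."""
    targets = set(targets)
    identity = source in targets
    path_targets = targets - {source}
    vals: list[float] = []

    if path_targets:
        counts = ngram_count_features(graph, source, path_targets, config.max_len)
        vals.extend(counts[s] for s in all_ngrams(config.max_len))
        vals.append(best_path_confidence(graph, source, path_targets, config.max_len))
        thermo, count, exists = topology_features(graph, source, path_targets, config.max_len)
        vals.extend(thermo)
        vals.extend([count, exists])
        vals.append(max_inverse_degree_product(graph, source, path_targets, config.max_len))
    else:
        # source is the sole target: direct-identity convention
        vals.extend([0.0] * len(all_ngrams(config.max_len)))
        vals.append(1.0)  # confidence
        vals.extend([1.0] * config.max_len)  # thermometer
        vals.extend([0.0, 1.0])  # count, exists
        vals.append(1.0)  # inverse degree product

    for a in config.rwr_alphas:
        vals.append(float(rwr_by_alpha[a][idx[source]]))

    svec = node_vecs[source]
    tvecs = [node_vecs[t] for t in sorted(targets)]
    loc_cos, go_cos, diff, absdiff = similarity_features(svec, tvecs, config.sim_agg)
    if identity:
        loc_cos, go_cos = 1.0, 1.0
    vals.extend([loc_cos, go_cos])
    vals.extend(diff)
    vals.extend(absdiff)
    return vals


def assemble_matrix(
    graph: KnowledgeGraph,
    phenotype: Phenotype,
    instances: pd.DataFrame,
    embedding: GoEmbedding,
    config: FeaturesConfig | None = None,
) -> FeatureMatrix:
    """Build the raw feature matrix for an instance table.

    ``instances`` needs a ``source`` column; an optional per-row ``target``
    column (non-null for per-target phenotypes) overrides the phenotype-level
    target set for that row. RWR diffusion features are computed once per
    phenotype from target-only seeding, so feature construction never sees
    labels. Scaling is applied later, per training fold (see
    :class:`MinMaxScaler`).
    """
    config = config or FeaturesConfig()
    missing = set(instances["source"]) - set(graph.nodes)
    if missing:
        raise KeyError(f"instance sources not in graph: {sorted(missing)[:5]}")

    idx = graph.node_index()
    seed = diffusion.make_seed(graph, phenotype.targets, mode="target")
    rwr_by_alpha = {
        a: diffusion.rwr_scores(graph, seed, a).scores for a in config.rwr_alphas
    }

    per_row_targets = "target" in instances.columns and instances["target"].notna().any()
    needed = set(instances["source"]) | set(phenotype.targets)
    if per_row_targets:
        needed |= set(instances.loc[instances["target"].notna(), "target"])
    node_vecs = {g: node_features(graph, g, embedding, config) for g in needed}

    layout = _layout(config, embedding.dim)
    names = [c[0] for c in layout]
    tgt_cache: dict[frozenset, np.ndarray] = {}
    rel_cache: dict[tuple, list[float]] = {}
    rows = np.empty((len(instances), len(names)))

    for r, row in enumerate(instances.itertuples(index=False)):
        source = row.source
        if per_row_targets and getattr(row, "target", None) and pd.notna(row.target):
            tset = frozenset([row.target])
        else:
            tset = frozenset(phenotype.targets)
        key = (source, tset)
        if key not in rel_cache:
            rel_cache[key] = _relation_row(
                graph, source, tset, node_vecs, config, rwr_by_alpha, idx
            )
        if tset not in tgt_cache:
            tgt_cache[tset] = aggregate_targets([node_vecs[t] for t in sorted(tset)]).concat()
        rows[r] = np.concatenate(
            [node_vecs[source].concat(), rel_cache[key], tgt_cache[tset]]
        )

    X = pd.DataFrame(rows, columns=names)
    return FeatureMatrix(
        X=X,
        subgraph_tags={c[0]: c[1] for c in layout},
        evidence_tags={c[0]: c[2] for c in layout},
        config=config,
    )
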