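"""Screen-derived instance labeling and cross-validation fold construction.

Instances are (source gene, phenotype) pairs. Labels come from CRISPR-screen
statistics (MaGeCK FDR or q-values), which are consumed as given:

* pooled labeling — a gene is positive iff ANY screen for the phenotype
  reports FDR < 0.1 (pooling positives across studies on the premise that
  non-overlap is mostly false negatives);
* per-target labeling — one instance per (knocked-out gene, measured
  protein), positive iff the q-value < 0.05;
* stringent negatives — positives as pooled; negatives restricted to
  FDR > 0.9 or to round-dropout genes, with the ambiguous middle discarded.

All thresholds are strict inequalities; boundary values fall to the
non-significant side. The fold column uses 1..n_folds, with the sentinel
``TRAIN_ONLY_FOLD`` (-1) for injected target-as-source instances that join
every training set but never a test set.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from perturbgraph.kgraph import KnowledgeGraph, Phenotype

logger = logging.getLogger(__name__)

#: Fold sentinel for instances present in every training fold, never in test.
TRAIN_ONLY_FOLD = -1

_COLUMNS = ["source", "phenotype", "target", "label", "fold", "is_target_instance"]


def read_screen_table(path) -> pd.DataFrame:
    """Load a screen TSV: ``gene screen_id stat stat_kind [round] [target]``."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "screen_id": str})
    _validate_stats(df)
    return df


def _validate_stats(records: pd.DataFrame) -> None:
    if ((records["stat"] < 0) | (records["stat"] > 1)).any():
        bad = records.loc[(records["stat"] < 0) | (records["stat"] > 1), "stat"]
        raise ValueError(f"screen stats outside [0, 1]: {bad.tolist()[:5]}")
    if "stat_kind" in records.columns:
        kinds = records.groupby("gene")["stat_kind"].nunique()
        mixed = kinds[kinds > 1]
        if len(mixed):
            raise ValueError(f"conflicting stat kinds for genes: {list(mixed.index)[:5]}")


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(columns=_COLUMNS)


def pool_labels(
    records: pd.DataFrame,
    graph: KnowledgeGraph,
    phenotype: Phenotype,
    pos_threshold: float = 0.1,
) -> pd.DataFrame:
    """Pooled labeling: positive iff any screen reports stat < pos_threshold.

    The instance set is the union of screened genes intersected with the
    graph's node set.
    """
    if records.empty:
        raise ValueError("no screen records")
    _validate_stats(records)
    in_graph = records["gene"].isin(set(graph.nodes))
    dropped = (~in_graph).sum()
    if dropped:
        logger.info("pool_labels: %d screen rows for genes not in graph excluded", dropped)
    sub = records[in_graph]
    pos = sub.groupby("gene")["stat"].min() < pos_threshold
    table = pd.DataFrame(
        {
            "source": pos.index,
            "phenotype": phenotype.name,
            "target": None,
            "label": pos.astype(int).values,
            "fold": np.nan,
            "is_target_instance": 0,
        }
    )
    return table.sort_values("source", ignore_index=True)


def per_target_labels(
    records: pd.DataFrame,
    graph: KnowledgeGraph,
    phenotype: Phenotype,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-target labeling: one instance per (source, measured target), q < 0.05."""
    if "target" not in records.columns or records["target"].isna().any():
        raise ValueError("per-target labeling needs a target column on every record")
    _validate_stats(records)
    if records.duplicated(subset=["gene", "target"]).any():
        dups = records[records.duplicated(subset=["gene", "target"])]
        raise ValueError(f"duplicate (source, target) pairs: {dups[['gene', 'target']].values[:3]}")
    sub = records[records["gene"].isin(set(graph.nodes))]
    if sub.empty:
        return _empty_table()
    table = pd.DataFrame(
        {
            "source": sub["gene"].values,
            "phenotype": phenotype.name,
            "target": sub["target"].values,
            "label": (sub["stat"] < q_threshold).astype(int).values,
            "fold": np.nan,
            "is_target_instance": 0,
        }
    )
    return table.sort_values(["source", "target"], ignore_index=True)


def stringent_negatives(
    records: pd.DataFrame,
    graph: KnowledgeGraph,
    phenotype: Phenotype,
    mode: str = "fdr_high",
    pos_threshold: float = 0.1,
    neg_threshold: float = 0.9,
) -> pd.DataFrame:
    """Three-way split: stringent positives and negatives, middle dropped.

    ``fdr_high`` keeps negatives with min stat > neg_threshold across screens;
    ``round_dropout`` keeps genes screened in round 1 but absent from round 2.
    """
    table = pool_labels(records, graph, phenotype, pos_threshold)
    sub = records[records["gene"].isin(set(graph.nodes))]
    min_stat = sub.groupby("gene")["stat"].min()
    positives = set(table.loc[table["label"] == 1, "source"])

    if mode == "fdr_high":
        negatives = set(min_stat[min_stat > neg_threshold].index) - positives
    elif mode == "round_dropout":
        if "round" not in sub.columns or sub["round"].isna().any():
            raise ValueError("round_dropout mode needs round annotations on every record")
        by_gene = sub.groupby("gene")["round"].agg(set)
        negatives = {
            g for g, rounds in by_gene.items() if 1 in rounds and 2 not in rounds
        } - positives
    else:
        raise ValueError(f"unknown stringent-negative mode {mode!r}")

    keep = table["source"].isin(positives | negatives)
    return table[keep].reset_index(drop=True)


def add_target_instances(table: pd.DataFrame, phenotype: Phenotype) -> pd.DataFrame:
    """Append one positive target-as-source instance per target node.

    These carry the ``TRAIN_ONLY_FOLD`` sentinel: the target is known to
    matter for the phenotype, so it joins every training set but is never
    tested. Targets already present as positive sources are not duplicated.
    """
    existing_pos = set(table.loc[table["label"] == 1, "source"])
    new = [
        {
            "source": t,
            "phenotype": phenotype.name,
            "target": None,
            "label": 1,
            "fold": TRAIN_ONLY_FOLD,
            "is_target_instance": 1,
        }
        for t in sorted(phenotype.targets)
        if t not in existing_pos
    ]
    if not new:
        return table.copy()
    return pd.concat([table, pd.DataFrame(new)], ignore_index=True)


def make_folds(
    table: pd.DataFrame, scheme: str = "stratified", n_folds: int = 5, seed: int = 0
) -> pd.DataFrame:
    """Assign folds 1..n_folds to all non-target-instance rows.

    ``stratified``: shuffled round-robin within each class, so per-fold
    positive counts differ by at most one. ``by_source``: all instances of a
    source share one fold and per-fold source counts differ by at most one.
    Deterministic given ``seed``.
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    table = table.copy()
    mask = table["is_target_instance"] == 0
    rows = table[mask]

    if scheme == "stratified":
        n_pos = int((rows["label"] == 1).sum())
        if 0 < n_pos < n_folds:
            logger.warning(
                "only %d positives for %d folds: stratification is degenerate", n_pos, n_folds
            )
        fold = pd.Series(index=rows.index, dtype=int)
        for lab in (1, 0):
            idx = rows.index[rows["label"] == lab].to_numpy()
            idx = idx[rng.permutation(len(idx))]
            fold.loc[idx] = np.arange(len(idx)) % n_folds + 1
    elif scheme == "by_source":
        sources = np.array(sorted(rows["source"].unique()))
        sources = sources[rng.permutation(len(sources))]
        src_fold = {s: i % n_folds + 1 for i, s in enumerate(sources)}
        fold = rows["source"].map(src_fold)
    else:
        raise ValueError(f"unknown fold scheme {scheme!r}")

    table.loc[mask, "fold"] = fold
    table.loc[~mask, "fold"] = TRAIN_ONLY_FOLD
    table["fold"] = table["fold"].astype(int)
    return table


def write_instances(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_instances(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "phenotype": str})
    if "target" in df.columns:
        df["target"] = df["target"].astype("object").where(df["target"].notna(), None)
    return df
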