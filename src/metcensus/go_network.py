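"""GO-similarity protein networks: Jaccard edges, nominal assortativity
with permutation controls, and hypergeometric term enrichment.

Proteins are nodes labelled MR / NonMR; two nodes are joined when the
Jaccard similarity of their GO term sets is at least 0.25.  The degree to
which edges stay within a label class is Newman's nominal assortativity

    r = (sum_i e_ii - sum_i a_i b_i) / (1 - sum_i a_i b_i),

computed from the edge mixing matrix e (a, b its marginals).  Two controls
gauge significance: relabelling (shuffle labels on the fixed graph, 1e5
reps) and resampling (rebuild the graph from proteins resampled out of a
reference annotation pool, random labels at the observed proportion, 1e3
reps); both are upper-tail plug-in permutation tests.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

JACCARD_THRESHOLD = 0.25


def read_gaf(path: str | Path) -> dict[str, set[str]]:
    """Annotation map (DB object id -> GO term set) from a GAF 2.x file.

    GAF is plain 17-column TSV; comment lines start with '!'.  Only columns
    2 (object id) and 5 (GO id) are consumed.
    """
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 5:
                logger.warning("malformed GAF row skipped: %r", line[:60])
                continue
            out.setdefault(f[1], set()).add(f[4])
    return out


def read_label_table(path: str | Path) -> dict[str, str]:
    """accession -> label from a two-column TSV (header optional)."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["accession", "label"]:
        df = pd.read_csv(path, sep="\t", header=None, names=["accession", "label"])
    return dict(zip(df["accession"], df["label"]))


def jaccard(set_a: set, set_b: set) -> float:
    """|A ∩ B| / |A ∪ B|; two empty sets give 0 (logged)."""
    union = set_a | set_b
    if not union:
        logger.info("Jaccard of two empty sets defined as 0")
        return 0.0
    return len(set_a & set_b) / len(union)


def build_graph(
    annotations: Mapping[str, set[str]],
    labels: Mapping[str, str],
    threshold: float = JACCARD_THRESHOLD,
) -> nx.Graph:
    """Graph over the labelled proteins with edges at Jaccard >= threshold.

    Isolated nodes are retained.  Labelled proteins missing from the
    annotation map get an empty term set (logged).
    """
    g = nx.Graph()
    for acc, lab in labels.items():
        if acc not in annotations:
            logger.info("no annotations for %s; empty term set", acc)
        g.add_node(acc, label=lab)
    nodes = list(g.nodes)
    for a, b in itertools.combinations(nodes, 2):
        if jaccard(annotations.get(a, set()), annotations.get(b, set())) >= threshold:
            g.add_edge(a, b)
    return g


def assortativity(graph: nx.Graph, labels: Mapping[str, str] | None = None) -> float:
    """Newman's nominal assortativity from the edge mixing matrix.

    Returns NaN (not evaluable) for an edgeless graph.  Perfectly
    single-class edge sets with no cross terms give r = 1 by convention
    (the 0/0 limit of the formula).
    """
    if graph.number_of_edges() == 0:
        return float("nan")
    if labels is None:
        labels = nx.get_node_attributes(graph, "label")
    cats = sorted({labels[n] for n in graph.nodes})
    idx = {c: i for i, c in enumerate(cats)}
    e = np.zeros((len(cats), len(cats)))
    for u, v in graph.edges:
        i, j = idx[labels[u]], idx[labels[v]]
        e[i, j] += 1.0
        e[j, i] += 1.0
    e /= e.sum()
    a = e.sum(axis=1)
    b = e.sum(axis=0)
    tr = np.trace(e)
    ab = float(a @ b)
    if ab >= 1.0 - 1e-12:
        return 1.0
    return float((tr - ab) / (1.0 - ab))


def relabel_test(
    graph: nx.Graph, reps: int = 100_000, seed: int = 0
) -> tuple[float, float, np.ndarray]:
    """Permutation control: shuffle node labels (preserving label counts) on
    the fixed topology; upper-tail plug-in p for the observed r.

    Returns (observed r, p, null sample).  Relabelings whose r is not
    evaluable never occur here since the edge set is fixed and non-empty.
    """
    labels = nx.get_node_attributes(graph, "label")
    r_obs = assortativity(graph, labels)
    if np.isnan(r_obs):
        raise ValueError("observed assortativity not evaluable (edgeless graph)")
    nodes = list(graph.nodes)
    lab_arr = np.array([labels[n] for n in nodes])
    edges = np.array([(nodes.index(u), nodes.index(v)) for u, v in graph.edges])
    rng = np.random.default_rng(seed)
    null = np.empty(reps)
    for rdx in range(reps):
        perm = rng.permutation(len(nodes))
        null[rdx] = _assort_from_arrays(lab_arr[perm], edges)
    p = float(np.mean(null >= r_obs))
    return r_obs, p, null


def _assort_from_arrays(lab_arr: np.ndarray, edges: np.ndarray) -> float:
    """Nominal r for an edge index array under a label vector (fast path for
    the permutation loop)."""
    cats, codes = np.unique(lab_arr, return_inverse=True)
    k = len(cats)
    ci, cj = codes[edges[:, 0]], codes[edges[:, 1]]
    e = np.zeros((k, k))
    np.add.at(e, (ci, cj), 1.0)
    np.add.at(e, (cj, ci), 1.0)
    e /= e.sum()
    ab = float(e.sum(axis=1) @ e.sum(axis=0))
    if ab >= 1.0 - 1e-12:
        return 1.0
    return float((np.trace(e) - ab) / (1.0 - ab))


def resample_test(
    full_annotation_pool: Mapping[str, set[str]],
    observed_r: float,
    n_nodes: int,
    label_proportion: float,
    threshold: float = JACCARD_THRESHOLD,
    reps: int = 1000,
    seed: int = 0,
) -> tuple[float, int]:
    """Sampling control: per rep, draw ``n_nodes`` proteins from the pool,
    build the Jaccard graph, label nodes at random with ``label_proportion``
    of the first class, and record r.  Upper-tail plug-in p over the
    evaluable reps; returns (p, number of evaluable reps)."""
    accs = sorted(full_annotation_pool)
    if len(accs) < n_nodes:
        raise ValueError("annotation pool smaller than n_nodes")
    rng = np.random.default_rng(seed)
    n_first = int(round(label_proportion * n_nodes))
    null = []
    for _ in range(reps):
        sample = [accs[i] for i in rng.choice(len(accs), size=n_nodes, replace=False)]
        lab = np.array(["MR"] * n_first + ["NonMR"] * (n_nodes - n_first))
        rng.shuffle(lab)
        labels = dict(zip(sample, lab))
        g = build_graph(
            {a: full_annotation_pool[a] for a in sample}, labels, threshold
        )
        r = assortativity(g)
        if np.isnan(r):
            logger.info("resample rep produced an edgeless graph; skipped")
            continue
        null.append(r)
    if not null:
        raise ValueError("no evaluable resampling replicate")
    p = float(np.mean(np.asarray(null) >= observed_r))
    return p, len(null)


def enrichment(
    test_set: set[str],
    reference_set: set[str],
    annotations: Mapping[str, set[str]],
    p_threshold: float = 1e-6,
) -> pd.DataFrame:
    """Per-term hypergeometric enrichment of a test set against a reference.

    For a term annotated to K of N reference proteins and k of n test
    proteins, p is the upper-tail hypergeometric probability of >= k hits;
    Bonferroni multiplies by the number of tested terms (capped at 1);
    fold = (k/n)/(K/N).  Terms never seen in the reference are skipped.
    """
    if not test_set <= reference_set:
        raise ValueError("test_set must be a subset of reference_set")
    N, n = len(reference_set), len(test_set)
    term_ref: dict[str, int] = {}
    term_test: dict[str, int] = {}
    for acc in reference_set:
        for t in annotations.get(acc, set()):
            term_ref[t] = term_ref.get(t, 0) + 1
            if acc in test_set:
                term_test[t] = term_test.get(t, 0) + 1
    n_tested = len(term_ref)
    rows = []
    for term, K in sorted(term_ref.items()):
        k = term_test.get(term, 0)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term": term,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p": p,
                "p_bonferroni": min(1.0, p * n_tested),
                "fold": (k / n) / (K / N) if n else float("nan"),
                "significant": min(1.0, p * n_tested) < p_threshold,
            }
        )
    return pd.DataFrame(rows).sort_values("p", ignore_index=True)
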