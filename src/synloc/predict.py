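"""Consensus candidate prediction and preranked gene-set enrichment.

Three trained models score every brain-expressed gene; genes called
positive (probability >= threshold) by all three form the high-confidence
consensus list, and all genes are ranked by the mean of the three
probabilities.  Enrichment of a reference gene set (e.g. curated synaptic
genes) near the top of that ranking is measured with a weighted
Kolmogorov-Smirnov-style running sum: walking down the ranked list, set
members ("hits") increment the sum by |score|^p normalized over the set,
non-members decrement it by 1/(N - n_set); the enrichment score (ES) is
the signed maximum-magnitude deviation.  Significance comes from random
same-size gene sets (the standard preranked surrogate for phenotype
permutation), with the plus-one correction so p >= 1/(n_permutations+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import models as mod
from .types import FeatureMatrix, GeneSet


@dataclass
class CandidateTable:
    """Per-gene model probabilities, calls, mean probability, consensus."""

    table: pd.DataFrame  # columns p_<name>..., call_<name>..., p_mean, consensus
    model_names: tuple[str, ...]
    threshold: float


@dataclass
class EnrichmentResult:
    es: float
    running_sum: np.ndarray
    nominal_p: float
    n_permutations: int
    leading_edge: list[str]


def consensus_predict(models: list[mod.TrainedModel],
                      features: FeatureMatrix,
                      threshold: float = 0.5,
                      names: list[str] | None = None) -> CandidateTable:
    """Score genes with exactly three models and flag consensus positives."""
    if len(models) != 3:
        raise ValueError("consensus prediction requires exactly 3 models")
    feature_sets = {tuple(m.feature_names) for m in models}
    if len(feature_sets) != 1:
        raise ValueError("models were trained on different feature sets")
    if names is None:
        names = [m.spec.family for m in models]
    if len(set(names)) != 3:
        names = [f"{n}_{i}" for i, n in enumerate(names)]
    cols = {}
    for name, m in zip(names, models):
        cols[f"p_{name}"] = mod.predict_proba(m, features)
    df = pd.DataFrame(cols)
    prob_cols = [f"p_{n}" for n in names]
    for name in names:
        df[f"call_{name}"] = df[f"p_{name}"] >= threshold
    df["p_mean"] = df[prob_cols].mean(axis=1)
    df["consensus"] = df[[f"call_{n}" for n in names]].all(axis=1)
    return CandidateTable(df, tuple(names), threshold)


def rank_candidates(table: CandidateTable) -> pd.Series:
    """Mean probability, descending; ties break by gene ID ascending."""
    df = table.table
    order = sorted(df.index, key=lambda g: (-df.at[g, "p_mean"], g))
    return df.loc[order, "p_mean"]


def _running_sum(scores: np.ndarray, hits: np.ndarray,
                 weight_exponent: float) -> np.ndarray:
    n = len(scores)
    n_hits = int(hits.sum())
    n_miss = n - n_hits
    w = np.abs(scores) ** weight_exponent
    denom = w[hits].sum()
    if denom == 0:
        raise ValueError("zero total hit weight (all set members score 0)")
    inc = np.where(hits, w / denom, 0.0)
    if n_miss:
        inc = inc - np.where(hits, 0.0, 1.0 / n_miss)
    return np.cumsum(inc)


def _es_from_running(running: np.ndarray) -> tuple[float, int]:
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), i


def preranked_enrichment(ranked: pd.Series, gene_set: GeneSet,
                         weight_exponent: float = 1.0,
                         n_permutations: int = 1000,
                         seed: int = 0) -> EnrichmentResult:
    """Weighted running-sum enrichment of a gene set in a ranked list.

    ``ranked``: ranking scores indexed by gene, sorted descending (as
    produced by :func:`rank_candidates`).  The permutation null draws
    random gene sets of the same size from the ranked list.
    """
    genes = np.asarray(ranked.index)
    scores = ranked.to_numpy(dtype=float)
    if np.any(np.diff(scores) > 0):
        raise ValueError("ranked scores must be non-increasing")
    hits = np.isin(genes, list(gene_set.genes))
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("gene set is disjoint from the ranked list")
    running = _running_sum(scores, hits, weight_exponent)
    es, peak = _es_from_running(running)

    hit_positions = np.nonzero(hits)[0]
    if es >= 0:
        leading = genes[hit_positions[hit_positions <= peak]]
    else:
        leading = genes[hit_positions[hit_positions >= peak]]

    rng = np.random.default_rng(seed)
    n = len(genes)
    perm_es = np.empty(n_permutations)
    w = np.abs(scores) ** weight_exponent
    n_miss = n - n_hits
    for b in range(n_permutations):
        idx = rng.choice(n, size=n_hits, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        denom = w[mask].sum()
        if denom == 0:
            perm_es[b] = 0.0
            continue
        inc = np.where(mask, w / denom, -1.0 / n_miss if n_miss else 0.0)
        r = np.cumsum(inc)
        perm_es[b] = r[np.argmax(np.abs(r))]
    if es >= 0:
        same_sign = perm_es[perm_es >= 0]
        extreme = int((same_sign >= es).sum())
    else:
        same_sign = perm_es[perm_es < 0]
        extreme = int((same_sign <= es).sum())
    p = (extreme + 1) / (len(same_sign) + 1)
    return EnrichmentResult(es, running, float(p), n_permutations,
                            list(leading))
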