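"""Feature encoding: UTR k-mer frequencies and expression transforms.

Sequence features are overlapping k-mer counts over the concatenated
5' + 3' UTR, normalized by the concatenated sequence length L (so for an
N-free sequence the frequencies of all 4^k words of one k sum to
(L - k + 1) / L, not 1).  Windows containing an ambiguous base N are
skipped.  Expression features are per-sample log2(RPKM + 1) values.
Both families are min-max scaled against a reference (training) matrix.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    EXPRESSION_KIND,
    SEQUENCE_KIND,
    ExpressionMatrix,
    FeatureMatrix,
    TranscriptSequence,
)

logger = logging.getLogger(__name__)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1}


@dataclass(frozen=True)
class KmerConfig:
    """Which word lengths to count; the DNA alphabet is fixed."""

    ks: tuple[int, ...] = (1, 2, 3)

    def __post_init__(self) -> None:
        if not self.ks:
            raise ValueError("ks must be non-empty")
        if any(k < 1 for k in self.ks):
            raise ValueError("k must be >= 1")

    @property
    def n_features(self) -> int:
        return sum(4 ** k for k in self.ks)

    def feature_names(self) -> list[str]:
        names = []
        for k in self.ks:
            names.extend("".join(p) for p in
                         itertools.product("ACGT", repeat=k))
        return names


def kmer_frequencies(t: TranscriptSequence, cfg: KmerConfig) -> np.ndarray:
    """Overlapping k-mer counts over utr5+utr3, divided by total length L.

    Raises ``ValueError`` for sequences shorter than max(ks) (callers flag
    and exclude such instances).
    """
    seq = t.concatenated
    L = len(seq)
    if L < max(cfg.ks):
        raise ValueError(
            f"transcript {t.transcript_id}: concatenated UTR length {L} "
            f"shorter than max k={max(cfg.ks)}"
        )
    codes = np.fromiter((_CODE[c] for c in seq), dtype=np.int64, count=L)
    out = np.empty(cfg.n_features, dtype=float)
    pos = 0
    for k in cfg.ks:
        windows = np.lib.stride_tricks.sliding_window_view(codes, k)
        valid = (windows >= 0).all(axis=1)
        powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        idx = windows[valid] @ powers
        counts = np.bincount(idx, minlength=4 ** k)
        out[pos:pos + 4 ** k] = counts / L
        pos += 4 ** k
    return out


def kmer_feature_matrix(transcripts: list[TranscriptSequence],
                        cfg: KmerConfig) -> tuple[FeatureMatrix, list[str]]:
    """Per-gene k-mer features; for each gene the transcript with the
    longest CDS supplies the UTRs.  Returns (matrix, flagged gene IDs)."""
    best: dict[str, TranscriptSequence] = {}
    for t in transcripts:
        cur = best.get(t.gene)
        if cur is None or t.cds_length > cur.cds_length:
            best[t.gene] = t
    rows, index, flagged = [], [], []
    for gene, t in best.items():
        try:
            rows.append(kmer_frequencies(t, cfg))
            index.append(gene)
        except ValueError as exc:
            logger.warning("sequence features: %s; gene %s flagged", exc, gene)
            flagged.append(gene)
    names = cfg.feature_names()
    values = pd.DataFrame(np.asarray(rows).reshape(len(index), len(names)),
                          index=index, columns=names)
    kinds = pd.Series(SEQUENCE_KIND, index=names)
    return FeatureMatrix(values, kinds), flagged


def log_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Apply log2(RPKM + 1) cell-wise; shape and metadata preserved."""
    return ExpressionMatrix(np.log2(expr.values + 1.0), expr.samples.copy())


@dataclass
class MinMaxScalerState:
    """Per-feature min and max learned from a reference matrix."""

    mins: pd.Series
    maxs: pd.Series

    def __post_init__(self) -> None:
        if (self.maxs < self.mins).any():
            raise ValueError("max < min in scaler state")


def fit_minmax(reference: FeatureMatrix) -> MinMaxScalerState:
    return MinMaxScalerState(reference.values.min(axis=0),
                             reference.values.max(axis=0))


def apply_minmax(m: FeatureMatrix, s: MinMaxScalerState,
                 clip: bool = True) -> FeatureMatrix:
    """(v - min) / (max - min); constant features map to 0.

    Out-of-range values on non-reference data are clipped to [0, 1] and
    logged.
    """
    if list(m.feature_names) != list(s.mins.index):
        raise ValueError("feature names do not match scaler state")
    span = (s.maxs - s.mins).replace(0.0, np.inf)  # constant feature -> 0
    scaled = (m.values - s.mins) / span
    if clip:
        n_out = int(((scaled < 0) | (scaled > 1)).sum().sum())
        if n_out:
            logger.info("min-max scaling clipped %d out-of-range value(s)",
                        n_out)
        scaled = scaled.clip(0.0, 1.0)
    return FeatureMatrix(scaled, m.kinds.copy())


def expression_feature_matrix(genes: list[str],
                              expr: ExpressionMatrix) -> FeatureMatrix:
    """log2(RPKM+1) expression features, one column per sample."""
    logged = log_transform(expr)
    present = [g for g in genes if g in logged.values.index]
    values = logged.values.loc[present].copy()
    kinds = pd.Series(EXPRESSION_KIND, index=values.columns)
    return FeatureMatrix(values, kinds)


def assemble_features(genes: list[str],
                      transcripts: list[TranscriptSequence] | None,
                      expr: ExpressionMatrix | None,
                      cfg: KmerConfig = KmerConfig(),
                      mode: str = "both") -> FeatureMatrix:
    """Build the per-gene feature matrix for the requested feature family.

    ``mode='both'`` horizontally concatenates sequence and expression
    blocks; only genes with all required inputs are kept (exclusions are
    logged).
    """
    if mode not in ("sequence", "expression", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    genes = list(dict.fromkeys(genes))
    blocks: list[FeatureMatrix] = []
    if mode in ("sequence", "both"):
        if not transcripts:
            raise ValueError("sequence mode requires transcripts")
        seq_fm, _ = kmer_feature_matrix(
            [t for t in transcripts if t.gene in set(genes)], cfg)
        blocks.append(seq_fm)
    if mode in ("expression", "both"):
        if expr is None:
            raise ValueError("expression mode requires an expression matrix")
        blocks.append(expression_feature_matrix(genes, expr))
    keep = [g for g in genes
            if all(g in b.values.index for b in blocks)]
    dropped = [g for g in genes if g not in keep]
    if dropped:
        logger.info("assemble_features(mode=%s): %d gene(s) lacking inputs "
                    "excluded", mode, len(dropped))
    values = pd.concat([b.values.loc[keep] for b in blocks], axis=1)
    kinds = pd.concat([b.kinds for b in blocks])
    return FeatureMatrix(values, kinds)
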