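"""Synthetic inputs emulating the real pipeline's data sources.

The generator produces every input the pipeline consumes — multi-study
localization gene lists with an ortholog map, UTR sequences, a
BrainSpan-style gene x sample RPKM matrix with (age stage, tissue)
metadata, and a reference gene set — with controllable class signal and
full ground-truth bookkeeping, so every module is testable without
downloads.

Expression values are log-normal: per-cell log2 expression is Gaussian
(``baseline_log2``, ``noise_sd``) and RPKM = 2^x - 1 (clipped at 0), so
the RPKM > 1 support filter has nontrivial action at small baselines.
Class signal is planted by shifting positive-class genes by
``effect_size`` log2 units on a contiguous block of (age, tissue) sample
columns, mirroring the early-development cortical signal structure the
importance-grid aggregation is meant to recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .types import (
    ExpressionMatrix,
    GeneSet,
    OrthologMap,
    StudyList,
    TranscriptSequence,
)

_TISSUES = ["OFC", "HIP", "S1C", "V1C", "AMY", "DFC", "MFC", "STC",
            "ITC", "A1C", "M1C", "CBC"]
_AGE_STAGES = ["8 pcw", "12 pcw", "16 pcw", "21 pcw", "35 pcw", "4 mos",
               "2 yrs", "8 yrs", "13 yrs", "21 yrs", "30 yrs", "40 yrs"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic data.

    Defaults give 200 expression features (5 tissues x 8 stages x 5
    samples), 300 positive and 300 negative genes, 20 signal features
    shifted by 2 log2 units — the planted-signal regime the recovery
    experiments use.
    """

    n_positive: int = 300
    n_negative: int = 300
    n_tissues: int = 5
    n_age_stages: int = 8
    samples_per_cell: int = 5
    signal_features: int = 20
    effect_size: float = 2.0
    noise_sd: float = 1.0
    baseline_log2: float = 2.0
    utr_length_range: tuple[int, int] = (100, 500)
    kmer_bias: tuple[tuple[str, float], ...] | None = None
    n_studies_per_label: int = 3
    multi_study_fraction: float = 0.8
    n_contaminants: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_positive, self.n_negative, self.n_tissues,
               self.n_age_stages, self.samples_per_cell) < 1:
            raise ValueError("counts must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        n_samples = self.n_tissues * self.n_age_stages * self.samples_per_cell
        if self.signal_features > n_samples:
            raise ValueError("signal_features exceeds sample count")

    @property
    def n_samples(self) -> int:
        return self.n_tissues * self.n_age_stages * self.samples_per_cell


def _gene_ids(cfg: SimulationConfig) -> tuple[list[str], list[str]]:
    pos = [f"GP{i:05d}" for i in range(cfg.n_positive)]
    neg = [f"GN{i:05d}" for i in range(cfg.n_negative)]
    return pos, neg


def _sample_frame(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    idx = 0
    for age in _AGE_STAGES[:cfg.n_age_stages]:
        for tissue in _TISSUES[:cfg.n_tissues]:
            for _ in range(cfg.samples_per_cell):
                rows.append({"sample_id": f"S{idx:04d}", "age_stage": age,
                             "tissue_code": tissue})
                idx += 1
    return pd.DataFrame(rows).set_index("sample_id")


def signal_sample_ids(cfg: SimulationConfig) -> list[str]:
    """Sample columns carrying the planted class signal.

    The first ``signal_features`` samples in (age, tissue) order — i.e.
    contiguous early-development cells — are the signal block.
    """
    return [f"S{i:04d}" for i in range(cfg.signal_features)]


def simulate_expression(cfg: SimulationConfig
                        ) -> tuple[ExpressionMatrix, pd.Series]:
    """Gene x sample RPKM matrix with class labels (1 = dendritic)."""
    rng = np.random.default_rng(cfg.seed)
    pos, neg = _gene_ids(cfg)
    genes = pos + neg
    samples = _sample_frame(cfg)
    log2 = rng.normal(cfg.baseline_log2, cfg.noise_sd,
                      size=(len(genes), cfg.n_samples))
    sig_cols = [samples.index.get_loc(s) for s in signal_sample_ids(cfg)]
    log2[:len(pos), sig_cols] += cfg.effect_size
    rpkm = np.clip(np.exp2(log2) - 1.0, 0.0, None)
    values = pd.DataFrame(rpkm, index=genes, columns=samples.index)
    labels = pd.Series([1] * len(pos) + [0] * len(neg), index=genes,
                       name="label")
    return ExpressionMatrix(values, samples), labels


def _biased_sequence(rng: np.random.Generator, length: int,
                     bias: dict[str, float]) -> str:
    # multiplicative enrichment via biased emission: before each base,
    # insert k-mer m with probability (factor-1) * 4^-k
    probs = {m: (f - 1.0) * 4.0 ** (-len(m)) for m, f in bias.items()
             if f > 1.0}
    parts: list[str] = []
    n = 0
    alphabet = np.array(list("ACGT"))
    while n < length:
        u = rng.random()
        acc = 0.0
        emitted = False
        for m, p in probs.items():
            acc += p
            if u < acc:
                parts.append(m)
                n += len(m)
                emitted = True
                break
        if not emitted:
            parts.append(str(rng.choice(alphabet)))
            n += 1
    return "".join(parts)[:length]


def simulate_utrs(cfg: SimulationConfig, labels: pd.Series
                  ) -> list[TranscriptSequence]:
    """UTR sequences; positive-class sequences get the configured k-mer bias."""
    rng = np.random.default_rng(cfg.seed + 1)
    lo, hi = cfg.utr_length_range
    bias = dict(cfg.kmer_bias) if cfg.kmer_bias else {}
    alphabet = np.array(list("ACGT"))
    out = []
    for gene, label in labels.items():
        len5 = int(rng.integers(max(1, lo // 3), max(2, hi // 3)))
        len3 = int(rng.integers(lo, hi + 1))
        if label == 1 and bias:
            utr5 = _biased_sequence(rng, len5, bias)
            utr3 = _biased_sequence(rng, len3, bias)
        else:
            utr5 = "".join(rng.choice(alphabet, size=len5))
            utr3 = "".join(rng.choice(alphabet, size=len3))
        cds = int(rng.integers(300, 3000))
        out.append(TranscriptSequence(f"T_{gene}", gene, utr5, utr3, cds))
    return out


def simulate_study_lists(cfg: SimulationConfig, labels: pd.Series
                         ) -> tuple[list[StudyList], list[StudyList],
                                    OrthologMap, dict]:
    """Pseudo-studies in rodent ID space plus the ortholog map.

    Each gene lands in two distinct studies of its label with probability
    ``multi_study_fraction`` (else one study); ``n_contaminants``
    positive multi-study genes are additionally planted into two negative
    studies to exercise the exclusion rule.  Ground truth records which
    human genes are supported by >= 2 studies per label, from the
    assignment bookkeeping (not by re-running the overlap logic).
    """
    rng = np.random.default_rng(cfg.seed + 2)
    omap = OrthologMap()
    pos_genes = list(labels.index[labels == 1])
    neg_genes = list(labels.index[labels == 0])
    n_studies = cfg.n_studies_per_label

    def assign(genes: list[str], prefix: str
               ) -> tuple[list[set[str]], dict[str, int]]:
        buckets: list[set[str]] = [set() for _ in range(n_studies)]
        study_count: dict[str, int] = {}
        for g in genes:
            k = 2 if rng.random() < cfg.multi_study_fraction else 1
            chosen = rng.choice(n_studies, size=k, replace=False)
            for s in chosen:
                src = f"{prefix}{s}_{g}"  # per-study rodent ID, same human gene
                omap.add(src, g)
                buckets[int(s)].add(src)
            study_count[g] = k
        return buckets, study_count

    pos_buckets, pos_counts = assign(pos_genes, "rp")
    neg_buckets, neg_counts = assign(neg_genes, "rn")

    multi_pos = sorted(g for g, c in pos_counts.items() if c >= 2)
    contaminants = multi_pos[:cfg.n_contaminants]
    for g in contaminants:
        for s in rng.choice(n_studies, size=2, replace=False):
            src = f"rc{s}_{g}"
            omap.add(src, g)
            neg_buckets[int(s)].add(src)

    # orphan rodent IDs with no ortholog entry: dropped by mapping
    for s in range(n_studies):
        pos_buckets[s].add(f"orphan_p{s}")
        neg_buckets[s].add(f"orphan_n{s}")

    pos_studies = [StudyList(f"study_pos{s}", "dendritic",
                             frozenset(pos_buckets[s]))
                   for s in range(n_studies)]
    neg_studies = [StudyList(f"study_neg{s}", "somatic",
                             frozenset(neg_buckets[s]))
                   for s in range(n_studies)]
    planted_pos = set(multi_pos)
    planted_neg = {g for g, c in neg_counts.items() if c >= 2}
    truth = {
        "planted_positive": sorted(planted_pos),
        "planted_negative": sorted(planted_neg),
        "contaminants": sorted(contaminants),
        "n_planted_positive": len(planted_pos),
        "n_planted_negative": len(planted_neg),
    }
    return pos_studies, neg_studies, omap, truth


def simulate_gene_set(cfg: SimulationConfig, labels: pd.Series,
                      name: str = "synaptic_reference") -> GeneSet:
    """Reference gene set: the true dendritic genes plus decoys."""
    rng = np.random.default_rng(cfg.seed + 3)
    pos = list(labels.index[labels == 1])
    neg = list(labels.index[labels == 0])
    n_decoys = max(1, len(pos) // 10)
    decoys = rng.choice(neg, size=min(n_decoys, len(neg)), replace=False)
    return GeneSet(name, frozenset(pos) | frozenset(decoys),
                   "simulated synaptic reference set")


@dataclass
class SimulatedData:
    config: SimulationConfig
    expression: ExpressionMatrix
    labels: pd.Series
    transcripts: list[TranscriptSequence]
    positive_studies: list[StudyList]
    negative_studies: list[StudyList]
    orthologs: OrthologMap
    gene_set: GeneSet
    ground_truth: dict


def simulate_all(cfg: SimulationConfig) -> SimulatedData:
    expr, labels = simulate_expression(cfg)
    transcripts = simulate_utrs(cfg, labels)
    pos_st, neg_st, omap, truth = simulate_study_lists(cfg, labels)
    gene_set = simulate_gene_set(cfg, labels)
    truth = dict(truth)
    truth["signal_samples"] = signal_sample_ids(cfg)
    return SimulatedData(cfg, expr, labels, transcripts, pos_st, neg_st,
                         omap, gene_set, truth)


def write_fixtures(data: SimulatedData, outdir: str | Path) -> dict[str, str]:
    """Write every simulated input as plain-text files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    sio.write_expression_matrix(data.expression,
                                outdir / "expression.tsv",
                                outdir / "samples.tsv")
    paths["expression"] = str(outdir / "expression.tsv")
    paths["samples"] = str(outdir / "samples.tsv")

    sio.write_utr_fasta(data.transcripts, outdir / "utrs.fasta")
    paths["utrs"] = str(outdir / "utrs.fasta")

    for st in data.positive_studies + data.negative_studies:
        p = outdir / f"{st.study_id}.txt"
        p.write_text("".join(f"{g}\n" for g in sorted(st.genes)))
        paths[st.study_id] = str(p)

    with open(outdir / "orthologs.tsv", "w") as fh:
        for src, dsts in data.orthologs.items():
            for dst in sorted(dsts):
                fh.write(f"{src}\t{dst}\n")
    paths["orthologs"] = str(outdir / "orthologs.tsv")

    sio.write_gmt([data.gene_set], outdir / "gene_sets.gmt")
    paths["gene_sets"] = str(outdir / "gene_sets.gmt")

    sio.write_labels(data.labels, outdir / "labels.tsv")
    paths["labels"] = str(outdir / "labels.tsv")

    (outdir / "ground_truth.json").write_text(
        json.dumps(data.ground_truth, indent=1))
    paths["ground_truth"] = str(outdir / "ground_truth.json")
    return paths
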