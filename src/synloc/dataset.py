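"""Compilation of labeled training instances from multi-study gene lists.

The pipeline mirrors how dendritic/somatic RNA catalogues are built from
several rodent profiling studies: map every study's genes to human
orthologs, keep genes supported by at least two independent studies,
remove from the somatic (negative) list anything that also appears among
the dendritic (positive) candidates, and finally require detectable brain
expression (RPKM above a threshold in a minimum fraction of samples).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .types import (
    ExpressionMatrix,
    FeatureMatrix,
    LabeledDataset,
    OrthologMap,
    StudyList,
)

logger = logging.getLogger(__name__)


@dataclass
class CompilationReport:
    """Bookkeeping for one dataset build."""

    per_study_mapped: dict[str, int] = field(default_factory=dict)
    per_study_unmapped: dict[str, int] = field(default_factory=dict)
    overlap_counts: dict[str, int] = field(default_factory=dict)
    n_positive_before_filter: int = 0
    n_negative_before_filter: int = 0
    n_positive_after_filter: int = 0
    n_negative_after_filter: int = 0
    n_positive_unfeaturized: int = 0
    n_negative_unfeaturized: int = 0

    def to_dict(self) -> dict:
        return {
            "per_study_mapped": self.per_study_mapped,
            "per_study_unmapped": self.per_study_unmapped,
            "overlap_counts": self.overlap_counts,
            "n_positive_before_filter": self.n_positive_before_filter,
            "n_negative_before_filter": self.n_negative_before_filter,
            "n_positive_after_filter": self.n_positive_after_filter,
            "n_negative_after_filter": self.n_negative_after_filter,
            "n_positive_unfeaturized": self.n_positive_unfeaturized,
            "n_negative_unfeaturized": self.n_negative_unfeaturized,
        }


def map_to_human(study: StudyList, orthologs: OrthologMap,
                 report: CompilationReport | None = None) -> StudyList:
    """Replace a study's genes with the union of their human orthologs.

    One-to-many orthology expands (union semantics); unmapped genes are
    dropped with a warning and counted in the report.
    """
    mapped: set[str] = set()
    n_unmapped = 0
    for g in study.genes:
        hits = orthologs.lookup(g)
        if hits:
            mapped |= hits
        else:
            n_unmapped += 1
    if n_unmapped:
        logger.warning("study %s: %d gene(s) without human ortholog dropped",
                       study.study_id, n_unmapped)
    if report is not None:
        report.per_study_mapped[study.study_id] = len(mapped)
        report.per_study_unmapped[study.study_id] = n_unmapped
    return StudyList(study.study_id, study.label, frozenset(mapped))


def select_by_overlap(studies: list[StudyList], label: str,
                      min_studies: int = 2) -> set[str]:
    """Genes reported by at least ``min_studies`` distinct studies.

    Within a study a gene counts once (set semantics).
    """
    if min_studies < 1:
        raise ValueError("min_studies must be >= 1")
    if len(studies) < min_studies:
        raise ValueError(
            f"need at least {min_studies} studies, got {len(studies)}"
        )
    mismatched = [s.study_id for s in studies if s.label != label]
    if mismatched:
        raise ValueError(f"studies with wrong label: {mismatched}")
    counts: dict[str, int] = {}
    for s in studies:
        for g in s.genes:
            counts[g] = counts.get(g, 0) + 1
    return {g for g, c in counts.items() if c >= min_studies}


def exclude_positives(negatives: set[str], positives: set[str]) -> set[str]:
    """Remove any candidate negatives that overlap the positive list."""
    return set(negatives) - set(positives)


def filter_by_expression_support(genes: set[str], expr: ExpressionMatrix,
                                 rpkm_threshold: float = 1.0,
                                 min_sample_fraction: float = 0.01
                                 ) -> set[str]:
    """Keep genes with RPKM strictly above threshold in enough samples.

    A gene is retained iff it exceeds ``rpkm_threshold`` in at least
    ``ceil(min_sample_fraction * n_samples)`` samples (minimum one sample).
    Genes absent from the matrix are dropped and counted.
    """
    if rpkm_threshold <= 0 or min_sample_fraction <= 0:
        raise ValueError("thresholds must be positive")
    n_samples = expr.n_samples()
    need = max(1, math.ceil(min_sample_fraction * n_samples))
    present = [g for g in genes if g in expr.values.index]
    n_absent = len(genes) - len(present)
    if n_absent:
        logger.info("expression filter: %d gene(s) absent from matrix dropped",
                    n_absent)
    if not present:
        return set()
    sub = expr.values.loc[present]
    support = (sub > rpkm_threshold).sum(axis=1)
    return set(support.index[support >= need])


def build_labeled_dataset(positives: set[str], negatives: set[str],
                          features: FeatureMatrix,
                          report: CompilationReport | None = None
                          ) -> tuple[LabeledDataset, CompilationReport]:
    """Assemble the final dataset over featurized genes.

    Instances are ``(positives | negatives)`` intersected with the feature
    matrix's rows; positives get label 1.  Genes in both input sets are a
    caller error.
    """
    overlap = set(positives) & set(negatives)
    if overlap:
        raise ValueError(f"genes labeled both positive and negative: "
                         f"{sorted(overlap)[:10]}")
    if report is None:
        report = CompilationReport()
    featurized = set(features.instances)
    pos = sorted(set(positives) & featurized)
    neg = sorted(set(negatives) & featurized)
    report.n_positive_unfeaturized = len(positives) - len(pos)
    report.n_negative_unfeaturized = len(negatives) - len(neg)
    if report.n_positive_unfeaturized or report.n_negative_unfeaturized:
        logger.info("dataset build: %d positive / %d negative gene(s) lacked "
                    "features and were excluded",
                    report.n_positive_unfeaturized,
                    report.n_negative_unfeaturized)
    if not pos or not neg:
        raise ValueError("a class is empty after assembly")
    order = pos + neg
    fm = FeatureMatrix(features.values.loc[order].copy(),
                       features.kinds.copy())
    labels = pd.Series([1] * len(pos) + [0] * len(neg), index=order,
                       name="label")
    report.n_positive_after_filter = len(pos)
    report.n_negative_after_filter = len(neg)
    dataset = LabeledDataset(fm, labels)
    assert set(labels[labels == 1].index).isdisjoint(labels[labels == 0].index)
    return dataset, report


def compile_instances(positive_studies: list[StudyList],
                      negative_studies: list[StudyList],
                      orthologs: OrthologMap,
                      expr: ExpressionMatrix,
                      min_studies: int = 2,
                      rpkm_threshold: float = 1.0,
                      min_sample_fraction: float = 0.01
                      ) -> tuple[set[str], set[str], CompilationReport]:
    """Full compilation: ortholog mapping -> overlap -> exclusion -> filter.

    Returns the final positive and negative gene sets plus a report.
    """
    report = CompilationReport()
    pos_mapped = [map_to_human(s, orthologs, report) for s in positive_studies]
    neg_mapped = [map_to_human(s, orthologs, report) for s in negative_studies]
    positives = select_by_overlap(pos_mapped, "dendritic", min_studies)
    negatives_raw = select_by_overlap(neg_mapped, "somatic", min_studies)
    negatives = exclude_positives(negatives_raw, positives)
    report.overlap_counts = {"dendritic": len(positives),
                             "somatic": len(negatives_raw),
                             "somatic_after_exclusion": len(negatives)}
    report.n_positive_before_filter = len(positives)
    report.n_negative_before_filter = len(negatives)
    positives = filter_by_expression_support(
        positives, expr, rpkm_threshold, min_sample_fraction)
    negatives = filter_by_expression_support(
        negatives, expr, rpkm_threshold, min_sample_fraction)
    report.n_positive_after_filter = len(positives)
    report.n_negative_after_filter = len(negatives)
    return positives, negatives, report
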