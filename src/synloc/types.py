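"""Core domain containers shared across the pipeline.

Gene identifiers are opaque strings.  Version suffixes (``ENSG...\\.5``) are
stripped on ingest because instance compilation intersects gene sets from
several sources and versioned identifiers would silently break equality.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

_VERSION_SUFFIX = re.compile(r"\.\d+$")

POSITIVE_LABEL = "dendritic"
NEGATIVE_LABEL = "somatic"
VALID_LABELS = frozenset({POSITIVE_LABEL, NEGATIVE_LABEL})


def normalize_gene_id(raw: str) -> str:
    """Trim whitespace and strip a trailing ``.N`` version suffix.

    Raises ``ValueError`` on empty tokens or internal whitespace.
    """
    token = raw.strip()
    if not token:
        raise ValueError("empty gene identifier")
    if any(ch.isspace() for ch in token):
        raise ValueError(f"gene identifier contains whitespace: {raw!r}")
    return _VERSION_SUFFIX.sub("", token)


@dataclass(frozen=True)
class StudyList:
    """One study's dendritic or somatic gene list (set semantics)."""

    study_id: str
    label: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(
                f"label must be one of {sorted(VALID_LABELS)}, got {self.label!r}"
            )


class OrthologMap:
    """Many-to-many mapping from source (e.g. rodent) to human gene IDs.

    Lookups of unmapped identifiers return the empty set.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()) -> None:
        self._map: dict[str, set[str]] = {}
        for src, dst in pairs:
            self.add(src, dst)

    def add(self, source: str, human: str) -> None:
        self._map.setdefault(normalize_gene_id(source), set()).add(
            normalize_gene_id(human)
        )

    def lookup(self, source: str) -> frozenset[str]:
        return frozenset(self._map.get(normalize_gene_id(source), ()))

    def items(self) -> list[tuple[str, frozenset[str]]]:
        return [(s, frozenset(d)) for s, d in sorted(self._map.items())]

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, source: str) -> bool:
        return normalize_gene_id(source) in self._map


@dataclass
class TranscriptSequence:
    """UTR sequences for one transcript of a gene.

    ``cds_length`` disambiguates which transcript represents a gene: the one
    with the longest coding sequence supplies the UTRs.
    """

    transcript_id: str
    gene: str
    utr5: str = ""
    utr3: str = ""
    cds_length: int = 0

    @property
    def concatenated(self) -> str:
        return self.utr5 + self.utr3


@dataclass(frozen=True)
class SampleAnnotation:
    """Metadata for one expression sample: developmental stage and tissue."""

    sample_id: str
    age_stage: str
    tissue_code: str


@dataclass
class ExpressionMatrix:
    """Gene x sample RPKM (or transformed) values plus sample metadata.

    ``values``: DataFrame indexed by gene, columns = sample IDs.
    ``samples``: DataFrame indexed by sample_id with columns
    ``age_stage`` and ``tissue_code``, row order matching the columns.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("sample order of values and metadata disagree")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing cells")
        for col in ("age_stage", "tissue_code"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_annotations(self) -> list[SampleAnnotation]:
        return [
            SampleAnnotation(s, row["age_stage"], row["tissue_code"])
            for s, row in self.samples.iterrows()
        ]

    def n_samples(self) -> int:
        return self.values.shape[1]


SEQUENCE_KIND = "sequence"
EXPRESSION_KIND = "expression"


@dataclass
class FeatureMatrix:
    """Instances x named features with per-feature provenance tags.

    ``kinds`` maps each feature name to ``sequence`` or ``expression``.
    """

    values: pd.DataFrame
    kinds: pd.Series

    def __post_init__(self) -> None:
        names = list(self.values.columns)
        if len(names) != len(set(names)):
            raise ValueError("feature names are not unique")
        if list(self.kinds.index) != names:
            raise ValueError("feature kinds do not align with feature names")
        bad = set(self.kinds) - {SEQUENCE_KIND, EXPRESSION_KIND}
        if bad:
            raise ValueError(f"unknown feature kinds: {sorted(bad)}")

    @property
    def instances(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def subset_features(self, names: Iterable[str]) -> "FeatureMatrix":
        names = list(names)
        return FeatureMatrix(self.values[names].copy(), self.kinds[names].copy())


@dataclass
class LabeledDataset:
    """Feature matrix plus binary labels (1 = dendritic, 0 = somatic)."""

    features: FeatureMatrix
    labels: pd.Series

    def __post_init__(self) -> None:
        if list(self.labels.index) != self.features.instances:
            raise ValueError("labels do not align with feature instances")
        if len(self.labels) == 0:
            raise ValueError("empty dataset")
        vals = set(self.labels.unique().tolist())
        if not vals <= {0, 1}:
            raise ValueError(f"labels must be 0/1, got {sorted(vals)}")
        # single-class sets are tolerated (independent-test edge case);
        # training rejects them in models.train

    @property
    def n_positive(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_negative(self) -> int:
        return int((self.labels == 0).sum())

    def subset_instances(self, ids: Iterable[str]) -> "LabeledDataset":
        ids = list(ids)
        fm = FeatureMatrix(
            self.features.values.loc[ids].copy(), self.features.kinds.copy()
        )
        return LabeledDataset(fm, self.labels.loc[ids].copy())


@dataclass(frozen=True)
class GeneSet:
    """Named set of genes, e.g. curated synaptic genes for enrichment."""

    name: str
    genes: frozenset[str]
    description: str = ""
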