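"""Readers and writers for the plain-text formats the pipeline consumes.

Formats
-------
* gene lists: one ID per line, ``#`` comments allowed
* ortholog map: two-column TSV, source ID -> human ID (many-to-many)
* UTR FASTA dialect: headers ``>transcript_id|gene_id|utr5`` or ``...|utr3``,
  optionally a fourth ``cds=<nt>`` field carrying the coding-sequence length
* expression: values TSV (gene rows x sample columns) + sample metadata TSV
  with columns ``sample_id``, ``age_stage``, ``tissue_code``
* feature matrices: values TSV + sidecar JSON of feature kinds
* gene sets: GMT (name, description, member genes per tab-separated line)

Ingest never silently drops data: every skipped record is logged with a
reason.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO

from .types import (
    EXPRESSION_KIND,
    SEQUENCE_KIND,
    ExpressionMatrix,
    FeatureMatrix,
    GeneSet,
    OrthologMap,
    StudyList,
    TranscriptSequence,
    normalize_gene_id,
)

logger = logging.getLogger(__name__)

_SEQ_ALPHABET = set("ACGTUN")


def read_gene_list(path: str | Path, study_id: str | None = None,
                   label: str = "dendritic") -> StudyList:
    """Read a one-ID-per-line gene list into a deduplicated study list."""
    path = Path(path)
    genes: list[str] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        genes.append(normalize_gene_id(line))
    if not genes:
        raise ValueError(f"empty gene list: {path}")
    unique = frozenset(genes)
    n_dup = len(genes) - len(unique)
    if n_dup:
        logger.info("%s: %d duplicate line(s) collapsed", path.name, n_dup)
    return StudyList(study_id or path.stem, label, unique)


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a two-column TSV of source -> human gene ID pairs."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"ortholog map needs two columns: {path}")
    omap = OrthologMap()
    for src, dst in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if pd.isna(src) or pd.isna(dst):
            continue
        omap.add(src, dst)
    return omap


def _normalize_sequence(seq: str, record_id: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _SEQ_ALPHABET
    if bad:
        raise ValueError(
            f"record {record_id!r} contains invalid characters {sorted(bad)}"
        )
    return seq.replace("U", "T")


def read_utr_fasta(path: str | Path,
                   id_map: Mapping[str, str] | None = None
                   ) -> list[TranscriptSequence]:
    """Read UTR sequences in the ``>transcript|gene|utr5`` dialect.

    ``id_map`` (transcript -> gene) supplies the gene when the header has
    only two fields (``>transcript|utr5``).  Transcripts with no resolvable
    gene are skipped with a warning.  Two records (utr5 + utr3) for one
    transcript merge into a single :class:`TranscriptSequence`.
    """
    by_transcript: dict[str, TranscriptSequence] = {}
    order: list[str] = []
    for record in SeqIO.parse(str(path), "fasta"):
        fields = record.id.split("|")
        cds_length = 0
        for extra in fields[2:]:
            if extra.startswith("cds="):
                cds_length = int(extra[4:])
        if len(fields) >= 2 and fields[1] in ("utr5", "utr3"):
            transcript_id, which = fields[0], fields[1]
            gene = id_map.get(transcript_id) if id_map else None
        elif len(fields) >= 3 and fields[2] in ("utr5", "utr3"):
            transcript_id, gene, which = fields[0], fields[1], fields[2]
            if id_map and transcript_id in id_map:
                gene = id_map[transcript_id]
        else:
            raise ValueError(
                f"malformed UTR FASTA header {record.id!r}: expected "
                "'transcript|gene|utr5' or 'transcript|utr3'"
            )
        if not gene:
            logger.warning("transcript %s has no gene mapping; skipped",
                           transcript_id)
            continue
        seq = _normalize_sequence(str(record.seq), record.id)
        if transcript_id not in by_transcript:
            by_transcript[transcript_id] = TranscriptSequence(
                transcript_id, normalize_gene_id(gene), cds_length=cds_length
            )
            order.append(transcript_id)
        ts = by_transcript[transcript_id]
        if cds_length:
            ts.cds_length = cds_length
        if which == "utr5":
            ts.utr5 += seq
        else:
            ts.utr3 += seq
    return [by_transcript[t] for t in order]


def write_utr_fasta(transcripts: list[TranscriptSequence],
                    path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            header = f"{t.transcript_id}|{t.gene}"
            if t.cds_length:
                header += f"|{{which}}|cds={t.cds_length}"
            else:
                header += "|{which}"
            if t.utr5:
                fh.write(f">{header.format(which='utr5')}\n{t.utr5}\n")
            if t.utr3:
                fh.write(f">{header.format(which='utr3')}\n{t.utr3}\n")


def read_expression_matrix(values_path: str | Path,
                           samples_path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample RPKM TSV plus a sample-metadata TSV."""
    values = pd.read_csv(values_path, sep="\t", index_col=0,
                         float_precision="round_trip")
    samples = pd.read_csv(samples_path, sep="\t", dtype=str)
    if "sample_id" not in samples.columns:
        raise ValueError(f"sample metadata lacks 'sample_id': {samples_path}")
    samples = samples.set_index("sample_id")

    value_cols = list(values.columns)
    meta_rows = list(samples.index)
    missing_meta = sorted(set(value_cols) - set(meta_rows))
    missing_vals = sorted(set(meta_rows) - set(value_cols))
    if missing_meta or missing_vals:
        raise ValueError(
            "sample mismatch between values and metadata: "
            f"absent from metadata {missing_meta}; absent from values {missing_vals}"
        )
    samples = samples.loc[value_cols]
    if values.isna().any().any():
        raise ValueError(f"missing expression cells in {values_path}")
    if (values.to_numpy() < 0).any():
        raise ValueError(f"negative expression value in {values_path}")
    values.index = [normalize_gene_id(g) for g in values.index]
    logger.info("read expression matrix: %d genes x %d samples", *values.shape)
    return ExpressionMatrix(values, samples)


def write_expression_matrix(expr: ExpressionMatrix, values_path: str | Path,
                            samples_path: str | Path) -> None:
    expr.values.to_csv(values_path, sep="\t", index_label="gene",
                       float_format="%.17g")
    expr.samples.to_csv(samples_path, sep="\t", index_label="sample_id")


def write_feature_matrix(fm: FeatureMatrix, values_path: str | Path,
                         sidecar_path: str | Path | None = None) -> None:
    """Write values as TSV and feature kinds as a sidecar JSON."""
    fm.values.to_csv(values_path, sep="\t", index_label="instance",
                     float_format="%.17g")
    if sidecar_path is None:
        sidecar_path = Path(values_path).with_suffix(".json")
    payload = {"feature_kinds": fm.kinds.to_dict(),
               "feature_order": fm.feature_names}
    Path(sidecar_path).write_text(json.dumps(payload, indent=1))


def read_feature_matrix(values_path: str | Path,
                        sidecar_path: str | Path | None = None
                        ) -> FeatureMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0,
                         float_precision="round_trip")
    values.index = values.index.astype(str)
    if sidecar_path is None:
        sidecar_path = Path(values_path).with_suffix(".json")
    sidecar_path = Path(sidecar_path)
    if sidecar_path.exists():
        payload = json.loads(sidecar_path.read_text())
        order = payload["feature_order"]
        values = values[order]
        kinds = pd.Series({k: payload["feature_kinds"][k] for k in order})
    else:
        # no sidecar: assume expression provenance
        kinds = pd.Series(EXPRESSION_KIND, index=values.columns)
    return FeatureMatrix(values, kinds)


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column TSV of instance ID and 0/1 label."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    series = df.iloc[:, 0].astype(int)
    series.index = series.index.astype(str)
    return series


def write_labels(labels: pd.Series, path: str | Path) -> None:
    labels.rename("label").to_csv(path, sep="\t", index_label="instance")


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets: list[GeneSet] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line needs name, description, >=1 gene: {line!r}")
        genes = frozenset(normalize_gene_id(g) for g in fields[2:] if g.strip())
        sets.append(GeneSet(fields[0], genes, fields[1]))
    if not sets:
        raise ValueError(f"empty GMT file: {path}")
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            members = "\t".join(sorted(gs.genes))
            fh.write(f"{gs.name}\t{gs.description}\t{members}\n")
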