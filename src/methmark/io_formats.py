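"""Reading, writing and validation of the pipeline's on-disk artifacts.

The central container is :class:`BetaMatrix`: a probes x samples matrix of
methylation fractions (beta-values) together with a matched matrix of
detection p-values and a sample -> entity assignment.  A beta-value is the
ratio of methylated probe signal to total (methylated + unmethylated)
signal, so it lives in [0, 1]; a detection p-value quantifies whether the
probe signal is distinguishable from array background.

All tabular artifacts are plain tab-delimited text: the beta and detection
matrices have probes in rows and a header row of sample ids, the sample
sheet maps sample_id -> entity, and the probe annotation carries gene
symbol, CpG-island flag and genomic coordinate per probe.  Missing values
are written as ``NA``; empty cells and ``NA`` are both accepted on input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "LabelingError",
    "BetaMatrix",
    "compute_beta",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_probe_annotation",
    "write_result_table",
    "read_fasta",
    "write_fasta",
]

NA_VALUES = ["", "NA"]

ANNOTATION_COLUMNS = ["probe_id", "gene_symbol", "cpg_island", "chrom", "pos", "strand"]


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


class ValidationError(ValueError):
    """Values violate a domain invariant (e.g. beta outside [0, 1])."""


class LabelingError(ValueError):
    """Samples and the sample sheet disagree."""


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions with detection p-values.

    Parameters
    ----------
    beta
        DataFrame of methylation fractions in [0, 1], probes in rows,
        samples in columns.  NaN marks a missing measurement.
    detection_p
        DataFrame of detection p-values with the same index/columns as
        ``beta``.  An all-NaN frame means no detection information is
        available and detection-based QC is skipped downstream.
    entity_of
        Series mapping every sample id to its entity label
        (e.g. CCSK, RTK, ESFT, NK).
    reference
        The entity label acting as the non-neoplastic reference
        (default ``"NK"``).
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame
    entity_of: pd.Series
    reference: str = "NK"

    def __post_init__(self) -> None:
        if self.beta.shape[1] == 0:
            raise ValidationError("beta matrix has no samples")
        if not self.beta.index.is_unique:
            raise ValidationError("duplicate probe ids in beta matrix")
        if not self.beta.columns.is_unique:
            raise ValidationError("duplicate sample ids in beta matrix")
        if self.detection_p is None:
            self.detection_p = pd.DataFrame(
                np.nan, index=self.beta.index, columns=self.beta.columns
            )
        if self.detection_p.shape != self.beta.shape or not (
            self.detection_p.index.equals(self.beta.index)
            and self.detection_p.columns.equals(self.beta.columns)
        ):
            raise FormatError(
                "detection p-value matrix dimensions do not match beta matrix "
                f"({self.detection_p.shape} vs {self.beta.shape})"
            )
        bad = _out_of_unit_interval(self.beta)
        if bad:
            probe, sample = bad[0]
            raise ValidationError(
                f"beta value outside [0, 1] at probe {probe!r}, sample {sample!r}"
            )
        bad_p = _out_of_unit_interval(self.detection_p)
        if bad_p:
            probe, sample = bad_p[0]
            raise ValidationError(
                f"detection p-value outside [0, 1] at probe {probe!r}, sample {sample!r}"
            )
        missing = [s for s in self.beta.columns if s not in self.entity_of.index]
        if missing:
            raise LabelingError(
                f"samples absent from sample sheet: {', '.join(map(str, missing))}"
            )
        self.entity_of = self.entity_of.loc[list(self.beta.columns)]

    # -- convenience accessors -------------------------------------------------

    @property
    def probe_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def entities(self) -> list[str]:
        """Entity labels in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.beta.columns:
            seen.setdefault(self.entity_of[s], None)
        return list(seen)

    @property
    def tumor_entities(self) -> list[str]:
        return [e for e in self.entities if e != self.reference]

    def samples_of(self, entity: str) -> list[str]:
        return [s for s in self.beta.columns if self.entity_of[s] == entity]

    @property
    def has_detection(self) -> bool:
        return bool(self.detection_p.notna().any().any())

    def subset_probes(self, probe_ids: Iterable[str]) -> "BetaMatrix":
        """Return a new matrix restricted to ``probe_ids``, order preserved."""
        idx = [p for p in self.beta.index if p in set(probe_ids)]
        return BetaMatrix(
            beta=self.beta.loc[idx].copy(),
            detection_p=self.detection_p.loc[idx].copy(),
            entity_of=self.entity_of.copy(),
            reference=self.reference,
        )


def _out_of_unit_interval(frame: pd.DataFrame) -> list[tuple[str, str]]:
    arr = frame.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        mask = (arr < 0.0) | (arr > 1.0)
    rows, cols = np.nonzero(mask)
    return [(frame.index[r], frame.columns[c]) for r, c in zip(rows, cols)]


def compute_beta(m_signal: float, u_signal: float) -> float:
    """Methylation fraction from methylated / unmethylated signal intensities.

    Returns ``m / (m + u)``; NaN when both signals are zero (undefined
    ratio).  No background offset is added to the denominator: the value
    is the plain intensity ratio.
    """
    if m_signal < 0 or u_signal < 0:
        raise ValidationError(
            f"signal intensities must be non-negative (got {m_signal}, {u_signal})"
        )
    total = m_signal + u_signal
    if total == 0:
        return math.nan
    return m_signal / total


def _read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        na_values=NA_VALUES,
        keep_default_na=False,
    )
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: could not parse numeric matrix ({exc})") from exc
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return frame


def read_samplesheet(path: str | Path) -> pd.Series:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "entity"):
        if col not in sheet.columns:
            raise FormatError(f"{path}: sample sheet lacks required column {col!r}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{path}: duplicate sample id {dup!r} in sample sheet")
    return pd.Series(
        sheet["entity"].to_numpy(), index=sheet["sample_id"].to_numpy(), name="entity"
    )


def read_beta_matrix(
    beta_path: str | Path,
    samplesheet_path: str | Path,
    detection_path: str | Path | None = None,
    reference: str = "NK",
) -> BetaMatrix:
    """Load a beta matrix, optional detection p-value matrix and sample sheet.

    The two matrices must agree exactly in probe and sample ids.  When
    ``detection_path`` is omitted the detection matrix is all-missing and
    detection-p QC is skipped downstream.
    """
    beta = _read_matrix_tsv(beta_path)
    if detection_path is not None:
        detection = _read_matrix_tsv(detection_path)
        if detection.shape != beta.shape or not (
            detection.index.equals(beta.index) and detection.columns.equals(beta.columns)
        ):
            raise FormatError(
                f"{detection_path}: dimensions/ids do not match beta matrix {beta_path}"
            )
    else:
        detection = pd.DataFrame(np.nan, index=beta.index, columns=beta.columns)
    entity_of = read_samplesheet(samplesheet_path)
    return BetaMatrix(
        beta=beta, detection_p=detection, entity_of=entity_of, reference=reference
    )


def write_beta_matrix(
    matrix: BetaMatrix,
    beta_path: str | Path,
    samplesheet_path: str | Path,
    detection_path: str | Path | None = None,
    precision: int = 6,
) -> None:
    """Write a BetaMatrix back to disk; inverse of :func:`read_beta_matrix`.

    Values are formatted with ``precision`` decimals, so a write/read
    round trip reproduces values exactly at that precision.
    """
    fmt = f"%.{precision}g"
    matrix.beta.to_csv(beta_path, sep="\t", na_rep="NA", float_format=fmt)
    if detection_path is not None:
        matrix.detection_p.to_csv(detection_path, sep="\t", na_rep="NA", float_format=fmt)
    sheet = pd.DataFrame(
        {"sample_id": matrix.sample_ids, "entity": matrix.entity_of.to_numpy()}
    )
    sheet.to_csv(samplesheet_path, sep="\t", index=False)


def read_probe_annotation(path: str | Path) -> pd.DataFrame:
    """Load a probe annotation table, indexed by probe_id.

    Required columns: probe_id, gene_symbol, cpg_island (0/1), chrom, pos
    (1-based coordinate of the interrogated CpG's C), strand.  One gene
    symbol per probe; multi-gene manifests must be pre-collapsed.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, na_values=NA_VALUES, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: annotation lacks required columns {missing}")
    if table["probe_id"].duplicated().any():
        dup = table.loc[table["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise FormatError(f"{path}: duplicated probe_id {dup!r}")
    table = table.set_index("probe_id")
    table["cpg_island"] = table["cpg_island"].map({"0": False, "1": True})
    if table["cpg_island"].isna().any():
        raise FormatError(f"{path}: cpg_island column must be 0/1")
    table["pos"] = table["pos"].astype(int)
    if (table["pos"] < 1).any():
        raise ValidationError(f"{path}: positions must be >= 1 (1-based coordinates)")
    return table


def annotate_probes(
    probe_ids: Iterable[str], annotation: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Join probe ids against an annotation; report unannotated ids."""
    ids = list(probe_ids)
    known = [p for p in ids if p in annotation.index]
    unannotated = [p for p in ids if p not in annotation.index]
    return annotation.loc[known], unannotated


def write_result_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as deterministic, tab-delimited UTF-8 text.

    Columns keep their given order; the same input always yields
    byte-identical output.
    """
    table.to_csv(path, sep="\t", index=False, na_rep="NA", encoding="utf-8", lineterminator="\n")


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    out = annotation.copy()
    out["cpg_island"] = out["cpg_island"].astype(int)
    out.index.name = "probe_id"
    out.reset_index().to_csv(path, sep="\t", index=False)


# -- FASTA --------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    seqrecs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    SeqIO.write(seqrecs, str(path), "fasta")
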