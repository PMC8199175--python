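"""Expression-matrix container, TSV IO, normalization, and detection calls.

The substrate of the whole pipeline is a miRNA × sample matrix of small
RNA-seq read counts (or RPM after normalization) together with per-sample
metadata: sample group (FL = fetal lung, ANL = adult non-neoplastic lung,
LUAD = lung adenocarcinoma), cohort (discovery / validation), patient id
(for collapsing replicate libraries) and total mapped reads (for the
sequencing-depth filter).

Processing conventions:

* samples with fewer than 5 million reads are dropped before anything else;
* replicate libraries of one patient are collapsed by averaging raw counts;
* RPM = count / (sample's total miRNA-assigned reads, i.e. column sum) × 1e6 —
  normalization is self-contained in the matrix; the ``total_reads`` metadata
  is used only for the depth filter;
* a miRNA is "expressed" in a sample group when ≥10% of the group's samples
  have ≥1 RPM (both comparisons inclusive).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("oncomir")

#: Sequencing-depth cutoff: samples with fewer total reads are excluded.
MIN_TOTAL_READS = 5_000_000

#: A miRNA is positive in a sample when its RPM is at or above this value.
RPM_POSITIVE_THRESHOLD = 1.0

#: A miRNA is expressed in a group when at least this fraction of the
#: group's samples are RPM-positive.
DETECTION_FRACTION = 0.10

META_COLUMNS = ("patient_id", "group", "cohort", "total_reads")


class MatrixFormatError(ValueError):
    """Malformed matrix or annotation file (non-numeric, negative, duplicated...)."""


class MetadataError(ValueError):
    """Sample metadata missing, inconsistent, or contradicting the matrix."""


class UnitError(ValueError):
    """Operation applied to a matrix in the wrong unit (counts vs rpm)."""


class EmptyCohortError(ValueError):
    """A filter removed every sample."""


class DegenerateSampleError(ValueError):
    """A sample with zero total counts cannot be normalized."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """miRNA × sample expression values plus per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by miRNA id, columns are sample ids. Non-negative,
        finite. Raw read counts (``unit="counts"``) or reads-per-million
        (``unit="rpm"``).
    meta
        DataFrame indexed by sample id with columns ``patient_id``, ``group``,
        ``cohort``, ``total_reads``; row order matches the value columns.
    unit
        ``"counts"`` or ``"rpm"``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "rpm"):
            raise UnitError(f"unknown unit {self.unit!r}")
        vals = self.values.to_numpy(dtype=float, copy=False)
        if not np.all(np.isfinite(vals)):
            raise MatrixFormatError("expression values must be finite")
        if (vals < 0).any():
            raise MatrixFormatError("expression values must be non-negative")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise MatrixFormatError(f"duplicate miRNA ids: {dups}")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise MetadataError(f"metadata lacks columns {missing}")
        if list(self.values.columns) != list(self.meta.index):
            extra = set(self.values.columns) - set(self.meta.index)
            if extra:
                raise MetadataError(f"samples absent from metadata: {sorted(extra)}")
            # same sample set, different order: align metadata to the matrix
            self.meta = self.meta.loc[list(self.values.columns)]
        if self.meta["group"].isna().any() or self.meta["cohort"].isna().any():
            raise MetadataError("every sample needs a group and a cohort label")

    # -- convenience accessors ------------------------------------------------

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.meta.index[self.meta["group"] == group])

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values[list(sample_ids)].copy(),
            meta=self.meta.loc[list(sample_ids)].copy(),
            unit=self.unit,
        )

    def subset_groups(self, groups: list[str]) -> "ExpressionMatrix":
        keep = self.meta.index[self.meta["group"].isin(groups)]
        return self.subset_samples(list(keep))

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (
            self.unit == other.unit
            and self.values.equals(other.values)
            and self.meta.equals(other.meta)
        )


@dataclass(frozen=True)
class GenomicLocus:
    """A mature-miRNA genomic interval, 1-based inclusive on both ends."""

    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise MatrixFormatError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 < self.start <= self.end):
            raise MatrixFormatError(
                f"invalid interval {self.start}-{self.end} (need 0 < start <= end)"
            )


@dataclass(frozen=True)
class ExpressionCall:
    """Presence/absence call of one miRNA in one sample group."""

    mirna_id: str
    group: str
    fraction_positive: float
    expressed: bool


# ---------------------------------------------------------------------------
# TSV IO
# ---------------------------------------------------------------------------


def read_count_matrix(matrix_path, meta_path) -> ExpressionMatrix:
    """Read a TSV count matrix plus its sample-metadata TSV.

    The matrix file has a header of sample ids and a first column
    ``mirna_id``; the metadata file has columns ``sample_id``, ``patient_id``,
    ``group``, ``cohort``, ``total_reads``. Every matrix sample must appear in
    the metadata; empty cells are an error, not zeros.
    """
    try:
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    except ValueError as exc:
        raise MatrixFormatError(f"cannot parse matrix file: {exc}") from exc
    if values.isna().any().any():
        raise MatrixFormatError("matrix contains empty or missing cells")
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise MatrixFormatError(f"non-numeric cell in matrix: {exc}") from exc
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in meta.columns:
        raise MetadataError("metadata file needs a sample_id column")
    if meta["sample_id"].duplicated().any():
        raise MetadataError("duplicate sample_id rows in metadata")
    meta = meta.set_index("sample_id")
    values.columns = values.columns.astype(str)
    absent = [s for s in values.columns if s not in meta.index]
    if absent:
        raise MetadataError(f"samples absent from metadata: {absent}")
    meta = meta.loc[list(values.columns)]
    return ExpressionMatrix(values=values, meta=meta, unit="counts")


def write_matrix(m: ExpressionMatrix, matrix_path, meta_path=None) -> None:
    """Write the matrix (and optionally its metadata) as tab-separated text.

    Emitted dialect: tab separator, '.' decimal, LF line endings — identical
    to what :func:`read_count_matrix` reads, so write→read round-trips.
    """
    df = m.values.copy()
    df.index.name = "mirna_id"
    df.to_csv(matrix_path, sep="\t", lineterminator="\n")
    if meta_path is not None:
        out = m.meta.copy()
        out.index.name = "sample_id"
        out.to_csv(meta_path, sep="\t", lineterminator="\n")


def read_annotation(path) -> dict[str, GenomicLocus]:
    """Read a miRNA annotation TSV (columns: mirna_id, locus) into a dict."""
    df = pd.read_csv(path, sep="\t")
    if not {"mirna_id", "locus"} <= set(df.columns):
        raise MatrixFormatError("annotation needs mirna_id and locus columns")
    return {row.mirna_id: parse_locus(row.locus) for row in df.itertuples()}


# ---------------------------------------------------------------------------
# Sample-level preprocessing
# ---------------------------------------------------------------------------


def filter_low_depth(
    m: ExpressionMatrix, min_reads: int = MIN_TOTAL_READS
) -> ExpressionMatrix:
    """Drop samples sequenced to fewer than ``min_reads`` total reads.

    The boundary is strict-less: a sample with exactly ``min_reads`` is kept.
    Falls back to matrix column sums when ``total_reads`` is missing.
    """
    if m.unit != "counts":
        raise UnitError("depth filter applies to count matrices")
    totals = m.meta["total_reads"]
    if totals.isna().any():
        logger.warning(
            "total_reads missing for %d samples; using miRNA column sums",
            int(totals.isna().sum()),
        )
        colsums = m.values.sum(axis=0)
        totals = totals.fillna(colsums)
    keep = totals >= min_reads
    removed = list(totals.index[~keep])
    if removed:
        logger.info("depth filter removed %d samples: %s", len(removed), removed)
    if not keep.any():
        raise EmptyCohortError("depth filter removed every sample")
    return m.subset_samples(list(totals.index[keep]))


def average_replicates(m: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse replicate libraries of the same patient to their mean counts.

    Samples sharing (patient_id, group) become one pseudo-sample whose counts
    and total_reads are arithmetic means over the replicates (real-valued
    counts are allowed afterwards). Singleton patients pass through untouched,
    keeping their original sample id. A patient whose replicates span
    different groups is a metadata error.
    """
    if m.unit != "counts":
        raise UnitError("replicate averaging applies to raw counts")
    meta = m.meta
    span = meta.groupby("patient_id")["group"].nunique()
    bad = list(span.index[span > 1])
    if bad:
        raise MetadataError(f"replicates span multiple groups for patients: {bad}")

    new_cols: dict[str, np.ndarray] = {}
    new_meta_rows = []
    for (patient, group), samp in meta.groupby(["patient_id", "group"], sort=False):
        ids = list(samp.index)
        if len(ids) == 1:
            sid = ids[0]
            new_cols[sid] = m.values[sid].to_numpy()
            new_meta_rows.append((sid, patient, group, samp.iloc[0]["cohort"],
                                  samp.iloc[0]["total_reads"]))
        else:
            sid = str(patient)
            new_cols[sid] = m.values[ids].mean(axis=1).to_numpy()
            new_meta_rows.append((sid, patient, group, samp.iloc[0]["cohort"],
                                  float(np.mean(samp["total_reads"]))))
            logger.info("averaged %d replicates of patient %s", len(ids), patient)
    values = pd.DataFrame(new_cols, index=m.values.index)
    meta_out = pd.DataFrame(
        new_meta_rows, columns=["sample_id", *META_COLUMNS]
    ).set_index("sample_id")
    return ExpressionMatrix(values=values, meta=meta_out, unit="counts")


def normalize_rpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample to reads-per-million of its miRNA-assigned total.

    value[i, j] = counts[i, j] / Σ_i counts[i, j] × 1e6. Every column of the
    result sums to 1e6 (to relative tolerance 1e-9).
    """
    if m.unit != "counts":
        raise UnitError("matrix is already normalized")
    colsums = m.values.sum(axis=0)
    dead = list(colsums.index[colsums <= 0])
    if dead:
        raise DegenerateSampleError(f"samples with zero total counts: {dead}")
    rpm = m.values.div(colsums, axis=1) * 1e6
    return ExpressionMatrix(values=rpm, meta=m.meta.copy(), unit="rpm")


# ---------------------------------------------------------------------------
# Detection rule
# ---------------------------------------------------------------------------


def detect_expressed(
    m: ExpressionMatrix,
    group: str,
    rpm_threshold: float = RPM_POSITIVE_THRESHOLD,
    fraction: float = DETECTION_FRACTION,
) -> list[ExpressionCall]:
    """Call each miRNA expressed/not-expressed in one sample group.

    fraction_positive = (# samples in the group with RPM ≥ rpm_threshold)
    divided by the group size; the miRNA is expressed iff fraction_positive
    ≥ ``fraction``. Both inequalities are inclusive.
    """
    if m.unit != "rpm":
        raise UnitError("detection rule needs an RPM matrix")
    samples = m.samples_in_group(group)
    if not samples:
        raise EmptyCohortError(f"no samples in group {group!r}")
    sub = m.values[samples].to_numpy()
    frac = (sub >= rpm_threshold).sum(axis=1) / len(samples)
    return [
        ExpressionCall(mid, group, float(f), bool(f >= fraction))
        for mid, f in zip(m.mirna_ids, frac)
    ]


def calls_to_frame(calls: list[ExpressionCall]) -> pd.DataFrame:
    """Tabulate expression calls (one row per miRNA) for writing/joining."""
    return pd.DataFrame(
        [(c.mirna_id, c.group, c.fraction_positive, c.expressed) for c in calls],
        columns=["mirna_id", "group", "fraction_positive", "expressed"],
    ).set_index("mirna_id")


# ---------------------------------------------------------------------------
# Genomic locus strings
# ---------------------------------------------------------------------------

# "<chrom><strand>:<start>-<end>"; the minus strand may be an ASCII hyphen
# or a Unicode minus sign (published tables mix both glyphs).
_LOCUS_RE = re.compile(r"^(?P<chrom>\S+?)(?P<strand>[+\-−]):(?P<start>\d+)-(?P<end>\d+)$")


def parse_locus(s: str) -> GenomicLocus:
    """Parse a locus string like ``"chr14+:101056233-101056255"``."""
    match = _LOCUS_RE.match(s.strip())
    if not match:
        raise MatrixFormatError(f"unparseable locus string: {s!r}")
    strand = match["strand"].replace("−", "-")
    start, end = int(match["start"]), int(match["end"])
    if start > end:
        raise MatrixFormatError(f"locus start > end in {s!r}")
    return GenomicLocus(match["chrom"], strand, start, end)


def format_locus(locus: GenomicLocus) -> str:
    """Emit the canonical ASCII form (minus strand as '-')."""
    return f"{locus.chrom}{locus.strand}:{locus.start}-{locus.end}"
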