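"""Plain-TSV readers and writers for expression, samples, truth and results.

All files are UTF-8 tab-separated text with a header row, "." decimals and
"NA" for missing values.  Sample-to-column alignment is always by id, never
by position, so a permuted metadata file can never silently permute the
phenotype against the expression columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ValidationError",
    "read_expression",
    "write_expression",
    "read_samples",
    "write_samples",
    "write_truth",
    "read_truth",
    "write_results",
    "read_results",
    "align_to_samples",
    "load_table2",
]

_FLOAT_FMT = "%.10g"

SAMPLE_COLUMNS = ["sample_id", "patient_id", "within_patient_index", "sav", "batch", "cohort"]


class ValidationError(ValueError):
    """Raised when a file or table violates the declared invariants."""


@dataclass
class ExpressionMatrix:
    """Genes x samples grid of log-ratio expression values.

    ``values`` is indexed by gene id with sample ids as columns;
    ``mean_log_intensity`` is the per-gene average log10 signal used by the
    expression-level marker filter.
    """

    values: pd.DataFrame
    mean_log_intensity: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        if not self.mean_log_intensity.index.equals(self.values.index):
            raise ValidationError("mean_log_intensity index does not match gene ids")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.to_list()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.to_list()

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Parse an expression TSV (gene rows, sample columns).

    The first column holds gene ids; an optional ``mean_log_intensity``
    column is split off into the per-gene intensity channel (missing
    intensities default to 0).  Non-numeric cells raise a parse error
    naming the offending row and column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], dtype=str)
    df.index = df.index.astype(str)
    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            raise ValidationError(
                f"non-numeric cell at gene {df.index[bad.argmax()]!r}, column {col!r}"
            )
        numeric[col] = converted
    if "mean_log_intensity" in numeric.columns:
        intensity = numeric.pop("mean_log_intensity")
    else:
        intensity = pd.Series(0.0, index=numeric.index)
    intensity.name = "mean_log_intensity"
    return ExpressionMatrix(values=numeric, mean_log_intensity=intensity)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out["mean_log_intensity"] = matrix.mean_log_intensity
    out.to_csv(path, sep="\t", index_label="gene_id", na_rep="NA", float_format=_FLOAT_FMT)


def read_samples(path: str | Path, matrix: ExpressionMatrix | None = None) -> pd.DataFrame:
    """Parse and validate the sample-metadata TSV.

    Checks: required columns present; sav positive; each discovery patient
    has exactly two samples with distinct within-patient indices; each
    replication patient exactly one.  When ``matrix`` is given, the sample
    id sets must agree exactly.
    """
    samples = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str})
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValidationError(f"sample table missing columns: {missing}")
    samples = samples[SAMPLE_COLUMNS]
    validate_samples(samples)
    if matrix is not None:
        meta_ids = set(samples["sample_id"])
        mat_ids = set(matrix.sample_ids)
        if meta_ids != mat_ids:
            raise ValidationError(
                f"sample ids disagree: only in metadata {sorted(meta_ids - mat_ids)[:5]}, "
                f"only in matrix {sorted(mat_ids - meta_ids)[:5]}"
            )
    return samples


def validate_samples(samples: pd.DataFrame) -> None:
    if samples["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample ids in metadata")
    if (samples["sav"] <= 0).any():
        bad = samples.loc[samples["sav"] <= 0, "sample_id"].tolist()
        raise ValidationError(f"non-positive sav for samples: {bad[:5]}")
    bad_cohort = set(samples["cohort"]) - {"discovery", "replication"}
    if bad_cohort:
        raise ValidationError(f"unknown cohort labels: {sorted(bad_cohort)}")
    disc = samples[samples["cohort"] == "discovery"]
    counts = disc.groupby("patient_id").size()
    offenders = counts[counts != 2].index.tolist()
    if offenders:
        raise ValidationError(f"discovery patients without exactly 2 samples: {offenders[:5]}")
    for pid, grp in disc.groupby("patient_id"):
        if sorted(grp["within_patient_index"]) != [1, 2]:
            raise ValidationError(f"discovery patient {pid} lacks within-patient indices 1 and 2")
    rep = samples[samples["cohort"] == "replication"]
    counts = rep.groupby("patient_id").size()
    offenders = counts[counts != 1].index.tolist()
    if offenders:
        raise ValidationError(f"replication patients without exactly 1 sample: {offenders[:5]}")


def align_to_samples(matrix: ExpressionMatrix, samples: pd.DataFrame) -> ExpressionMatrix:
    """Reorder matrix columns to the metadata row order (by sample id)."""
    ids = samples["sample_id"].to_list()
    missing = [s for s in ids if s not in matrix.values.columns]
    if missing:
        raise ValidationError(f"sample ids absent from matrix: {missing[:5]}")
    return ExpressionMatrix(
        values=matrix.values[ids], mean_log_intensity=matrix.mean_log_intensity
    )


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=_FLOAT_FMT)


def write_truth(truth, path: str | Path) -> None:
    """Write the gene-level ground truth (planted slopes, batch offsets)."""
    out = truth.genes.copy()
    out["noise_sd"] = truth.noise_sd
    out.to_csv(path, sep="\t", index_label="gene_id", na_rep="NA", float_format=_FLOAT_FMT)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id", na_values=["NA"])


RESULT_COLUMNS = [
    "gene_id",
    "mean_log_intensity",
    "slope",
    "slope_se",
    "p_slope",
    "p_patient",
    "q_value",
    "passed_intensity",
    "passed_slope",
    "passed_patient",
    "selected",
    "rep_slope",
    "rep_intercept",
    "rep_p",
    "replicated",
]


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write the combined per-gene results table (one row per gene).

    Columns follow the printed layout of the replicated-gene table:
    discovery slope and p-value, genome-wide q-value, the three selection
    flags, and the replication slope and p-value where computed.  Numeric
    formatting keeps >= 6 significant digits.
    """
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise ValidationError(f"results table missing columns: {missing}")
    results[RESULT_COLUMNS].to_csv(
        path, sep="\t", index=False, na_rep="NA", float_format=_FLOAT_FMT
    )


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def load_table2() -> pd.DataFrame:
    """Load the packaged fixture of the 30 replicated genes.

    Columns: mrna, gene_symbol, discovery_slope, discovery_p,
    replication_slope, replication_p — the printed slope/p-value pairs of
    the replicated-marker table, transcribed to TSV.
    """
    with resources.files("savrex.data").joinpath("table2_replicated_genes.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
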