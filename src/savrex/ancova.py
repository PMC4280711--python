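"""Per-gene parallel-lines ANCOVA on the discovery cohort.

The model for a single gene is

    y_ij = beta_0 + beta_i + alpha * SAV_ij + eps_ij

with one intercept per patient (sum-to-zero coded, so beta_0 is the
grand-mean intercept) and a single common slope alpha shared by all
patients.  Inference: ``p_slope`` is the two-sided t-test of alpha = 0 on
the residual degrees of freedom; ``p_patient`` is the extra-sum-of-squares
F-test of the full model against the reduced model without patient terms
(y = beta_0 + alpha * SAV + eps).  With 21 patients contributing two
samples each, the residual df is 42 - 21 - 1 = 20.

Fitting is done by least squares on the shared design matrix, vectorised
over genes: the cross-product inverse and projection residual-makers are
computed once per cohort, so fitting the full probe set is a handful of
matrix products.

Batch adjustment (per-gene within-batch mean centering) is provided as a
preprocessing step; it removes a two-level processing offset while leaving
all within-batch contrasts untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from savrex.io import ExpressionMatrix, ValidationError, align_to_samples

__all__ = ["AncovaFit", "batch_adjust", "fit_gene_ancova", "fit_all_genes", "fits_to_frame"]

logger = logging.getLogger(__name__)


@dataclass
class AncovaFit:
    """Result of the parallel-lines fit for one gene.

    ``patient_intercepts`` are the sum-to-zero coded beta_i, one per
    patient in the order of ``patient_ids``; they sum to zero.  Degenerate
    fits (zero-variance gene, rank-deficient design, or too few usable
    samples) carry NaN statistics and ``degenerate=True``.
    """

    gene_id: str
    slope: float
    intercept: float
    patient_intercepts: np.ndarray
    patient_ids: list[str]
    slope_se: float
    p_slope: float
    p_patient: float
    residual_df: int
    n_used: int
    mean_log_intensity: float = float("nan")
    degenerate: bool = False


def batch_adjust(matrix: ExpressionMatrix, samples: pd.DataFrame) -> ExpressionMatrix:
    """Center every gene to mean zero within each batch.

    After adjustment the per-gene mean over each batch's samples is zero
    (to machine precision) and differences between samples of the same
    batch are unchanged.  A stand-in for the study's conservative
    phase/batch adjustment, replaceable via the pipeline config.
    """
    aligned = align_to_samples(matrix, samples)
    batches = samples["batch"].to_numpy()
    values = aligned.values.to_numpy(dtype=float).copy()
    for level in pd.unique(batches):
        cols = np.flatnonzero(batches == level)
        if cols.size == 0:
            raise ValidationError(f"batch {level!r} has no samples")
        values[:, cols] -= np.nanmean(values[:, cols], axis=1, keepdims=True)
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=aligned.values.index, columns=aligned.values.columns),
        mean_log_intensity=aligned.mean_log_intensity,
    )


def _design(sav: np.ndarray, patient_codes: np.ndarray, n_patients: int) -> np.ndarray:
    """Full design: intercept, SA/V, and n_patients-1 sum-to-zero contrasts."""
    n = sav.shape[0]
    X = np.zeros((n, n_patients + 1))
    X[:, 0] = 1.0
    X[:, 1] = sav
    for k in range(n_patients - 1):
        X[patient_codes == k, 2 + k] = 1.0
        X[patient_codes == n_patients - 1, 2 + k] = -1.0
    return X


def _fit_block(Y: np.ndarray, sav: np.ndarray, patient_codes: np.ndarray, n_patients: int):
    """Vectorised least-squares fit of the parallel-lines model.

    Y is genes x samples.  Returns per-gene slope, intercept, patient
    intercepts, slope SE, p_slope, p_patient, plus the design's residual df
    and a rank-ok flag shared by all genes.
    """
    n = Y.shape[1]
    X = _design(sav, patient_codes, n_patients)
    p_full = X.shape[1]
    rank = np.linalg.matrix_rank(X)
    df_resid = n - p_full
    if rank < p_full or df_resid < 1:
        nan = np.full(Y.shape[0], np.nan)
        return nan, nan, np.full((Y.shape[0], n_patients - 1), np.nan), nan, nan, nan, df_resid, False

    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y.T  # p_full x n_genes
    resid = Y.T - X @ B
    rss_full = np.einsum("ij,ij->j", resid, resid)

    X0 = X[:, :2]
    B0 = np.linalg.inv(X0.T @ X0) @ X0.T @ Y.T
    resid0 = Y.T - X0 @ B0
    rss_red = np.einsum("ij,ij->j", resid0, resid0)

    slope = B[1]
    intercept = B[0]
    sigma2 = rss_full / df_resid
    slope_se = np.sqrt(sigma2 * XtX_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = slope / slope_se
        p_slope = 2.0 * stats.t.sf(np.abs(tstat), df_resid)
        # exact-fit genes: zero residual with nonzero slope -> p = 0
        p_slope = np.where((slope_se == 0) & (slope != 0), 0.0, p_slope)
        df_pat = n_patients - 1
        fstat = ((rss_red - rss_full) / df_pat) / sigma2
        p_patient = stats.f.sf(fstat, df_pat, df_resid)
        # exact fits: patient terms explain everything left -> 0, nothing -> 1
        p_patient = np.where(
            sigma2 == 0, np.where(rss_red > rss_full, 0.0, 1.0), p_patient
        )
    return slope, intercept, B[2:].T, slope_se, p_slope, p_patient, df_resid, True


def fit_gene_ancova(
    y: np.ndarray,
    sav: np.ndarray,
    patient_ids,
    gene_id: str = "gene",
    mean_log_intensity: float = float("nan"),
) -> AncovaFit:
    """Fit the parallel-lines model for a single gene.

    Missing expression values are dropped together with their samples; the
    fit is flagged degenerate when fewer than n_patients + 2 usable samples
    remain, when the gene has zero variance, or when SA/V is constant
    within every patient (rank-deficient design).
    """
    y = np.asarray(y, dtype=float)
    sav = np.asarray(sav, dtype=float)
    patient_ids = np.asarray(patient_ids)
    mask = ~np.isnan(y)
    y, sav, patient_ids = y[mask], sav[mask], patient_ids[mask]
    uniq = list(pd.unique(patient_ids))
    n_patients = len(uniq)
    codes = pd.Categorical(patient_ids, categories=uniq).codes.astype(int)

    def _degenerate() -> AncovaFit:
        return AncovaFit(
            gene_id=gene_id,
            slope=float("nan"),
            intercept=float("nan"),
            patient_intercepts=np.full(n_patients, np.nan),
            patient_ids=[str(u) for u in uniq],
            slope_se=float("nan"),
            p_slope=float("nan"),
            p_patient=float("nan"),
            residual_df=0,
            n_used=int(y.size),
            mean_log_intensity=mean_log_intensity,
            degenerate=True,
        )

    if n_patients < 2 or y.size < n_patients + 2:
        return _degenerate()
    if np.ptp(y) == 0:
        return _degenerate()

    slope, intercept, contrasts, se, p_s, p_p, df_resid, rank_ok = _fit_block(
        y[None, :], sav, codes, n_patients
    )
    if not rank_ok:
        return _degenerate()
    beta = np.append(contrasts[0], -contrasts[0].sum())
    return AncovaFit(
        gene_id=gene_id,
        slope=float(slope[0]),
        intercept=float(intercept[0]),
        patient_intercepts=beta,
        patient_ids=[str(u) for u in uniq],
        slope_se=float(se[0]),
        p_slope=float(p_s[0]),
        p_patient=float(p_p[0]),
        residual_df=int(df_resid),
        n_used=int(y.size),
        mean_log_intensity=mean_log_intensity,
    )


def fit_all_genes(
    matrix: ExpressionMatrix,
    samples: pd.DataFrame,
    log_every: int = 5000,
) -> list[AncovaFit]:
    """Fit the ANCOVA for every gene of the discovery cohort.

    ``samples`` must contain discovery records only (a cohort-leakage
    guard).  Genes with complete data share one design and are fitted in a
    single vectorised block; genes with missing values fall back to the
    per-gene path.  Degenerate genes are flagged, never dropped.
    """
    if (samples["cohort"] != "discovery").any():
        raise ValidationError("fit_all_genes expects discovery samples only")
    aligned = align_to_samples(matrix, samples)
    Y = aligned.values.to_numpy(dtype=float)
    sav = samples["sav"].to_numpy(dtype=float)
    patient_ids = samples["patient_id"].to_numpy()
    uniq = list(pd.unique(patient_ids))
    n_patients = len(uniq)
    codes = pd.Categorical(patient_ids, categories=uniq).codes.astype(int)
    gene_ids = aligned.gene_ids
    intensity = aligned.mean_log_intensity.to_numpy(dtype=float)

    complete = ~np.isnan(Y).any(axis=1)
    nonconst = np.ptp(Y, axis=1) != 0
    block = complete & nonconst
    fits: list[AncovaFit | None] = [None] * len(gene_ids)

    if block.any():
        slope, intercept, contrasts, se, p_s, p_p, df_resid, rank_ok = _fit_block(
            Y[block], sav, codes, n_patients
        )
        for out_k, k in enumerate(np.flatnonzero(block)):
            if not rank_ok:
                fits[k] = fit_gene_ancova(
                    np.full(Y.shape[1], np.nan), sav, patient_ids, gene_ids[k], intensity[k]
                )
                continue
            beta = np.append(contrasts[out_k], -contrasts[out_k].sum())
            fits[k] = AncovaFit(
                gene_id=gene_ids[k],
                slope=float(slope[out_k]),
                intercept=float(intercept[out_k]),
                patient_intercepts=beta,
                patient_ids=[str(u) for u in uniq],
                slope_se=float(se[out_k]),
                p_slope=float(p_s[out_k]),
                p_patient=float(p_p[out_k]),
                residual_df=int(df_resid),
                n_used=Y.shape[1],
                mean_log_intensity=float(intensity[k]),
            )
            if log_every and (out_k + 1) % log_every == 0:
                logger.info("fitted %d genes", out_k + 1)

    for k in np.flatnonzero(~block):
        fits[k] = fit_gene_ancova(Y[k], sav, patient_ids, gene_ids[k], float(intensity[k]))
    logger.info("fitted %d genes (%d degenerate)", len(fits), sum(f.degenerate for f in fits))
    return fits  # type: ignore[return-value]


def fits_to_frame(fits: list[AncovaFit]) -> pd.DataFrame:
    """Tabulate per-gene fit statistics (one row per gene, input order)."""
    return pd.DataFrame(
        {
            "gene_id": [f.gene_id for f in fits],
            "slope": [f.slope for f in fits],
            "slope_se": [f.slope_se for f in fits],
            "p_slope": [f.p_slope for f in fits],
            "p_patient": [f.p_patient for f in fits],
            "residual_df": [f.residual_df for f in fits],
            "mean_log_intensity": [f.mean_log_intensity for f in fits],
            "degenerate": [f.degenerate for f in fits],
        }
    )
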