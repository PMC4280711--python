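"""Marker selection, BH FDR, replication regression and concordance.

Selection applies the three cutoffs with strict inequalities exactly as
printed: mean log-intensity > -1, P_slope < 0.05, P_patient > 0.1.  The
intensity filter keeps adequately expressed probes; the P_patient filter
drops genes dominated by between-patient variation, so that a simple
regression without patient terms is a sensible model in the single-sample
replication cohort.  BH q-values are computed genome-wide over all
non-degenerate fits before any filtering.

A selected gene "replicates" when its replication-cohort slope is
significant (two-sided p < 0.05 by default) *and* has the same sign as its
discovery slope; sign concordance is required so an effect in the opposite
direction never counts as confirmation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from savrex.io import ExpressionMatrix, ValidationError, align_to_samples

__all__ = [
    "bh_adjust",
    "select_markers",
    "ReplicationFit",
    "fit_replication",
    "replicate_genes",
    "ConcordanceSummary",
    "summarize_concordance",
]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order preserved.

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, capped at
    1, mapped back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_markers(
    fits: pd.DataFrame,
    intensity_min: float = -1.0,
    p_slope_max: float = 0.05,
    p_patient_min: float = 0.1,
) -> pd.DataFrame:
    """Apply the three marker-selection cutoffs to a table of ANCOVA fits.

    ``fits`` needs columns gene_id, mean_log_intensity, p_slope, p_patient
    and degenerate (see :func:`savrex.ancova.fits_to_frame`).  Returns one
    row per gene in input order with the three pass flags, the conjunction
    flag ``selected``, and the genome-wide BH ``q_value`` (computed over
    all non-degenerate fits, before the intensity filter; NaN for
    degenerate genes, which are never selected).
    """
    out = fits[["gene_id"]].copy()
    ok = ~fits["degenerate"].to_numpy(dtype=bool)
    out["passed_intensity"] = ok & (fits["mean_log_intensity"].to_numpy() > intensity_min)
    out["passed_slope"] = ok & (fits["p_slope"].to_numpy() < p_slope_max)
    out["passed_patient"] = ok & (fits["p_patient"].to_numpy() > p_patient_min)
    out["selected"] = out["passed_intensity"] & out["passed_slope"] & out["passed_patient"]
    q = np.full(len(fits), np.nan)
    if ok.any():
        q[ok] = bh_adjust(fits.loc[ok, "p_slope"].to_numpy())
    out["q_value"] = q
    return out


@dataclass
class ReplicationFit:
    """Simple-regression result for one gene in the replication cohort."""

    gene_id: str
    rep_slope: float
    rep_intercept: float
    rep_p: float
    n_used: int
    degenerate: bool = False


def fit_replication(y, sav, gene_id: str = "gene") -> ReplicationFit:
    """Ordinary least-squares regression of expression on SA/V.

    Two-sided slope p-value on n - 2 df.  Degenerate (NaN statistics) when
    fewer than 3 complete samples remain or SA/V is constant.
    """
    y = np.asarray(y, dtype=float)
    sav = np.asarray(sav, dtype=float)
    mask = ~(np.isnan(y) | np.isnan(sav))
    y, sav = y[mask], sav[mask]
    if y.size < 3 or np.ptp(sav) == 0:
        return ReplicationFit(gene_id, float("nan"), float("nan"), float("nan"), int(y.size), True)
    res = stats.linregress(sav, y)
    return ReplicationFit(
        gene_id=gene_id,
        rep_slope=float(res.slope),
        rep_intercept=float(res.intercept),
        rep_p=float(res.pvalue),
        n_used=int(y.size),
    )


def replicate_genes(
    matrix: ExpressionMatrix, samples: pd.DataFrame, gene_ids
) -> pd.DataFrame:
    """Run the replication regression for each listed gene.

    ``samples`` must contain replication-cohort records only.  Returns one
    row per requested gene (input order) with rep_slope, rep_intercept,
    rep_p and n_used.
    """
    if (samples["cohort"] != "replication").any():
        raise ValidationError("replicate_genes expects replication samples only")
    aligned = align_to_samples(matrix, samples)
    missing = [g for g in gene_ids if g not in aligned.values.index]
    if missing:
        raise ValidationError(f"genes absent from matrix: {missing[:5]}")
    sav = samples["sav"].to_numpy(dtype=float)
    fits = [
        fit_replication(aligned.values.loc[g].to_numpy(dtype=float), sav, g) for g in gene_ids
    ]
    return pd.DataFrame(
        {
            "gene_id": [f.gene_id for f in fits],
            "rep_slope": [f.rep_slope for f in fits],
            "rep_intercept": [f.rep_intercept for f in fits],
            "rep_p": [f.rep_p for f in fits],
            "rep_n": [f.n_used for f in fits],
            "rep_degenerate": [f.degenerate for f in fits],
        }
    )


@dataclass
class ConcordanceSummary:
    """Discovery-vs-replication agreement for the selected genes."""

    n_selected: int
    n_same_direction: int
    n_replicated: int
    slope_correlation: float

    def as_dict(self) -> dict:
        return {
            "n_selected": self.n_selected,
            "n_same_direction": self.n_same_direction,
            "n_replicated": self.n_replicated,
            "slope_correlation": self.slope_correlation,
        }


def summarize_concordance(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    rep_p_max: float = 0.05,
) -> ConcordanceSummary:
    """Compare discovery and replication slopes for the selected genes.

    ``discovery`` needs columns gene_id and slope; ``replication`` needs
    gene_id, rep_slope and rep_p; the two gene sets must match exactly.
    Counts sign-concordant pairs, pairs that additionally replicate at
    rep_p < rep_p_max, and the Pearson correlation of the slope pairs.
    """
    d_ids, r_ids = set(discovery["gene_id"]), set(replication["gene_id"])
    if d_ids != r_ids:
        raise ValidationError(
            f"gene sets differ: only in discovery {sorted(d_ids - r_ids)[:5]}, "
            f"only in replication {sorted(r_ids - d_ids)[:5]}"
        )
    merged = discovery[["gene_id", "slope"]].merge(
        replication[["gene_id", "rep_slope", "rep_p"]], on="gene_id"
    )
    d = merged["slope"].to_numpy(dtype=float)
    r = merged["rep_slope"].to_numpy(dtype=float)
    same = np.sign(d) == np.sign(r)
    replicated = same & (merged["rep_p"].to_numpy(dtype=float) < rep_p_max)
    if len(merged) >= 2 and np.ptp(d) > 0 and np.ptp(r) > 0:
        corr = float(stats.pearsonr(d, r).statistic)
    elif len(merged) >= 1:
        corr = 1.0 if len(merged) == 1 or np.allclose(d, r) else float("nan")
    else:
        corr = float("nan")
    return ConcordanceSummary(
        n_selected=int(len(merged)),
        n_same_direction=int(same.sum()),
        n_replicated=int(replicated.sum()),
        slope_correlation=corr,
    )
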