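"""Synthetic two-stage cohort generator.

Emulates the study design the analysis assumes: a discovery cohort of
paired lung samples per patient whose SA/V values differ by more than a
minimum delta, an independent replication cohort with a single sample per
patient, a two-level batch effect, per-patient intercepts, and a minority
of genes whose expression has a true linear SA/V slope.  Expression is
generated on the log-ratio scale as

    y_ij = beta_i + alpha * SAV_ij + batch_offset + eps_ij

with Gaussian patient intercepts beta_i, Gaussian noise eps_ij, and
per-gene per-batch Gaussian offsets.  The overall intercept is zero:
log-ratios against a pooled reference are centred by construction.

All randomness flows from one :class:`numpy.random.Generator` seeded once
from ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from savrex.io import ExpressionMatrix

__all__ = ["SimulationConfig", "TruthTable", "sample_sav_pairs", "generate_cohort"]


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig violates its feasibility constraints."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study design scale: 23,757 probes, 21 discovery
    patients with two samples each (SA/V differing by > 49 cm^2/mL),
    22 single-sample replication patients, a two-level batch effect, and
    planted slopes in the 2e-4 to 7e-4 per-cm^2/mL magnitude range.  Noise
    scales (``patient_sd``, ``noise_sd``) are calibrated so that slope
    tests at both stages operate in a realistic power regime; see the
    methods note for the calibration argument.
    """

    n_genes: int = 23757
    n_discovery_patients: int = 21
    n_replication_patients: int = 22
    frac_affected: float = 0.05
    slope_scale: tuple[float, float] = (2e-4, 7e-4)
    patient_sd: float = 0.03
    noise_sd: float = 0.05
    batch_sd: float = 0.1
    n_batches: int = 2
    sav_range: tuple[float, float] = (100.0, 300.0)
    min_sav_delta: float = 49.0
    intensity_mean: float = 0.0
    intensity_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if not 0.0 <= self.frac_affected <= 1.0:
            raise ConfigurationError("frac_affected must lie in [0, 1]")
        for name in ("patient_sd", "noise_sd", "batch_sd", "intensity_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        lo, hi = self.sav_range
        if not lo < hi:
            raise ConfigurationError("sav_range must satisfy low < high")
        if not self.min_sav_delta < hi - lo:
            raise ConfigurationError("min_sav_delta must be smaller than the sav_range width")
        slo, shi = self.slope_scale
        if not 0 <= slo <= shi:
            raise ConfigurationError("slope_scale must satisfy 0 <= low <= high")
        if self.n_batches < 1:
            raise ConfigurationError("n_batches must be >= 1")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class TruthTable:
    """Ground truth of a generated cohort, for recovery testing.

    ``genes`` holds one row per gene: the planted slope ``alpha_true``
    (0 for null genes) and the per-batch offsets.  ``patient_intercepts``
    is the genes x patients matrix of beta_i draws.  Null and affected
    genes are distinguished by ``alpha_true != 0``.
    """

    genes: pd.DataFrame
    patient_intercepts: pd.DataFrame
    noise_sd: float

    @property
    def alpha_true(self) -> pd.Series:
        return self.genes["alpha_true"]

    @property
    def affected(self) -> pd.Series:
        return self.genes["alpha_true"] != 0.0


def sample_sav_pairs(
    n_patients: int,
    sav_range: tuple[float, float],
    min_sav_delta: float,
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    """Draw (sav_low, sav_high) per patient with sav_high - sav_low > delta.

    The low value is uniform on [low, high - delta]; the high value is then
    uniform on (low + delta, high].  Draws landing exactly on the delta
    boundary are rejected so the strict inequality always holds.
    """
    lo, hi = sav_range
    if not min_sav_delta < hi - lo:
        raise ConfigurationError("min_sav_delta must be smaller than the sav_range width")
    pairs: list[tuple[float, float]] = []
    while len(pairs) < n_patients:
        low = rng.uniform(lo, hi - min_sav_delta)
        high = rng.uniform(low + min_sav_delta, hi)
        if high - low > min_sav_delta:
            pairs.append((low, high))
    return pairs


def _planted_slopes(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Slopes for all genes: zero for nulls, signed magnitudes for affected.

    Exactly round(frac_affected * n_genes) genes are affected; signs are
    balanced +/-1 up to rounding and assigned to a random gene subset.
    """
    alpha = np.zeros(cfg.n_genes)
    n_affected = int(round(cfg.frac_affected * cfg.n_genes))
    if n_affected == 0:
        return alpha
    idx = rng.choice(cfg.n_genes, size=n_affected, replace=False)
    mags = rng.uniform(cfg.slope_scale[0], cfg.slope_scale[1], size=n_affected)
    signs = np.ones(n_affected)
    signs[n_affected // 2 :] = -1.0
    rng.shuffle(signs)
    alpha[idx] = mags * signs
    return alpha


def generate_cohort(cfg: SimulationConfig) -> tuple[ExpressionMatrix, pd.DataFrame, TruthTable]:
    """Generate (expression matrix, sample table, truth) for both cohorts.

    Discovery patients contribute two samples each (paired SA/V values more
    than ``min_sav_delta`` apart); replication patients one sample each with
    SA/V uniform over ``sav_range``.  Patients are assigned to batches
    round-robin, so both samples of a discovery patient share a batch.
    Reproducible bit-for-bit from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)

    # --- sample frame -------------------------------------------------
    rows = []
    pairs = sample_sav_pairs(cfg.n_discovery_patients, cfg.sav_range, cfg.min_sav_delta, rng)
    for i, (sav_lo, sav_hi) in enumerate(pairs):
        pid = f"PD{i + 1:02d}"
        batch = f"batch{i % cfg.n_batches + 1}"
        rows.append((f"{pid}_s1", pid, 1, sav_lo, batch, "discovery"))
        rows.append((f"{pid}_s2", pid, 2, sav_hi, batch, "discovery"))
    rep_sav = rng.uniform(cfg.sav_range[0], cfg.sav_range[1], size=cfg.n_replication_patients)
    for i in range(cfg.n_replication_patients):
        pid = f"PR{i + 1:02d}"
        batch = f"batch{i % cfg.n_batches + 1}"
        rows.append((f"{pid}_s1", pid, 1, rep_sav[i], batch, "replication"))
    samples = pd.DataFrame(
        rows,
        columns=["sample_id", "patient_id", "within_patient_index", "sav", "batch", "cohort"],
    )

    # --- truth --------------------------------------------------------
    gene_ids = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    alpha = _planted_slopes(cfg, rng)
    patient_ids = samples["patient_id"].unique()
    beta = rng.normal(0.0, cfg.patient_sd, size=(cfg.n_genes, len(patient_ids)))
    batch_levels = [f"batch{b + 1}" for b in range(cfg.n_batches)]
    batch_off = rng.normal(0.0, cfg.batch_sd, size=(cfg.n_genes, cfg.n_batches))

    # --- expression ---------------------------------------------------
    pat_idx = pd.Categorical(samples["patient_id"], categories=patient_ids).codes
    batch_idx = pd.Categorical(samples["batch"], categories=batch_levels).codes
    sav = samples["sav"].to_numpy()
    y = (
        beta[:, pat_idx]
        + alpha[:, None] * sav[None, :]
        + batch_off[:, batch_idx]
        + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, len(samples)))
    )
    intensity = rng.normal(cfg.intensity_mean, cfg.intensity_sd, size=cfg.n_genes)

    matrix = ExpressionMatrix(
        values=pd.DataFrame(y, index=gene_ids, columns=samples["sample_id"].to_list()),
        mean_log_intensity=pd.Series(intensity, index=gene_ids, name="mean_log_intensity"),
    )
    truth = TruthTable(
        genes=pd.DataFrame(
            {"alpha_true": alpha}
            | {f"offset_{b}": batch_off[:, k] for k, b in enumerate(batch_levels)},
            index=gene_ids,
        ),
        patient_intercepts=pd.DataFrame(beta, index=gene_ids, columns=list(patient_ids)),
        noise_sd=cfg.noise_sd,
    )
    return matrix, samples, truth
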