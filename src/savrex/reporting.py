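"""Phenotype-ordered heatmaps, slope-scatter exports and the pipeline.

Heatmaps show the selected genes with samples ordered by increasing SA/V
and genes grouped by the sign of their discovery slope (negative block
first), each gene standardised to z-scores over the displayed samples.
Within a sign block genes are ordered by ascending discovery p_slope.
All acceptance-relevant content lives in the TSV exports; PNG rendering is
a thin optional layer.

``run_pipeline`` wires the stages together: simulate or load -> batch
adjust -> discovery ANCOVA -> genome-wide BH -> marker selection ->
replication regression -> concordance -> exports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from savrex import ancova, io, replication
from savrex.io import ExpressionMatrix, ValidationError
from savrex.simulate import SimulationConfig, generate_cohort

__all__ = ["HeatmapSpec", "build_heatmap", "export_slope_scatter", "PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class HeatmapSpec:
    """Standardised, phenotype-ordered display grid for selected genes.

    ``values`` is samples x genes: rows ordered by ascending SA/V, columns
    the selected genes with the negative-slope block first
    (``n_negative`` marks the block boundary).  Every gene is z-scored over
    the displayed samples (population SD); constant genes become all-zero.
    """

    values: pd.DataFrame
    sav: pd.Series
    n_negative: int

    @property
    def sample_order(self) -> list[str]:
        return self.values.index.to_list()

    @property
    def gene_order(self) -> list[str]:
        return self.values.columns.to_list()


def build_heatmap(
    matrix: ExpressionMatrix,
    samples: pd.DataFrame,
    results: pd.DataFrame,
    cohort: str,
    out_tsv: str | Path | None = None,
    out_png: str | Path | None = None,
) -> HeatmapSpec:
    """Build the SA/V-ordered heatmap of selected genes for one cohort.

    ``results`` needs gene_id, slope, p_slope and selected columns.  The
    TSV export carries the SA/V value per row, a header comment recording
    the sign-block boundary, and the z-scored grid.
    """
    if cohort not in ("discovery", "replication"):
        raise ValidationError(f"unknown cohort {cohort!r}")
    sub = samples[samples["cohort"] == cohort]
    sel = results[results["selected"].astype(bool)]
    if sel.empty:
        raise ValidationError("no selected genes to display")
    neg = sel[sel["slope"] < 0].sort_values("p_slope", kind="mergesort")
    pos = sel[sel["slope"] >= 0].sort_values("p_slope", kind="mergesort")
    gene_order = neg["gene_id"].to_list() + pos["gene_id"].to_list()

    aligned = io.align_to_samples(matrix, sub)
    order = np.argsort(sub["sav"].to_numpy(), kind="stable")
    sample_order = sub["sample_id"].to_numpy()[order]
    grid = aligned.values.loc[gene_order, sample_order].to_numpy(dtype=float).T
    mean = np.nanmean(grid, axis=0)
    sd = np.nanstd(grid, axis=0)
    z = np.where(sd > 0, (grid - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    spec = HeatmapSpec(
        values=pd.DataFrame(z, index=list(sample_order), columns=gene_order),
        sav=pd.Series(sub["sav"].to_numpy()[order], index=list(sample_order), name="sav"),
        n_negative=len(neg),
    )
    if out_tsv is not None:
        _write_heatmap_tsv(spec, out_tsv)
    if out_png is not None:
        _render_heatmap(spec, out_png, cohort)
    return spec


def _write_heatmap_tsv(spec: HeatmapSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# per-gene z-scores; samples ordered by increasing SA/V\n")
        fh.write(f"# n_negative_genes\t{spec.n_negative}\n")
        out = spec.values.copy()
        out.insert(0, "sav", spec.sav)
        out.to_csv(fh, sep="\t", index_label="sample_id", float_format="%.10g")


def read_heatmap_tsv(path: str | Path) -> HeatmapSpec:
    """Reconstruct a HeatmapSpec from its TSV export (round trip)."""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValidationError("missing heatmap header comment")
        n_negative = int(fh.readline().split("\t")[1])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    sav = df.pop("sav")
    return HeatmapSpec(values=df, sav=sav, n_negative=n_negative)


def _render_heatmap(spec: HeatmapSpec, path: str | Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    im = ax.imshow(spec.values.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-3, vmax=3)
    ax.axvline(spec.n_negative - 0.5, color="black", lw=0.8)
    ax.set_xlabel("selected genes (negative | positive slope)")
    ax.set_ylabel("samples by increasing SA/V")
    ax.set_title(f"{title} cohort")
    fig.colorbar(im, ax=ax, label="z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def export_slope_scatter(
    results: pd.DataFrame, replicated_only: bool = False, path: str | Path | None = None
) -> pd.DataFrame:
    """Tabulate (discovery slope, replication slope) pairs for selected genes.

    The export is sufficient to reproduce the slope-concordance scatter:
    one row per selected gene (or per replicated gene when
    ``replicated_only``), with both slopes and the replicated flag.
    """
    sel = results[results["selected"].astype(bool)]
    if replicated_only:
        sel = sel[sel["replicated"].astype(bool)]
    out = sel[["gene_id", "slope", "rep_slope", "replicated"]].rename(
        columns={"slope": "discovery_slope", "rep_slope": "replication_slope"}
    )
    if path is not None:
        out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")
    return out


@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    Either ``simulate=True`` (inputs generated from ``sim``) or paths to an
    expression TSV and a sample TSV.  Thresholds default to the published
    cutoffs; ``apply_batch_adjust`` toggles the within-batch centering for
    both cohorts.
    """

    out_dir: str | Path = "savrex_out"
    simulate: bool = False
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    expression_path: str | Path | None = None
    samples_path: str | Path | None = None
    apply_batch_adjust: bool = True
    intensity_min: float = -1.0
    p_slope_max: float = 0.05
    p_patient_min: float = 0.1
    rep_p_max: float = 0.05
    render_png: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_keys = {f for f in SimulationConfig.__dataclass_fields__}
        sim_kwargs = {k: raw.pop(k) for k in list(raw) if k in sim_keys}
        if "slope_scale" in sim_kwargs:
            sim_kwargs["slope_scale"] = tuple(sim_kwargs["slope_scale"])
        if "sav_range" in sim_kwargs:
            sim_kwargs["sav_range"] = tuple(sim_kwargs["sav_range"])
        return cls(sim=SimulationConfig(**sim_kwargs), **raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full discovery -> replication analysis and write all outputs.

    Outputs under ``config.out_dir``: results.tsv (one row per gene),
    summary.json (concordance counts + thresholds + seed), heatmap TSV/PNG
    per cohort, scatter.tsv, and run.log.  Byte-identical for identical
    inputs and seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    if config.simulate:
        log(f"stage simulate: seed={config.sim.seed} n_genes={config.sim.n_genes}")
        matrix, samples, truth = generate_cohort(config.sim)
        io.write_expression(matrix, out / "expression.tsv")
        io.write_samples(samples, out / "samples.tsv")
        io.write_truth(truth, out / "truth.tsv")
    else:
        if config.expression_path is None or config.samples_path is None:
            raise ValidationError("need expression_path and samples_path unless simulate=True")
        log(f"stage load: {config.expression_path}")
        matrix = io.read_expression(config.expression_path)
        samples = io.read_samples(config.samples_path, matrix)

    samples = samples.sort_values(
        ["cohort", "patient_id", "within_patient_index"], kind="mergesort"
    ).reset_index(drop=True)
    matrix = io.align_to_samples(matrix, samples)

    if config.apply_batch_adjust:
        log("stage batch_adjust: per-gene within-batch centering")
        matrix = ancova.batch_adjust(matrix, samples)

    disc_samples = samples[samples["cohort"] == "discovery"].reset_index(drop=True)
    rep_samples = samples[samples["cohort"] == "replication"].reset_index(drop=True)

    log(f"stage discover: {len(matrix.gene_ids)} genes, {len(disc_samples)} samples")
    fits = ancova.fit_all_genes(matrix, disc_samples)
    fits_df = ancova.fits_to_frame(fits)

    log("stage select: logIntensity > %g, P_slope < %g, P_patient > %g"
        % (config.intensity_min, config.p_slope_max, config.p_patient_min))
    selection = replication.select_markers(
        fits_df, config.intensity_min, config.p_slope_max, config.p_patient_min
    )
    selected_ids = selection.loc[selection["selected"], "gene_id"].to_list()
    log(f"selected {len(selected_ids)} markers")

    log(f"stage replicate: {len(rep_samples)} samples")
    rep_df = replication.replicate_genes(matrix, rep_samples, selected_ids)

    results = fits_df.merge(selection.drop(columns="gene_id"), left_index=True, right_index=True)
    results = results.merge(rep_df, on="gene_id", how="left")
    with np.errstate(invalid="ignore"):
        same_sign = np.sign(results["slope"].to_numpy()) == np.sign(
            results["rep_slope"].to_numpy()
        )
        rep_sig = results["rep_p"].to_numpy() < config.rep_p_max
    results["replicated"] = results["selected"].to_numpy(dtype=bool) & same_sign & rep_sig
    io.write_results(results, out / "results.tsv")

    disc_sel = results.loc[results["selected"], ["gene_id", "slope"]]
    summary = replication.summarize_concordance(disc_sel, rep_df, config.rep_p_max)
    log(
        f"concordance: selected={summary.n_selected} same_direction={summary.n_same_direction} "
        f"replicated={summary.n_replicated} r={summary.slope_correlation:.4f}"
    )

    if selected_ids:
        for cohort, sub in (("discovery", disc_samples), ("replication", rep_samples)):
            build_heatmap(
                matrix,
                samples,
                results,
                cohort,
                out_tsv=out / f"heatmap_{cohort}.tsv",
                out_png=(out / f"heatmap_{cohort}.png") if config.render_png else None,
            )
        export_slope_scatter(results, path=out / "scatter.tsv")

    summary_dict = {
        **summary.as_dict(),
        "n_genes": len(matrix.gene_ids),
        "thresholds": {
            "intensity_min": config.intensity_min,
            "p_slope_max": config.p_slope_max,
            "p_patient_min": config.p_patient_min,
            "rep_p_max": config.rep_p_max,
        },
        "seed": config.sim.seed if config.simulate else None,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary_dict, fh, indent=2)
        fh.write("\n")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary_dict
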