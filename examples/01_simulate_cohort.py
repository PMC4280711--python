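"""Generate a synthetic two-stage emphysema expression study.

Builds a small cohort with the study's design: 21 discovery patients with
two lung samples each (SA/V differing by > 49 cm^2/mL), 22 single-sample
replication patients, a two-level batch effect, and 5% of genes carrying a
true SA/V slope.  Prints the design summary and one affected gene's truth.
"""

from savrex import SimulationConfig, generate_cohort

cfg = SimulationConfig(n_genes=2000, seed=42)
matrix, samples, truth = generate_cohort(cfg)

disc = samples[samples.cohort == "discovery"]
rep = samples[samples.cohort == "replication"]
print(f"expression matrix: {matrix.values.shape[0]} genes x {matrix.values.shape[1]} samples")
print(f"discovery: {disc.patient_id.nunique()} patients, {len(disc)} samples")
print(f"replication: {rep.patient_id.nunique()} patients, {len(rep)} samples")

deltas = disc.groupby("patient_id")["sav"].agg(lambda s: s.max() - s.min())
print(f"min within-patient SA/V delta: {deltas.min():.1f} cm^2/mL (all > {cfg.min_sav_delta})")

affected = truth.genes[truth.genes.alpha_true != 0]
print(f"{len(affected)} genes carry a planted slope; first few:")
print(affected.head(3).round(6).to_string())
# alpha_true is the planted expression change per cm^2/mL of SA/V;
# the offset columns are the per-batch shifts the batch adjustment removes.
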