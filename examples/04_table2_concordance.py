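"""Concordance of the packaged 30-gene replicated-marker table.

The fixture transcribes the published table of 30 markers that replicated
(discovery and replication slopes with their p-values).  The summary
confirms that every printed pair is sign-concordant and computes the
Pearson correlation of the 30 slope pairs.
"""

import pandas as pd

from savrex import load_table2, summarize_concordance

t2 = load_table2()
print(f"{len(t2)} replicated markers; slope magnitudes "
      f"{t2.discovery_slope.abs().min():.5f}-{t2.discovery_slope.abs().max():.5f} per cm^2/mL")

summary = summarize_concordance(
    pd.DataFrame({"gene_id": t2.mrna, "slope": t2.discovery_slope}),
    pd.DataFrame({"gene_id": t2.mrna, "rep_slope": t2.replication_slope,
                  "rep_p": t2.replication_p}),
)
print(f"sign-concordant pairs: {summary.n_same_direction}/{summary.n_selected}")
print(f"replicated at p < 0.05 with same sign: {summary.n_replicated}")
print(f"Pearson r of the 30 slope pairs: {summary.slope_correlation:.3f}")
# All 30 pairs share their sign, so the replication criterion (significant
# slope, same direction) is met by every row of the printed table.
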