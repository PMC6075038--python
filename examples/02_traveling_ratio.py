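"""Traveling ratios and K-means gene classes on simulated NET-seq data.

Simulates ~310 genes in three planted pausing-response classes for a
baseline ("wt") and a pausing-factor mutant ("mut"), computes 5'/3'
traveling ratios per transcript, clusters genes on their log ratios and
compares the genotypes per cluster.
"""

import pandas as pd

from pausepier.demo import run_tr_recovery

res = run_tr_recovery(seed=1)

print(f"eligible transcripts: {res['n_transcripts']}")
print(
    f"median 5' TR: wt={res['median_tr5_wt']:.2f}  mut={res['median_tr5_mut']:.2f}"
    f"   (KS p={res['tr5_ks_p']:.2e})"
)
print(
    f"median 3' TR: wt={res['median_tr3_wt']:.2f}  mut={res['median_tr3_mut']:.2f}"
    f"   (KS p={res['tr3_ks_p']:.2e})"
)
print(f"planted-class recovery (adjusted Rand index): {res['ari']:.3f}")
print("\nper-cluster summary:")
cols = ["cluster", "n", "tr5_ks_p", "tr3_ks_p"]
print(res["cluster_summary"][cols].to_string(index=False))
print(
    "\nA TR of 1 means uniform polymerase density; the mutant's lower 5' and"
    "\nhigher 3' medians reproduce the loss of 5' pausing with release into"
    "\nthe gene body."
)
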