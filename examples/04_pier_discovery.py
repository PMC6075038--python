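"""Discover an ectopic heterochromatin domain (PIER) from ChIP-seq tracks.

Simulates an isolate IP track carrying one spiked 6-kb H3K9me2 domain at
5x enrichment (absent from the parental strain), plus WCE and parental
tracks, and runs the dual 3-fold criteria with 10-kb exclusion zones.
"""

import numpy as np

from pausepier import Interval
from pausepier.chipseq import discover_piers, pier_list, piers_to_frame, prepare_chip_track
from pausepier.demo import chip_scenario_config
from pausepier.simulate import (
    ChipDomain,
    make_toy_genome,
    plant_truth,
    simulate_chipseq,
)

domain = ChipDomain(Interval("chrI", 150_000, 156_000), enrichment_fold=5.0,
                    in_parental=False)
cfg = chip_scenario_config(seed=1, domains=[domain])
ann = make_toy_genome(cfg)
truth = plant_truth(ann, cfg)

ip = prepare_chip_track(simulate_chipseq(ann, cfg, truth, "isolate"))
wce = prepare_chip_track(simulate_chipseq(ann, cfg, truth, "wce"))
parental = prepare_chip_track(simulate_chipseq(ann, cfg, truth, "parental"))

calls = discover_piers(ip, wce, parental, ann.curated_sites)
print("candidate domains with exclusion flags:")
print(piers_to_frame(calls).to_string(index=False))
piers = pier_list(calls)
print(f"\nPIERs called: {len(piers)}")
for p in piers:
    print(
        f"  [{p.iv.start},{p.iv.end})  IP/background={p.peak_fold_over_background:.1f}x"
        f"  enrichment={p.enrichment_fold:.1f}x  vs parental={p.parental_fold:.1f}x"
    )
print(
    "\nThe planted domain is recovered (boundaries within one smoothing"
    "\nwindow); a domain near a curated nucleation site or present in the"
    "\nparental strain would instead be excluded with a reason flag."
)
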