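"""Call pause peaks and sliding-window clusters on a small NET-seq track.

Builds a 2-kb region with Poisson background and three planted pauses, then
runs robust-Z peak calling (Z >= 2 over log2 counts of covered positions,
>= 10 reads) and window clustering (width 50 nt, step 10 nt).
"""

import numpy as np

from pausepier import Interval, SignalTrack, call_peaks, find_clusters

rng = np.random.default_rng(0)
size = 2000
track = SignalTrack({"chrI": size})
v = track.values("chrI", "+")
v[:] = rng.poisson(0.3, size)  # sparse elongating-polymerase background
for pos, reads in [(400, 35), (430, 22), (1500, 60)]:
    v[pos] += reads  # planted pause sites

region = Interval("chrI", 0, size, "+")
peaks = call_peaks(track, region, z_min=2, min_reads=10)
clusters = find_clusters(peaks, track, region, width=50, step=10)

print(f"called {len(peaks)} pause peaks:")
for p in peaks:
    print(f"  pos={p.pos}  reads={p.reads:.0f}  robust_Z={p.z:.2f}")
print(f"\ngrouped into {len(clusters)} clusters:")
for c in clusters:
    print(
        f"  span=[{c.iv.start},{c.iv.end})  peaks={len(c.peaks)}  "
        f"reads={c.reads_total:.0f}  density={c.density:.0f} reads/kb"
    )
print(
    "\nThe two nearby pauses share a 50-nt window and merge into one cluster;"
    "\ncluster density (reads/kb over the occupied span) is the pausing score."
)
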