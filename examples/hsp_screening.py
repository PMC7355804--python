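"""Hansen solubility parameter screening: which Transcutol-HP + water blend
sits closest to piperine's own solubility parameter?"""

from cosolvency import mixture_hsp, proximity_rank
from cosolvency.piperine import HSP_TOTALS

d_ppn = HSP_TOTALS["piperine"]
d_thp = HSP_TOTALS["Transcutol-HP"]
d_water = HSP_TOTALS["water"]

candidates = [("water (m=0.0)", d_water)]
for i in range(1, 10):
    m = round(0.1 * i, 1)
    candidates.append((f"m={m}", mixture_hsp(m, d_thp, d_water)))
candidates.append(("THP (m=1.0)", d_thp))

print(f"piperine delta = {d_ppn} MPa^1/2\n")
print("rank  blend          delta_mix   |delta - delta_ppn|")
for rank, (label, delta, dist) in enumerate(proximity_rank(d_ppn, candidates), 1):
    print(f"{rank:4d}  {label:13s}  {delta:8.2f}   {dist:8.2f}")

# Pure THP (21.40) and the m = 0.9 blend (24.04) bracket piperine (22.30):
# the closest-delta blends are exactly where measured solubility peaks.
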