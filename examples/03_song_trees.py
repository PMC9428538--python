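"""Song-level LSI and DSI trees on the bundled synthetic survey.

Loads the synthetic South Pacific table (19 included singers across two
populations and three years), computes both song-level similarity indices,
clusters each with UPGMA, and prints the cophenetic correlation plus the
top-level split. The pre-revolution Ecuador singers (2016/2017) separate
from everyone else; the 2018 Ecuador singers join the French Polynesian
song-type-1 cluster — the signature of an eastward song revolution.
"""

import numpy as np

import whalesong as ws
from whalesong.datasets import south_pacific_song_strings

songs = south_pacific_song_strings()
print(f"{len(songs)} included singers")

# sequence view: LSI over compressed theme sequences
lsi_sim = ws.pairwise_lsi(songs)
d = lsi_sim.to_dissimilarity()
tree = ws.upgma(d)
print(f"LSI tree CCC: {ws.ccc(d, tree):.4f}")

# repertoire view: Dice overlap of theme sets
labels = tuple(s for s, _ in songs)
sets = [frozenset(t) for _, t in songs]
v = np.ones((len(sets), len(sets)))
for i in range(len(sets)):
    for j in range(i + 1, len(sets)):
        v[i, j] = v[j, i] = ws.dsi(sets[i], sets[j])
d2 = ws.SimilarityMatrix(labels, v).to_dissimilarity()
tree2 = ws.upgma(d2)
print(f"DSI tree CCC: {ws.ccc(d2, tree2):.4f}")

for name, t in (("LSI", tree), ("DSI", tree2)):
    parts = ws.cut_tree(t, 2)
    groups = {}
    for singer, cid in parts.items():
        groups.setdefault(cid, []).append(singer)
    print(f"{name} top-level split:")
    for cid in sorted(groups):
        print("   ", " ".join(sorted(groups[cid])))
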