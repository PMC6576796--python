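"""Build an nMI coupling network and rank fragments by centrality.

Plants one coupled fragment pair among 60 otherwise independent fragments,
computes all pairwise bias-corrected normalized mutual informations,
thresholds at mean + 2 sigma, and reports the surviving couplings and the
eigenvector-centrality profile.  The planted pair should top both lists.
"""

import numpy as np

from fragnet import (coupling_matrix, eigenvector_centrality, markov_letters,
                     threshold_and_filter)

m = markov_letters(n_fragments=60, n_frames=500, planted_pairs=((10, 45),),
                   coupling_strength=0.9, seed=42)
cm = coupling_matrix(m)
print(f"candidate couplings: {cm.n_candidate_pairs} "
      f"(= n(n-1)/2 for n = {cm.n_fragments})")

net = threshold_and_filter(cm, sigma_k=2.0)
print(f"2-sigma threshold: nMI >= {net.threshold_value:.4f}; "
      f"{net.n_edges} coupling(s) retained")
for i, j, nmi, dist in net.edges[:5]:
    print(f"  fragments {i:2d}-{j:2d}: nMI = {nmi:.3f}")

cent = eigenvector_centrality(cm)
top = np.argsort(cent.centrality)[::-1][:3]
print("highest-centrality fragments (max normalised to 1):")
for i in top:
    print(f"  fragment {i:2d}: centrality {cent.centrality[i]:.3f}")
print("the planted pair (10, 45) carries the only real coupling, so those "
      "two fragments dominate the leading eigenvector.")
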