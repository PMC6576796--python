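"""The full pipeline on a synthetic dimer with a planted signal relay.

Generates a two-chain ensemble carrying three chained couplings (a relay
running chain A -> chain B -> chain B -> chain A), writes it as a
multi-model PDB, runs the complete encode -> couple -> threshold ->
centrality/communities pipeline, and shows that the relay dominates the
top-coupling list and the centrality profile.

Writes outputs under scratch/relay_demo/ (state matrices, edge list,
centrality and community tables, painted PDBs, manifest).
"""

import json
from pathlib import Path

import pandas as pd

from fragnet import (PipelineConfig, SyntheticSpec, coupled_two_state_ensemble,
                     run_pipeline, write_multimodel_pdb)

out = Path("scratch/relay_demo")
out.mkdir(parents=True, exist_ok=True)

relay = ((3, 32), (32, 45), (45, 12))  # A -> B -> B -> A signal path
spec = SyntheticSpec(n_residues=30, n_chains=2, n_frames=2000,
                     planted_pairs=relay, coupling_strength=0.9,
                     switch_rate=0.2, background_fragments=(20, 50), seed=42)
ens, _, _ = coupled_two_state_ensemble(spec)
pdb = write_multimodel_pdb(ens, out / "dimer.pdb")

cfg = PipelineConfig(inputs=[str(pdb)], output_dir=str(out / "analysis"),
                     long_range_cutoff=12.0, log_level="WARNING")
manifest = run_pipeline(cfg)

print(f"fragments: {manifest['n_fragments']}, candidate pairs: "
      f"{manifest['n_candidate_pairs']}")
print(f"2-sigma threshold: {manifest['threshold_value']:.3f}; "
      f"{manifest['n_edges']} couplings retained")

edges = pd.read_csv(out / "analysis" / "edges.tsv", sep="\t")
pairs = {frozenset((r.frag_i, r.frag_j)) for r in edges.itertuples()}
print("planted relay couplings recovered:",
      sum(frozenset(p) in pairs for p in relay), "of", len(relay))

cent = pd.read_csv(out / "analysis" / "centrality.tsv", sep="\t")
top = cent.sort_values("centrality", ascending=False).head(3)
print("top-centrality fragments (id = chain:first_residue):")
for r in top.itertuples():
    print(f"  {r.id}: {r.centrality:.3f}")
print("the hub fragments cover the central segments of the planted relay, "
      "mirroring a captured regulatory segment acting as network hub.")
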