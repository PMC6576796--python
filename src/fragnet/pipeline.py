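"""One-command orchestration: encode -> couple -> filter -> centrality /
communities -> fluctuation & PCA reports.

Given one or more replica ensembles the pipeline writes, into the output
directory: per-replica fragment state matrices (TSV), the thresholded
coupling edge list, eigenvector-centrality tables and a centrality-painted
PDB, the community table and community graph (GraphML), RMSF/pseudo-B
profiles and a painted PDB, PC1/PC2 projections, and a manifest recording
the configuration hash and every threshold actually used.  Output is a pure
function of (inputs, config): identical configs give byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .alphabet import encode_ensemble, load_alphabet
from .ensemble import AtomSelection, read_ensemble, write_annotated_pdb
from .info import (community_graph, coupling_matrix, detect_communities,
                   eigenvector_centrality, threshold_and_filter)
from .motions import pca_ensemble, project_and_spread, rmsf_profile, superpose

log = logging.getLogger(__name__)

__all__ = ["ConfigError", "PipelineConfig", "PipelineError", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`.

    Defaults follow the analysis conventions: significance threshold at
    mean + 2 sigma of the off-diagonal nMI, 12 Å long-range spatial cutoff,
    communities reported above size 3.
    """

    inputs: list[str] = field(default_factory=list)
    input_format: str = "multimodel-pdb"
    chain: str | None = None
    residue_range: tuple[int, int] | None = None
    alphabet: str = "SA25"
    sigma_k: float = 2.0
    explicit_threshold: float | None = None
    long_range_cutoff: float | None = 12.0
    community_min_size: int = 3
    window: int = 50
    stride: int = 10
    output_dir: str = "fragnet_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.sigma_k < 0:
            raise ConfigError("sigma_k must be >= 0")
        if self.residue_range is not None:
            self.residue_range = tuple(self.residue_range)  # type: ignore[assignment]

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        try:
            data = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as e:
            raise ConfigError(f"cannot read config {path}: {e}") from e
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def canonical_json(self) -> str:
        d = asdict(self)
        if d.get("residue_range") is not None:
            d["residue_range"] = list(d["residue_range"])
        return json.dumps(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def _stage(name: str, source: str = ""):
    """Decorator-free stage guard: re-raise with stage provenance."""
    class _Guard:
        def __enter__(self):
            log.info("stage %s%s", name, f" [{source}]" if source else "")
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed"
                                    + (f" for {source}" if source else "")
                                    + f": {exc}") from exc
            return False
    return _Guard()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full coupling-network analysis; returns the manifest dict."""
    if not cfg.inputs:
        raise ConfigError("config lists no input ensembles")
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)

    with _stage("load-alphabet", cfg.alphabet):
        alpha = load_alphabet(cfg.alphabet)

    selection = None
    if cfg.chain is not None or cfg.residue_range is not None:
        selection = AtomSelection(chain_id=cfg.chain, residue_range=cfg.residue_range)

    ensembles, matrices = [], []
    for k, path in enumerate(cfg.inputs):
        with _stage("read-ensemble", path):
            ens = read_ensemble(path, format=cfg.input_format)
            if selection is not None:
                from .ensemble import select_subset
                ens = select_subset(ens, selection)
        ensembles.append(ens)
        with _stage("encode", path):
            m = encode_ensemble(ens, alpha)
            m.to_tsv(out / f"states_rep{k}.tsv")
        matrices.append(m)
        log.info("replica %d: %d frames, %d fragments", k, m.n_frames, m.n_fragments)

    with _stage("coupling-matrix"):
        cm = coupling_matrix(matrices)
    with _stage("threshold"):
        net = threshold_and_filter(cm, sigma_k=cfg.sigma_k,
                                   min_distance=cfg.long_range_cutoff,
                                   explicit_threshold=cfg.explicit_threshold)
        net.edge_table().to_csv(out / "edges.tsv", sep="\t", index=False,
                                float_format="%.6f")
    log.info("threshold %.6f: %d of %d candidate pairs retained",
             net.threshold_value, net.n_edges, cm.n_candidate_pairs)

    with _stage("centrality"):
        cent = eigenvector_centrality(cm)
        rows = [(i, f"{c}:{r}", float(cent.centrality[i]))
                for i, (c, r) in enumerate(cm.fragment_map)]
        pd.DataFrame(rows, columns=["fragment", "id", "centrality"]).to_csv(
            out / "centrality.tsv", sep="\t", index=False, float_format="%.6f")
        write_annotated_pdb(
            ensembles[0],
            {key: 100.0 * v for key, v in cent.per_residue().items()},
            out / "centrality.pdb",
        )

    with _stage("communities"):
        part = detect_communities(net, min_reported_size=cfg.community_min_size)
        rows = [(i, f"{c}:{r}", part.labels.get(i, -1))
                for i, (c, r) in enumerate(cm.fragment_map)]
        pd.DataFrame(rows, columns=["fragment", "id", "community"]).to_csv(
            out / "communities.tsv", sep="\t", index=False)
        cg = community_graph(part, net)
        nx.write_graphml(cg.to_networkx(), out / "community_graph.graphml")

    with _stage("superpose-rmsf"):
        fit = superpose(ensembles[0])
        prof = rmsf_profile(fit.ensemble)
        pd.DataFrame(
            [(f"{c}:{r}", v, 8.0 * np.pi ** 2 / 3.0 * v * v)
             for (c, r), v in sorted(prof.residue_rmsf.items())],
            columns=["residue", "rmsf_A", "pseudo_b_A2"],
        ).to_csv(out / "rmsf.tsv", sep="\t", index=False, float_format="%.6f")
        write_annotated_pdb(ensembles[0],
                            {k2: v for k2, v in prof.residue_rmsf.items()},
                            out / "rmsf.pdb")

    with _stage("pca"):
        pca = pca_ensemble(fit.ensemble)
        ncomp = min(2, pca.n_components)
        cloud = project_and_spread(fit.ensemble, pca, components=(1, 2))
        df = pd.DataFrame(cloud.points[:, :2], columns=["PC1", "PC2"])
        df.insert(0, "frame", np.arange(len(df)))
        df.to_csv(out / "pca_projections.tsv", sep="\t", index=False,
                  float_format="%.6f")

    manifest = {
        "fragnet_version": __version__,
        "config": json.loads(cfg.canonical_json()),
        "config_hash": cfg.config_hash(),
        "n_replicas": len(matrices),
        "n_fragments": cm.n_fragments,
        "n_candidate_pairs": cm.n_candidate_pairs,
        "threshold_value": net.threshold_value,
        "threshold_sigma": net.threshold_sigma,
        "long_range_cutoff": cfg.long_range_cutoff,
        "n_edges": net.n_edges,
        "n_communities": len(part.sizes()),
        "modularity": part.modularity,
        "principal_eigenvalue": cent.eigenvalue,
        "pc1_pc2_variance_fraction": float(pca.cumulative_fraction[ncomp - 1]),
        "hull_area_pc1_pc2": cloud.hull_area,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
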