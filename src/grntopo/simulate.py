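"""Synthetic inputs: power-law degree sequences and in-silico GRNs.

The in-silico GRN generator follows the static (fitness-based) power-law
model: a designated fraction of nodes (default 5%, mimicking the share of
genes encoding TFs) is allowed out-going edges; TF number i carries weight
w_i = i^(-1/(alpha-1)); each edge picks its TF proportionally to w and its
target uniformly among all nodes.  Duplicate edges are removed and the
deficit redrawn until the requested edge count is met exactly, so the
out-degree total always equals the number of PDIs.  The resulting
out-degree distribution follows a power law with the target exponent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .models import PowerLawModel
from .network import DegreeSequence, DirectedGRN, read_edge_list, build_grn


def generate_powerlaw_degrees(
    model: PowerLawModel, n: int, seed: int | np.random.Generator
) -> DegreeSequence:
    """Draw ``n`` i.i.d. degrees from the discrete power law (out-direction)."""
    return DegreeSequence(values=model.sample(n, seed), direction="out")


@dataclass(frozen=True)
class SyntheticGRNConfig:
    """Recipe for one in-silico GRN."""

    target_exponent: float
    n_edges: int
    n_nodes: int
    tf_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.tf_fraction <= 1):
            raise ValueError("tf_fraction must be in (0, 1]")
        if self.n_edges < 1 or self.n_nodes < 2:
            raise ValueError("need n_edges >= 1 and n_nodes >= 2")
        if self.target_exponent <= 1:
            raise ValueError("target_exponent must exceed 1")
        if self.n_edges > self.n_tfs * self.n_nodes:
            raise ValueError(
                f"{self.n_edges} edges infeasible: at most "
                f"{self.n_tfs * self.n_nodes} distinct TF→target pairs exist"
            )

    @property
    def n_tfs(self) -> int:
        return max(1, int(round(self.tf_fraction * self.n_nodes)))


def generate_insilico_grn(config: SyntheticGRNConfig) -> DirectedGRN:
    """Build one in-silico GRN under the static power-law model.

    Nodes 0..n_tfs-1 are the TF-coding genes (the only ones permitted
    out-going edges); every node may receive edges.  The graph is simple:
    duplicates are dropped and missing edges redrawn until the count is
    exact, so sum(out-degrees) == n_edges.
    """
    rng = np.random.default_rng(config.seed)
    n_tf, n_nodes, m = config.n_tfs, config.n_nodes, config.n_edges
    xi = 1.0 / (config.target_exponent - 1.0)
    w = np.arange(1, n_tf + 1, dtype=float) ** (-xi)
    w /= w.sum()
    seen = np.zeros(n_tf * n_nodes, dtype=bool)
    kept = 0
    chunks: list[np.ndarray] = []
    deficit = m
    stall = 0
    while deficit > 0:
        draw = max(deficit, 32)
        tf = rng.choice(n_tf, size=draw, p=w)
        tg = rng.integers(0, n_nodes, size=draw)
        codes = tf.astype(np.int64) * n_nodes + tg
        codes = np.unique(codes)
        fresh = codes[~seen[codes]]
        if fresh.size > deficit:
            fresh = fresh[rng.choice(fresh.size, size=deficit, replace=False)]
        seen[fresh] = True
        chunks.append(fresh)
        kept += fresh.size
        stall = stall + 1 if fresh.size == 0 else 0
        if stall > 200:
            raise RuntimeError("edge generation stalled; config near saturation")
        deficit = m - kept
    codes = np.concatenate(chunks)
    edges = np.empty((m, 2), dtype=np.int64)
    edges[:, 0] = codes // n_nodes
    edges[:, 1] = codes % n_nodes
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    edges = edges[order]
    width = len(str(n_nodes - 1))
    node_ids = np.array([f"g{i:0{width}d}" for i in range(n_nodes)])
    return DirectedGRN(node_ids=node_ids, edges=edges)


def write_pdi_fixture(grn: DirectedGRN, path) -> Path:
    """Write the GRN as a two-column TSV edge list (header ``tf<TAB>target``)."""
    if grn.n_edges == 0:
        raise ValueError("refusing to write an empty GRN")
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("tf\ttarget\n")
        for a, b in grn.edges:
            fh.write(f"{grn.node_ids[a]}\t{grn.node_ids[b]}\n")
    return path


def read_pdi_fixture(path) -> DirectedGRN:
    """Round-trip companion of :func:`write_pdi_fixture`."""
    return build_grn(read_edge_list(path))
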