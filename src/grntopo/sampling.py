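"""Edge-sampled subnetworks and the size threshold of scale-freeness.

Sampling edges — rather than nodes — mimics how GRNs are assembled
experimentally: every sampled interaction brings both its TF and its
target into the subnetwork, so no singleton nodes arise.  A node's chance
of inclusion is proportional to its degree (Pr ∝ p·k_i/k_T), which is why
edge-sampled subnetworks inherit the parent's power-law out-degree
distribution down to a size threshold.  That threshold is located with a
two-segment ("knee point") fit on a per-size summary such as the SD of
subnetwork exponents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import gof_pvalue, select_kmin
from .network import DirectedGRN


def _subsample_size(p: float, n_edges: int) -> int:
    # round-half-up, so p = 0.5 of 26,091 edges gives 13,046
    return int(np.floor(p * n_edges + 0.5))


def sample_edges(
    grn: DirectedGRN, p: float, seed: int | np.random.Generator | None = None
) -> DirectedGRN:
    """Uniform without-replacement sample of round(p·|E|) edges.

    The subnetwork's nodes are exactly the endpoints of the chosen edges.
    ``p = 1`` returns a graph identical to the parent.
    """
    if not (0 < p <= 1):
        raise ValueError("p must lie in (0, 1]")
    m = _subsample_size(p, grn.n_edges)
    if m < 1:
        raise ValueError(f"p={p} keeps zero of {grn.n_edges} edges")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if m == grn.n_edges:
        chosen = grn.edges
    else:
        take = rng.choice(grn.n_edges, size=m, replace=False)
        chosen = grn.edges[np.sort(take)]
    touched = np.unique(chosen)
    remap = np.full(grn.n_nodes, -1, dtype=np.int64)
    remap[touched] = np.arange(touched.size)
    return DirectedGRN(node_ids=grn.node_ids[touched], edges=remap[chosen])


def bernoulli_sample_edges(
    grn: DirectedGRN, p: float, seed: int | np.random.Generator | None = None
) -> DirectedGRN:
    """Per-edge Bernoulli(p) variant (random subnetwork size)."""
    if not (0 < p <= 1):
        raise ValueError("p must lie in (0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    keep = rng.random(grn.n_edges) < p
    if not keep.any():
        raise ValueError("Bernoulli sampling kept zero edges")
    chosen = grn.edges[keep]
    touched = np.unique(chosen)
    remap = np.full(grn.n_nodes, -1, dtype=np.int64)
    remap[touched] = np.arange(touched.size)
    return DirectedGRN(node_ids=grn.node_ids[touched], edges=remap[chosen])


@dataclass(frozen=True)
class SubnetSampleRecord:
    proportion: float
    replicate: int
    alpha: float
    kmin: int
    ks_D: float
    gof_p: float | None
    n_edges: int
    n_nodes: int


def exponent_vs_size(
    grn: DirectedGRN,
    proportions,
    r: int = 1000,
    seed: int | None = None,
    tail_floor: int = 10,
    method: str = "exact",
    gof: bool = False,
    n_boot: int = 200,
) -> pd.DataFrame:
    """Fit the out-degree power law of r edge-sampled subnetworks per size.

    Returns a long-format frame (proportion, replicate, alpha, kmin, D,
    gof_p, n_edges, n_nodes).  Failed fits are recorded as NaN rows, never
    fatal.  GOF bootstrap per replicate is opt-in (it dominates runtime).
    """
    ss = np.random.SeedSequence(seed)
    rows: list[SubnetSampleRecord] = []
    for p in proportions:
        if not (0 < p <= 1):
            raise ValueError(f"proportion {p} outside (0, 1]")
        children = ss.spawn(r)
        for j in range(r):
            child = np.random.default_rng(children[j])
            sub = sample_edges(grn, p, child)
            deg = sub.out_degree_counts()
            deg = deg[deg > 0]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = select_kmin(deg, tail_floor=tail_floor, method=method)
                    gp = (
                        gof_pvalue(fit, deg, n_boot=n_boot, seed=child,
                                   tail_floor=tail_floor)
                        if gof
                        else None
                    )
                rows.append(SubnetSampleRecord(p, j, fit.alpha, fit.kmin,
                                               fit.ks_D, gp, sub.n_edges,
                                               sub.n_nodes))
            except (ValueError, RuntimeError):
                rows.append(SubnetSampleRecord(p, j, np.nan, 0, np.nan, None,
                                               sub.n_edges, sub.n_nodes))
    return pd.DataFrame([r.__dict__ for r in rows])


def summarize_by_proportion(records: pd.DataFrame) -> pd.DataFrame:
    """Per-proportion mean/SD of alpha and fraction of plausible fits."""
    def frac_plausible(g):
        p = g.dropna()
        return np.nan if p.empty else float((p > 0.1).mean())

    grouped = records.groupby("proportion")
    out = grouped.agg(
        alpha_mean=("alpha", "mean"),
        alpha_sd=("alpha", lambda a: a.std(ddof=1)),
        n_failed=("alpha", lambda a: int(a.isna().sum())),
        mean_edges=("n_edges", "mean"),
        mean_nodes=("n_nodes", "mean"),
    )
    out["frac_gof_plausible"] = grouped["gof_p"].apply(frac_plausible)
    return out.reset_index()


@dataclass(frozen=True)
class KneePoint:
    x: float
    index: int
    sse: float
    defined: bool


def knee_point(x, y, collinear_tol: float = 1e-12) -> KneePoint:
    """Two-segment least-squares knee detection.

    At every interior bisection index a straight line is fitted to each
    side (the bisection point belongs to both segments); the knee is the
    bisection minimizing the total sum of squared errors, ties toward
    smaller x.  Exactly collinear data has no knee and is flagged
    ``defined=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need >= 5 (x, y) points")
    order = np.argsort(x)
    x, y = x[order], y[order]

    def sse(xs, ys) -> float:
        coef, res, *_ = np.polyfit(xs, ys, 1, full=True)
        return float(res[0]) if res.size else 0.0

    whole = sse(x, y)
    scale = float(np.sum((y - y.mean()) ** 2)) or 1.0
    if whole / scale < collinear_tol:
        return KneePoint(x=np.nan, index=-1, sse=whole, defined=False)
    best = None
    for i in range(2, x.size - 2):
        total = sse(x[: i + 1], y[: i + 1]) + sse(x[i:], y[i:])
        if best is None or total < best[0] - 1e-15:
            best = (total, i)
    total, i = best
    return KneePoint(x=float(x[i]), index=int(i), sse=total, defined=True)
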