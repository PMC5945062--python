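"""Lorenz-curve inequality analysis of TF→target binding.

TFs are ranked by increasing out-degree; the curve plots the cumulative
proportion of bound-target degree mass against the cumulative proportion
of TFs.  The diagonal is the egalitarian reference ("every TF binds the
same number of targets"); sag below it measures how disproportionately
hub TFs dominate binding.  The Gini coefficient summarizes a curve, and
simulated curves show equality rising with the power-law exponent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import PowerLawModel
from .simulate import generate_powerlaw_degrees


@dataclass(frozen=True)
class LorenzCurve:
    tf_fractions: np.ndarray  # x: cumulative proportion of TFs (low degree first)
    target_share: np.ndarray  # y: cumulative proportion of degree mass

    def __post_init__(self) -> None:
        x = np.asarray(self.tf_fractions, dtype=float)
        y = np.asarray(self.target_share, dtype=float)
        if x.shape != y.shape or x.ndim != 1 or x.size < 2:
            raise ValueError("curve needs matching 1-D arrays of length >= 2")
        object.__setattr__(self, "tf_fractions", x)
        object.__setattr__(self, "target_share", y)

    def share_at(self, x: float) -> float:
        """Linear interpolation of the curve at a TF fraction."""
        return float(np.interp(x, self.tf_fractions, self.target_share))


def lorenz_curve(degrees) -> LorenzCurve:
    """Lorenz curve of a positive degree sequence (sorted ascending)."""
    v = np.sort(np.asarray(degrees, dtype=float).ravel())
    if v.size == 0 or v.sum() <= 0:
        raise ValueError("need at least one positive degree")
    if v.min() < 0:
        raise ValueError("degrees must be non-negative")
    n = v.size
    x = np.arange(0, n + 1) / n
    y = np.concatenate(([0.0], np.cumsum(v) / v.sum()))
    return LorenzCurve(tf_fractions=x, target_share=y)


def top_share(curve: LorenzCurve, fraction: float) -> float:
    """Share of target-degree mass bound by the top ``fraction`` of TFs."""
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie strictly between 0 and 1")
    return 1.0 - curve.share_at(1.0 - fraction)


def gini(curve: LorenzCurve) -> float:
    """Gini coefficient: 1 − 2 × (trapezoidal area under the curve)."""
    area = float(np.trapezoid(curve.target_share, curve.tf_fractions))
    return 1.0 - 2.0 * area


def simulated_lorenz(
    alpha: float,
    n: int,
    seed: int | np.random.Generator,
    replicates: int = 10,
    kmin: int = 1,
    kmax: int | None = None,
) -> LorenzCurve:
    """Average Lorenz curve of power-law degree samples at a given exponent.

    ``kmax`` defaults to ``n`` (a TF cannot bind more genes than exist in
    the simulated genome).  Curves from all replicates share the same rank
    grid, so averaging is taken pointwise in the cumulative share.
    """
    if n < 100:
        raise ValueError("n >= 100 required for a stable simulated curve")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    model = PowerLawModel(alpha=alpha, kmin=kmin, kmax=n if kmax is None else kmax)
    acc = np.zeros(n + 1)
    for _ in range(replicates):
        deg = generate_powerlaw_degrees(model, n, rng)
        acc += lorenz_curve(deg).target_share
    x = np.arange(0, n + 1) / n
    return LorenzCurve(tf_fractions=x, target_share=acc / replicates)


def curve_frame(curve: LorenzCurve):
    """Long-format table (rank, tf_fraction, target_share) for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "rank": np.arange(curve.tf_fractions.size),
            "tf_fraction": curve.tf_fractions,
            "target_share": curve.target_share,
        }
    )
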