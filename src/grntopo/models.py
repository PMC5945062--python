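"""Discrete (zeta-normalized) power-law degree distribution.

The distribution of node degrees k on the integer support {kmin, ..., kmax}
is P(k) = k^(-alpha) / C, where C is the (generalized/Hurwitz) zeta
normalizer.  With kmax unbounded, C = zeta(alpha, kmin), which requires
alpha > 1; with a finite kmax, C = zeta(alpha, kmin) - zeta(alpha, kmax+1)
and any alpha > 0 is admissible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special


def hurwitz_zeta(alpha: float, a) -> np.ndarray | float:
    """Hurwitz zeta ``sum_{j>=0} (j+a)^-alpha`` for alpha > 1 (vectorized in a)."""
    return special.zeta(alpha, a)


def _finite_norm(alpha: float, kmin: int, kmax: int) -> float:
    # zeta(alpha, q) needs alpha > 1; fall back to a direct sum otherwise.
    if alpha > 1.0:
        return float(special.zeta(alpha, kmin) - special.zeta(alpha, kmax + 1))
    k = np.arange(kmin, kmax + 1, dtype=float)
    return float(np.sum(k ** (-alpha)))


@dataclass(frozen=True)
class PowerLawModel:
    """Truncated discrete power law P(k) ∝ k^-alpha on {kmin..kmax}.

    Parameters
    ----------
    alpha : float
        Scaling exponent. Must exceed 1 when ``kmax`` is unbounded
        (otherwise the distribution is non-normalizable).
    kmin : int
        Smallest supported degree (>= 1).
    kmax : int or None
        Largest supported degree; ``None`` means unbounded.
    """

    alpha: float
    kmin: int = 1
    kmax: int | None = None

    def __post_init__(self) -> None:
        if self.kmin < 1 or int(self.kmin) != self.kmin:
            raise ValueError(f"kmin must be a positive integer, got {self.kmin}")
        if self.kmax is not None and self.kmax < self.kmin:
            raise ValueError(f"kmax ({self.kmax}) < kmin ({self.kmin})")
        if self.kmax is None and self.alpha <= 1.0:
            raise ValueError(
                "alpha <= 1 with unbounded kmax is non-normalizable; "
                "supply a finite kmax or use alpha > 1"
            )
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    @property
    def normalizer(self) -> float:
        """The constant C such that sum_k k^-alpha / C = 1 on the support."""
        if self.kmax is None:
            return float(special.zeta(self.alpha, self.kmin))
        return _finite_norm(self.alpha, self.kmin, self.kmax)

    # -- probability functions -------------------------------------------------

    def pmf(self, k) -> np.ndarray:
        k = np.asarray(k, dtype=float)
        out = np.where(
            self._in_support(k), k ** (-self.alpha) / self.normalizer, 0.0
        )
        return out

    def logpmf(self, k) -> np.ndarray:
        k = np.asarray(k, dtype=float)
        with np.errstate(divide="ignore"):
            out = np.where(
                self._in_support(k),
                -self.alpha * np.log(k) - np.log(self.normalizer),
                -np.inf,
            )
        return out

    def sf(self, k) -> np.ndarray:
        """P(K >= k), the survival function at integer k."""
        k = np.asarray(k, dtype=float)
        kk = np.clip(k, self.kmin, None)
        if self.alpha > 1.0:
            upper = special.zeta(self.alpha, kk)
            if self.kmax is not None:
                upper = upper - special.zeta(self.alpha, self.kmax + 1)
        else:
            # finite support guaranteed by the constructor
            grid = np.arange(self.kmin, self.kmax + 1, dtype=float)
            tail = np.cumsum((grid ** (-self.alpha))[::-1])[::-1]
            idx = np.clip(kk, self.kmin, self.kmax).astype(int) - self.kmin
            upper = tail[idx]
        out = np.clip(upper / self.normalizer, 0.0, 1.0)
        out = np.where(k < self.kmin, 1.0, out)
        if self.kmax is not None:
            out = np.where(k > self.kmax, 0.0, out)
        return out

    def cdf(self, k) -> np.ndarray:
        """P(K <= k) at integer k."""
        k = np.asarray(k, dtype=float)
        return 1.0 - self.sf(np.floor(k) + 1.0)

    def _in_support(self, k: np.ndarray) -> np.ndarray:
        ok = (k >= self.kmin) & (k == np.floor(k))
        if self.kmax is not None:
            ok &= k <= self.kmax
        return ok

    # -- sampling --------------------------------------------------------------

    def sample(self, n: int, rng: np.random.Generator | int) -> np.ndarray:
        """Draw ``n`` i.i.d. degrees by exact inverse-CDF sampling.

        With finite kmax the full pmf table is tabulated and inverted; with
        unbounded support, each uniform draw is inverted by bisection on the
        zeta survival function.
        """
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        if self.kmax is not None:
            grid = np.arange(self.kmin, self.kmax + 1, dtype=float)
            cdf = np.cumsum(grid ** (-self.alpha))
            cdf /= cdf[-1]
            u = rng.random(n)
            return (self.kmin + np.searchsorted(cdf, u, side="left")).astype(np.int64)
        return self._sample_unbounded(n, rng)

    def _sample_unbounded(self, n: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.random(n)
        cdf = lambda k: 1.0 - self.sf(k + 1)  # noqa: E731
        # smallest k with CDF(k) >= u; maintain cdf(lo) < u <= cdf(hi)
        lo = np.full(n, self.kmin - 1, dtype=np.int64)
        hi = np.full(n, self.kmin, dtype=np.int64)
        short = cdf(hi) < u
        while np.any(short):
            lo = np.where(short, hi, lo)
            hi = np.where(short, hi * 2, hi)
            short = cdf(hi) < u
        while np.any(hi - lo > 1):
            mid = (lo + hi) // 2
            up = cdf(mid) >= u
            hi = np.where(up, mid, hi)
            lo = np.where(up, lo, mid)
        return hi
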