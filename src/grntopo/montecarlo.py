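"""Monte-Carlo inference of complete-GRN properties.

An observed GRN samples only part of an organism's regulatory repertoire.
Treating its out-degrees as a random sample from a large population of
degrees with the same power-law exponent lets two complete-network
properties be predicted:

* the exponent of the complete GRN, via the sampling distribution of the
  MLE at the genome's TF count — a 95% prediction interval around the
  observed exponent;
* the total number of protein-DNA interactions in the complete GRN
  (I_comp = sum of N simulated out-degrees, N = TFs in the genome), with
  a Z-test validating the estimator at N = the observed TF count, where
  the simulated total must match the observed interaction count.

The per-replicate refit policy (re-select kmin, or keep it fixed at the
population's kmin) governs the sampling SD; see
:func:`sampling_distribution` for the trade-off.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import stats

from .fitting import PowerLawFit, mle_exponent, select_kmin
from .models import PowerLawModel
from .network import DegreeSequence


def build_population(
    alpha_pop: float,
    size: int = 10_000,
    kmin: int = 1,
    kmax: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> DegreeSequence:
    """Fixed population of ``size`` degrees with a known exponent.

    ``kmax`` defaults to ``size`` (degree ceiling = number of genes in the
    simulated genome).  The population should dwarf any sample drawn from
    it; a warning is raised downstream if it does not.
    """
    model = PowerLawModel(alpha=alpha_pop, kmin=kmin,
                          kmax=size if kmax is None else kmax)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return DegreeSequence(values=model.sample(size, rng), direction="out")


@dataclass
class SamplingDistribution:
    """MC sampling distribution of the exponent estimator."""

    alpha_pop: float | None
    sample_size: int
    estimates: np.ndarray
    n_excluded: int = 0

    @property
    def sd(self) -> float:
        return float(np.std(self.estimates, ddof=1))

    @property
    def mean(self) -> float:
        return float(np.mean(self.estimates))

    @property
    def skewness(self) -> float:
        return float(stats.skew(self.estimates))

    @property
    def excess_kurtosis(self) -> float:
        return float(stats.kurtosis(self.estimates))

    @property
    def shapiro_p(self) -> float:
        x = self.estimates
        if x.size > 5000:  # Shapiro-Wilk is defined for n <= 5000
            x = x[:5000]
        if np.ptp(x) == 0:
            return 1.0
        return float(stats.shapiro(x).pvalue)

    @property
    def nonnormal(self) -> bool:
        """Flag raised for small-sample regimes (skewed, heavy-tailed estimates)."""
        return self.shapiro_p < 0.01


def sampling_distribution(
    population,
    sample_size: int,
    r: int = 1000,
    seed: int | np.random.Generator | None = None,
    tail_floor: int = 10,
    method: str = "exact",
    replace: bool = True,
    alpha_pop: float | None = None,
    refit_policy: str = "reselect",
    fixed_kmin: int = 1,
) -> SamplingDistribution:
    """Resample the population r times and MLE-refit each sample.

    Samples are drawn with replacement (the census debug mode
    ``replace=False`` with ``sample_size == len(population)`` returns r
    identical estimates).  Pathological samples with a single distinct
    degree value are excluded and counted.

    Two refit policies are available because the per-sample treatment of
    kmin changes the sampling variance considerably:

    * ``"reselect"`` — kmin re-selected inside every refit (what an
      analyst does on a fresh observed sample).  Occasional high-kmin,
      thin-tail refits inflate the SD well beyond the asymptotic
      (alpha−1)/sqrt(n), increasingly so for steep exponents.
    * ``"fixed"`` — kmin frozen at ``fixed_kmin`` (the population's
      kmin) and alpha re-estimated by the exact discrete MLE; the SD
      tracks the asymptotic rate.  This is the policy under which
      prediction intervals for distinct exponents remain disjoint.
    """
    pop = np.asarray(population, dtype=np.int64)
    if sample_size < 2:
        raise ValueError("sample_size must be >= 2")
    if pop.size < 10 * sample_size and replace:
        warnings.warn(
            f"population ({pop.size}) is under 10x the sample size "
            f"({sample_size}); large-population premise is strained"
        )
    if refit_policy not in ("reselect", "fixed"):
        raise ValueError(f"unknown refit_policy {refit_policy!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    estimates = []
    excluded = 0
    for _ in range(r):
        s = rng.choice(pop, size=sample_size, replace=replace)
        if np.unique(s).size < 2:
            excluded += 1
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if refit_policy == "fixed":
                estimates.append(mle_exponent(s, kmin=fixed_kmin, method="exact"))
                continue
            fit = select_kmin(s, tail_floor=tail_floor, method=method)
        estimates.append(fit.alpha)
    if excluded:
        warnings.warn(f"excluded {excluded} pathological all-equal sample(s)")
    return SamplingDistribution(
        alpha_pop=alpha_pop,
        sample_size=sample_size,
        estimates=np.asarray(estimates),
        n_excluded=excluded,
    )


@dataclass(frozen=True)
class PredictionInterval:
    center: float
    lower: float
    upper: float
    level: float
    method: str  # normal_sd | percentile

    def __post_init__(self) -> None:
        if not (self.lower <= self.center <= self.upper):
            raise ValueError("require lower <= center <= upper")

    def overlaps(self, other: "PredictionInterval") -> bool:
        return self.lower <= other.upper and other.lower <= self.upper


def prediction_interval(
    dist: SamplingDistribution,
    center: float,
    level: float = 0.95,
    method: str = "normal_sd",
) -> PredictionInterval:
    """Prediction interval for the complete-GRN exponent.

    ``normal_sd``: center ± z(level)·SD of the MC estimates.
    ``percentile``: center ± half-width of the central level-mass of the
    deviations (estimate − mean) — robust to non-normal small-sample
    regimes.
    """
    if dist.sd == 0.0:
        warnings.warn("sampling distribution has zero SD; degenerate interval")
        return PredictionInterval(center, center, center, level, method)
    if method == "normal_sd":
        z = float(stats.norm.ppf(0.5 + level / 2.0))
        half = z * dist.sd
    elif method == "percentile":
        dev = np.abs(dist.estimates - dist.mean)
        half = float(np.quantile(dev, level))
    else:
        raise ValueError(f"unknown method {method!r}")
    return PredictionInterval(center, center - half, center + half, level, method)


@dataclass
class InteractionEstimate:
    """Simulated PDI total for a (complete or observed-size) GRN."""

    mean_pdis: float
    sd_pdis: float
    n_tfs_used: int
    r: int
    ztest_p: float | None = None


def estimate_interactions(
    fit: PowerLawFit,
    observed_degrees,
    N: int,
    r: int = 1000,
    seed: int | np.random.Generator | None = None,
    genome_genes: int | None = None,
    observed_count: int | None = None,
    force: bool = False,
) -> InteractionEstimate:
    """Estimate the PDI total of a GRN with N TFs by semiparametric simulation.

    Each replicate generates N out-degrees: with probability equal to the
    observed below-kmin mass a degree is resampled from the observed
    below-kmin values, otherwise it is drawn from the fitted power-law
    tail, capped at the genome gene count when given.  The replicate total
    is the interaction count; mean and SD are taken over r replicates.

    Requires a plausible fit (GOF p > 0.1) unless ``force``.
    """
    obs = np.asarray(observed_degrees, dtype=np.int64)
    n = obs.size
    if N < n:
        raise ValueError(f"N={N} smaller than the observed TF count {n}")
    if fit.gof_pvalue is not None and fit.gof_pvalue <= 0.1 and not force:
        raise ValueError(
            f"power-law fit not plausible (GOF p = {fit.gof_pvalue}); "
            "pass force=True to override"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    below = obs[obs < fit.kmin]
    p_below = below.size / n
    kmax = genome_genes if genome_genes is not None else fit.kmax
    model = PowerLawModel(alpha=fit.alpha, kmin=fit.kmin, kmax=kmax)
    total = r * N
    from_below = rng.random(total) < p_below
    draws = np.empty(total, dtype=np.int64)
    n_below = int(from_below.sum())
    if n_below:
        draws[from_below] = rng.choice(below, size=n_below, replace=True)
    if total - n_below:
        draws[~from_below] = model.sample(total - n_below, rng)
    sums = draws.reshape(r, N).sum(axis=1)
    est = InteractionEstimate(
        mean_pdis=float(sums.mean()),
        sd_pdis=float(sums.std(ddof=1)),
        n_tfs_used=N,
        r=r,
    )
    if observed_count is not None:
        est.ztest_p = ztest_observed(est, observed_count)
    return est


def ztest_observed(estimate: InteractionEstimate, observed_count: float) -> float:
    """Two-sided normal p-value for observed vs simulated PDI totals."""
    if estimate.sd_pdis == 0.0:
        warnings.warn("zero SD over replicates; Z-test undefined")
        return float("nan")
    z = (observed_count - estimate.mean_pdis) / estimate.sd_pdis
    return float(2.0 * stats.norm.sf(abs(z)))
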