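"""Monte Carlo uncertainty quantification of needle shape under tissue priors.

Tissue elastic moduli are uncertain in patients; each layer of a fixed
anatomy is given a truncated-normal prior (truncated at zero so no sampled
tissue is softer than vacuum). Property vectors drawn from the prior are
expanded into per-millimetre profiles, pushed through a trained surrogate in
one batch, and the resulting ensemble of 48-node needle shapes is summarized
by per-node empirical quantile bands.

Direct sampling is the default — the demonstrated priors are independent
across layers — but any callable with the sampler signature (for example the
provided random-walk Metropolis chain sampler) can be substituted for
non-independent priors without changing downstream code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset import LayeredAnatomy, anatomy_to_profile
from .insertion_sim import MAX_DEPTH
from .surrogate import SurrogateModel

__all__ = [
    "PriorSpec",
    "UQResult",
    "sample_prior",
    "chain_sample_prior",
    "confidence_band",
    "run_uq",
]


@dataclass(frozen=True)
class PriorSpec:
    """Independent truncated-normal priors for the moduli of each layer.

    ``boundaries`` fixes the layer geometry (as in
    :class:`~needleflex.dataset.LayeredAnatomy`); ``mu``/``sigma`` give the
    untruncated normal parameters per layer, MPa. The lower truncation is
    exactly 0 so sampled moduli are always physical.
    """

    boundaries: tuple[int, ...]
    mu: tuple[float, ...]
    sigma: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.mu) != len(self.sigma):
            raise ValueError("mu and sigma must have one entry per layer")
        if len(self.boundaries) != len(self.mu) - 1:
            raise ValueError("need exactly n_layers - 1 boundaries")
        if any(s < 0 for s in self.sigma):
            raise ValueError("prior sigma must be non-negative")

    @property
    def n_layers(self) -> int:
        return len(self.mu)

    def anatomy(self, moduli: np.ndarray) -> LayeredAnatomy:
        return LayeredAnatomy(self.boundaries, tuple(float(m) for m in moduli))


def sample_prior(prior: PriorSpec, n: int, seed: int) -> np.ndarray:
    """Draw n property vectors (n, n_layers) by direct truncated-normal sampling."""
    if n < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    cols = []
    for mu, sigma in zip(prior.mu, prior.sigma):
        if sigma == 0.0:
            cols.append(np.full(n, mu))
        else:
            a = (0.0 - mu) / sigma  # standardized lower bound; upper open
            cols.append(stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=n, random_state=rng))
    return np.column_stack(cols)


def chain_sample_prior(
    prior: PriorSpec,
    n: int,
    seed: int,
    step_scale: float = 0.5,
    burn_in: int = 500,
    thin: int = 5,
) -> np.ndarray:
    """Random-walk Metropolis sampler over the same truncated-normal prior.

    Interchangeable with :func:`sample_prior`; kept as the extension point
    for priors with dependence between layers, where direct sampling is no
    longer available. Proposals are Gaussian with per-layer scale
    ``step_scale * sigma``; ``burn_in`` initial states are discarded and the
    chain is thinned by ``thin``.
    """
    if n < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    mu = np.asarray(prior.mu)
    sigma = np.asarray(prior.sigma)
    free = sigma > 0

    def log_density(x: np.ndarray) -> float:
        if np.any(x[free] < 0):
            return -np.inf
        return float(-0.5 * np.sum(((x[free] - mu[free]) / sigma[free]) ** 2))

    x = mu.astype(float).copy()
    logp = log_density(x)
    out = np.empty((n, len(mu)))
    kept = 0
    it = 0
    max_iter = burn_in + thin * n * 50
    while kept < n:
        it += 1
        if it > max_iter:
            raise RuntimeError("chain sampler failed to collect enough samples")
        prop = x.copy()
        prop[free] = x[free] + rng.normal(scale=step_scale * sigma[free])
        logp_prop = log_density(prop)
        if np.log(rng.uniform()) < logp_prop - logp:
            x, logp = prop, logp_prop
        if it > burn_in and (it - burn_in) % thin == 0:
            out[kept] = x
            kept += 1
    return out


def confidence_band(samples: np.ndarray, level: float = 0.95) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-node empirical (lower, median, upper) quantiles at ``level``.

    ``samples`` is (n_samples, n_nodes); the band spans the central ``level``
    probability mass, so the quantile pair is ((1-level)/2, 1-(1-level)/2).
    """
    samples = np.asarray(samples)
    if samples.ndim != 2 or samples.shape[0] < 2:
        raise ValueError("need a (n_samples >= 2, n_nodes) sample matrix")
    if not 0.0 <= level < 1.0:
        raise ValueError("level must lie in [0, 1)")
    half = (1.0 - level) / 2.0
    lower, median, upper = np.quantile(samples, [half, 0.5, 1.0 - half], axis=0)
    return lower, median, upper


@dataclass(frozen=True)
class UQResult:
    """Monte Carlo needle-shape ensemble and its summary bands."""

    deflection_samples: np.ndarray  # (n_samples, 48), mm
    property_samples: np.ndarray  # (n_samples, n_layers), MPa
    lower: np.ndarray  # per-node band, mm
    median: np.ndarray
    upper: np.ndarray
    level: float
    depth: int
    n_samples: int
    seed: int
    sampler: str

    def band_width(self) -> np.ndarray:
        return self.upper - self.lower

    def tip_band_width(self) -> float:
        """Width of the confidence band at the needle tip, mm."""
        return float(self.upper[-1] - self.lower[-1])

    def recompute_band(self, level: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return confidence_band(self.deflection_samples, level)


def run_uq(
    prior: PriorSpec,
    depth: int,
    model: SurrogateModel,
    n: int = 2000,
    seed: int = 0,
    level: float = 0.95,
    sampler: str = "direct",
) -> UQResult:
    """Propagate a tissue-property prior to a needle-shape confidence band.

    Draws ``n`` property vectors with the chosen sampler ("direct" or
    "chain", or any callable ``(prior, n, seed) -> (n, n_layers)``), builds
    one encoded surrogate input per draw at insertion ``depth``, predicts
    all shapes in one batch, and summarizes with ``level`` quantile bands.
    """
    if not 1 <= depth <= MAX_DEPTH:
        raise ValueError(f"depth must be in [1, {MAX_DEPTH}]")
    if n < 2:
        raise ValueError("need n >= 2 Monte Carlo samples")
    if n < 2.0 / (1.0 - level):
        import warnings

        warnings.warn(
            f"n={n} is small for a {level:.0%} band; tail quantiles will be "
            "dominated by the sample extremes"
        )
    if callable(sampler):
        draw, sampler_name = sampler, getattr(sampler, "__name__", "custom")
    elif sampler == "direct":
        draw, sampler_name = sample_prior, "direct"
    elif sampler == "chain":
        draw, sampler_name = chain_sample_prior, "chain"
    else:
        raise ValueError("sampler must be 'direct', 'chain', or a callable")

    props = draw(prior, n, seed)
    X = np.empty((n, MAX_DEPTH + 1))
    for i in range(n):
        X[i, :MAX_DEPTH] = anatomy_to_profile(prior.anatomy(props[i])).modulus_per_mm
    X[:, -1] = depth
    samples = model.predict(X)
    lower, median, upper = confidence_band(samples, level)
    return UQResult(
        deflection_samples=samples,
        property_samples=props,
        lower=lower,
        median=median,
        upper=upper,
        level=level,
        depth=depth,
        n_samples=n,
        seed=seed,
        sampler=sampler_name,
    )
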