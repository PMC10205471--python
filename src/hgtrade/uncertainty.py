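"""Monte Carlo uncertainty propagation and the NRMSD evaluation statistic.

Four uncertainty components — food intake, food MeHg concentration, the
dose–response chain, and economic valuation — are treated as systematic
multiplicative factors: one factor per component per draw, shared across all
countries (the published component bounds describe global, not
country-independent, error).  Each component's factor is log-normal, fitted
so that its 2.5/97.5 percentiles match the stated relative bounds; the
health-risk computation is repeated ``n_iter`` times (1,000 by default) and
the 2.5th/97.5th percentiles of each output quantity form its interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

from .errors import ConfigurationError, MonteCarloError, NormalizationError, ValidationError

#: default component 95% bounds, in percent relative to the point value
DEFAULT_COMPONENT_BOUNDS: dict[str, tuple[float, float]] = {
    "food_intake": (-47.0, 42.0),
    "food_concentration": (-37.0, 63.0),
    "dose_response": (-59.0, 147.0),
    "valuation": (-70.0, 26.0),
}


def lognormal_from_bounds(
    lower_pct: float, upper_pct: float, ci: float = 0.95
) -> tuple[float, float]:
    """Fit (µ, σ) of a log-normal multiplicative factor whose ``ci`` central
    interval spans ``[1 + lower_pct/100, 1 + upper_pct/100]``.

    Asymmetric published bounds pin down both parameters: the log-midpoint
    gives µ and the log-halfwidth over the normal quantile gives σ.
    """
    a = 1.0 + lower_pct / 100.0
    b = 1.0 + upper_pct / 100.0
    if a <= 0 or b <= 0 or b < a:
        raise ConfigurationError(f"invalid relative bounds [{lower_pct}%, {upper_pct}%]")
    if a == b:
        return math.log(a), 0.0
    z = stats.norm.ppf(0.5 + ci / 2.0)
    mu = 0.5 * (math.log(a) + math.log(b))
    sigma = (math.log(b) - math.log(a)) / (2.0 * z)
    return mu, sigma


@dataclass(frozen=True)
class UncertaintySpec:
    """Component bounds (percent, 95% interval), iteration count, output
    percentiles and seed for the Monte Carlo run."""

    components: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COMPONENT_BOUNDS)
    )
    n_iter: int = 1000
    percentiles: tuple[float, float] = (2.5, 97.5)
    seed: int = 0
    max_failure_rate: float = 0.01

    def validate(self) -> None:
        if self.n_iter < 1:
            raise ConfigurationError("n_iter must be at least 1")
        lo, hi = self.percentiles
        if not (0 < lo < hi < 100):
            raise ConfigurationError("percentiles must satisfy 0 < lower < upper < 100")
        for name, (a, b) in self.components.items():
            lognormal_from_bounds(a, b)  # raises ConfigurationError if bad

    def fitted_parameters(self) -> dict[str, tuple[float, float]]:
        """(µ, σ) per component, recorded for reproducibility."""
        return {k: lognormal_from_bounds(a, b) for k, (a, b) in self.components.items()}


@dataclass
class IntervalResult:
    """Point value with percentile bounds; ``relative_bounds`` are the bound
    offsets in percent of the point (NaN for a zero point)."""

    point: float
    lower: float
    upper: float
    relative_bounds: tuple[float, float]

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValidationError("interval lower bound exceeds upper bound")


def _interval(point: float, draws: np.ndarray, percentiles) -> IntervalResult:
    lo, hi = np.percentile(draws, percentiles)
    if point != 0 and np.isfinite(point):
        rel = (100.0 * (lo - point) / abs(point), 100.0 * (hi - point) / abs(point))
    else:
        rel = (float("nan"), float("nan"))
    return IntervalResult(float(point), float(lo), float(hi), rel)


def run_monte_carlo(
    pipeline_fn: Callable[[dict[str, float]], dict[str, float]],
    spec: UncertaintySpec,
) -> dict[str, IntervalResult]:
    """Propagate component factors through an exposure→impact evaluator.

    ``pipeline_fn`` maps a dict of component factors (all 1.0 for the point
    run) to a dict of scalar output quantities and must be deterministic
    given the factors.  Failed draws are recorded; more than
    ``max_failure_rate`` of them aborts the run with diagnostics.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    params = spec.fitted_parameters()
    point = pipeline_fn({name: 1.0 for name in params})

    draws: dict[str, list[float]] = {k: [] for k in point}
    failures: list[tuple[int, str]] = []
    for i in range(spec.n_iter):
        factors = {
            name: float(np.exp(rng.normal(mu, sigma))) for name, (mu, sigma) in params.items()
        }
        try:
            result = pipeline_fn(factors)
        except Exception as exc:  # noqa: BLE001 — a failed draw is data, not a crash
            failures.append((i, repr(exc)))
            continue
        for k in draws:
            draws[k].append(float(result[k]))

    if len(failures) > spec.max_failure_rate * spec.n_iter:
        examples = "; ".join(msg for _, msg in failures[:3])
        raise MonteCarloError(
            f"{len(failures)}/{spec.n_iter} Monte Carlo draws failed (e.g. {examples})"
        )
    return {
        k: _interval(point[k], np.asarray(v), spec.percentiles) for k, v in draws.items()
    }


def nrmsd(simulated, observed, normalization: str = "range") -> float:
    """Root-mean-square deviation normalised by the observed range (or mean).

    The conventional model-evaluation statistic for comparing simulated
    against observed environmental levels.
    """
    sim = np.asarray(simulated, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if sim.shape != obs.shape or sim.ndim != 1:
        raise ValidationError("simulated and observed must be 1-D arrays of equal length")
    if sim.size < 2:
        raise ValidationError("at least two paired values are required")
    rmsd = float(np.sqrt(np.mean((sim - obs) ** 2)))
    if normalization == "range":
        denom = float(obs.max() - obs.min())
    elif normalization == "mean":
        denom = float(obs.mean())
    else:
        raise ConfigurationError("normalization must be 'range' or 'mean'")
    if denom == 0:
        raise NormalizationError(f"observed {normalization} is zero")
    return rmsd / denom
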