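"""Least-squares fitting of single-neuron connectivity distributions.

Trans-synaptic tracing yields, for each starter neuron, a count *k* of
presynaptic inputs.  Three generative hypotheses are compared against
the empirical frequency distribution of *k*:

* **Poisson** -- random connection with low probability to partners from
  a large pool; single parameter lambda, the mean inputs per neuron.
* **Binomial** -- connection with probability *P* to each of a small set
  of *n* candidate partners (e.g. near neighbours).
* **Power law** -- a scale-free network, ``p(k) = c * k**m`` with a
  negative characteristic exponent *m*; heavy-tailed, so a few hub
  neurons carry very large numbers of inputs.

All three are fitted by least squares to relative frequencies (making
the error sums invariant to sample size), and compared by SSE.  The
power-law support starts at ``k_min_fit >= 1`` since ``k**m`` is
undefined at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "DegreeHistogram",
    "PoissonFit",
    "BinomialFit",
    "PowerLawFit",
    "FitComparison",
    "pmf_poisson",
    "pmf_binomial",
    "pmf_powerlaw",
    "fit_poisson",
    "fit_binomial",
    "fit_powerlaw",
    "compare_fits",
]


@dataclass
class DegreeHistogram:
    """Histogram of per-neuron input counts: k -> number of neurons."""

    counts: dict[int, int]

    def __post_init__(self) -> None:
        clean: dict[int, int] = {}
        for k, c in self.counts.items():
            k = int(k)
            c = int(c)
            if k < 0:
                raise ValueError("connection counts k must be >= 0")
            if c < 0:
                raise ValueError("histogram counts must be >= 0")
            if c:
                clean[k] = clean.get(k, 0) + c
        if not clean:
            raise ValueError("histogram is empty (all counts zero)")
        self.counts = dict(sorted(clean.items()))

    @classmethod
    def from_sequence(cls, degrees: Iterable[int]) -> "DegreeHistogram":
        ks, cs = np.unique(np.asarray(list(degrees), dtype=int), return_counts=True)
        return cls(counts=dict(zip(ks.tolist(), cs.tolist())))

    @property
    def n_neurons(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def k_max(self) -> int:
        return int(max(self.counts))

    @property
    def sample_mean(self) -> float:
        return float(
            sum(k * c for k, c in self.counts.items()) / self.n_neurons
        )

    def frequencies(self, ks: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Relative frequencies over ``ks`` (default: 0..k_max inclusive)."""
        if ks is None:
            ks = np.arange(self.k_max + 1)
        ks = np.asarray(ks, dtype=int)
        f = np.array([self.counts.get(int(k), 0) for k in ks], dtype=float)
        return ks, f / self.n_neurons


@dataclass
class PoissonFit:
    lambda_: float
    sse: float
    method: str = "moment"


@dataclass
class BinomialFit:
    n_param: int
    p_param: float
    sse: float


@dataclass
class PowerLawFit:
    exponent_m: float
    c_norm: float
    k_min_fit: int
    sse: float
    space: str = "log"


@dataclass
class FitComparison:
    poisson: PoissonFit
    binomial: BinomialFit
    powerlaw: PowerLawFit
    best_model: str
    frequencies: dict[int, float] = field(default_factory=dict)

    def report(self) -> str:
        lines = [
            "model       parameters                      SSE",
            f"poisson     lambda={self.poisson.lambda_:.4g} ({self.poisson.method})"
            f"{'':<10}{self.poisson.sse:.3e}",
            f"binomial    n={self.binomial.n_param}, P={self.binomial.p_param:.4g}"
            f"{'':<12}{self.binomial.sse:.3e}",
            f"power law   m={self.powerlaw.exponent_m:.4g}, c={self.powerlaw.c_norm:.4g}"
            f" (k>={self.powerlaw.k_min_fit}, {self.powerlaw.space})"
            f"  {self.powerlaw.sse:.3e}",
            f"best model by SSE: {self.best_model}",
        ]
        return "\n".join(lines)


def pmf_poisson(lambda_: float, k) -> np.ndarray | float:
    """Poisson probability of k connections; lambda is the mean count."""
    if lambda_ <= 0:
        raise ValueError("lambda_ must be > 0")
    return stats.poisson.pmf(k, lambda_)


def pmf_binomial(n: int, P: float, k) -> np.ndarray | float:
    """Binomial(n, P) probability of k connections (0 outside 0..n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= P <= 1.0:
        raise ValueError("P must lie in [0, 1]")
    return stats.binom.pmf(k, n, P)


def pmf_powerlaw(
    c: float, m_exp: float, k, k_min: int = 1, strict: bool = False
) -> np.ndarray | float:
    """Power-law density ``c * k**m_exp`` on k >= k_min (not normalised).

    Values of k below ``k_min`` yield 0 by default, or raise when
    ``strict`` is set.
    """
    if m_exp >= 0:
        raise ValueError("m_exp must be < 0")
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    k_arr = np.asarray(k, dtype=float)
    below = k_arr < k_min
    if strict and np.any(below):
        raise ValueError(f"k below power-law support (k_min={k_min})")
    vals = np.where(below, 0.0, c * np.where(below, k_min, k_arr) ** m_exp)
    if np.isscalar(k):
        return float(vals)
    return vals


def _binom_pmf(ks: np.ndarray, n: int, p: float) -> np.ndarray:
    # gammaln-based pmf: avoids per-call scipy dispatch overhead inside the
    # binomial grid search; handles the p in {0, 1} edges explicitly
    if p <= 0.0:
        return (ks == 0).astype(float)
    if p >= 1.0:
        return (ks == n).astype(float)
    logc = (
        special.gammaln(n + 1)
        - special.gammaln(ks + 1)
        - special.gammaln(n - ks + 1)
    )
    out = np.exp(logc + ks * np.log(p) + (n - ks) * np.log1p(-p))
    out[ks > n] = 0.0
    return out


def _poisson_sse(lam: float, ks: np.ndarray, freqs: np.ndarray) -> float:
    return float(np.sum((stats.poisson.pmf(ks, lam) - freqs) ** 2))


def fit_poisson(hist: DegreeHistogram, method: str = "moment") -> PoissonFit:
    """Fit a Poisson model to the histogram.

    ``moment`` (default) sets lambda to the sample mean -- the Poisson
    distribution with the same mean number of connections as the data.
    ``least_squares`` instead minimises the SSE between the model pmf and
    the empirical relative frequencies over k in [0, k_max].  The SSE at
    the fitted lambda is reported either way.
    """
    if method not in ("moment", "least_squares"):
        raise ValueError("method must be 'moment' or 'least_squares'")
    if hist.sample_mean <= 0:
        raise ValueError("histogram mean is zero; Poisson fit undefined")
    ks, freqs = hist.frequencies()
    if method == "moment":
        lam = hist.sample_mean
    else:
        res = optimize.minimize_scalar(
            _poisson_sse,
            bounds=(1e-9, float(hist.k_max) + 1.0),
            args=(ks, freqs),
            method="bounded",
        )
        lam = float(res.x)
    return PoissonFit(lambda_=lam, sse=_poisson_sse(lam, ks, freqs), method=method)


def fit_binomial(hist: DegreeHistogram, n_grid_max: int = 2000) -> BinomialFit:
    """Least-squares binomial fit via exhaustive grid search over integer n.

    For each candidate pool size n in [max(k_max, 1), n_grid_max] the
    connection probability P is found by bounded 1-D minimisation of the
    SSE; the (n, P) pair with the globally smallest SSE wins, ties going
    to the smaller n.
    """
    k_low = max(hist.k_max, 1)
    if n_grid_max < k_low:
        raise ValueError(f"n_grid_max={n_grid_max} is below k_max={hist.k_max}")
    ks, freqs = hist.frequencies()
    mean = hist.sample_mean

    best: tuple[float, int, float] | None = None
    for n in range(k_low, n_grid_max + 1):

        def sse_at(P: float, n: int = n) -> float:
            return float(np.sum((_binom_pmf(ks, n, P) - freqs) ** 2))

        res = optimize.minimize_scalar(
            sse_at, bounds=(0.0, 1.0), method="bounded",
            options={"xatol": 1e-9},
        )
        p_hat = float(res.x)
        # the moment estimate mean/n is a cheap second candidate; keep
        # whichever of the two scores better
        p_mom = min(max(mean / n, 0.0), 1.0)
        sse, p_use = min((sse_at(p), p) for p in (p_hat, p_mom))
        if best is None or sse < best[0]:
            best = (sse, n, p_use)
    assert best is not None
    sse, n_best, p_best = best
    return BinomialFit(n_param=n_best, p_param=p_best, sse=sse)


def fit_powerlaw(
    hist: DegreeHistogram, k_min_fit: int = 1, space: str = "log"
) -> PowerLawFit:
    """Least-squares power-law fit ``c * k**m`` on k >= k_min_fit.

    ``space='log'`` fits a straight line to (log k, log frequency) over
    bins with nonzero counts -- the classic log-log regression, exact on
    noiseless power-law frequencies.  ``space='linear'`` minimises the
    SSE directly in frequency space.  The reported SSE is always computed
    in linear frequency space over k in [k_min_fit, k_max].
    """
    if space not in ("log", "linear"):
        raise ValueError("space must be 'log' or 'linear'")
    if k_min_fit < 1:
        raise ValueError("k_min_fit must be >= 1")
    ks_all, freqs_all = hist.frequencies()
    sel = ks_all >= k_min_fit
    ks_fit = ks_all[sel]
    freqs_fit = freqs_all[sel]
    nonzero = freqs_fit > 0
    if int(np.count_nonzero(nonzero)) < 2:
        raise ValueError(
            "power-law fit needs at least 2 distinct k >= k_min_fit with nonzero counts"
        )
    logk = np.log(ks_fit[nonzero].astype(float))
    logf = np.log(freqs_fit[nonzero])
    slope, intercept = np.polyfit(logk, logf, 1)
    m_exp = float(slope)
    c = float(np.exp(intercept))
    if space == "linear":

        def sse_at(theta: np.ndarray) -> float:
            cc, mm = theta
            return float(np.sum((cc * ks_fit.astype(float) ** mm - freqs_fit) ** 2))

        res = optimize.minimize(sse_at, x0=np.array([c, m_exp]), method="Nelder-Mead")
        c, m_exp = float(res.x[0]), float(res.x[1])
    if m_exp >= 0:
        raise ValueError(
            f"fitted exponent {m_exp:.3g} is non-negative; data are not power-law decaying"
        )
    sse = float(np.sum((c * ks_fit.astype(float) ** m_exp - freqs_fit) ** 2))
    return PowerLawFit(
        exponent_m=m_exp, c_norm=c, k_min_fit=k_min_fit, sse=sse, space=space
    )


def compare_fits(
    hist: DegreeHistogram,
    poisson_method: str = "moment",
    n_grid_max: int = 2000,
    k_min_fit: int = 1,
    space: str = "log",
) -> FitComparison:
    """Fit all three models to shared empirical frequencies and rank by SSE.

    The Poisson and binomial SSEs run over k in [0, k_max]; the power-law
    SSE runs over its fit support k >= k_min_fit (documented behaviour:
    the zero-connection bin lies outside any power law's support).
    """
    pois = fit_poisson(hist, method=poisson_method)
    binom = fit_binomial(hist, n_grid_max=n_grid_max)
    plaw = fit_powerlaw(hist, k_min_fit=k_min_fit, space=space)
    sses = {
        "poisson": pois.sse,
        "binomial": binom.sse,
        "powerlaw": plaw.sse,
    }
    best = min(sses, key=sses.get)
    ks, freqs = hist.frequencies()
    return FitComparison(
        poisson=pois,
        binomial=binom,
        powerlaw=plaw,
        best_model=best,
        frequencies={int(k): float(f) for k, f in zip(ks, freqs)},
    )
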