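"""Convergence diagnostics and residual goodness-of-fit checks."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri

__all__ = ["convergence_report", "QQEnvelope", "qq_envelope"]


def convergence_report(fit) -> pd.DataFrame:
    """Split potential-scale-reduction (Rhat) and effective sample size
    for every monitored scalar parameter.

    With a single chain, Rhat cannot be computed; a reduced report (ESS
    only) is returned with a warning.
    """
    import arviz as az

    draws = fit.scalar_draws()
    single = next(iter(draws.values())).shape[0] < 2
    if single:
        warnings.warn(
            "only one chain: split-Rhat unavailable, reporting ESS only",
            UserWarning,
            stacklevel=2,
        )
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # arviz warns on constant chains
        for name, arr in draws.items():
            ds = az.convert_to_dataset(np.asarray(arr))
            rhat = float(az.rhat(ds)["x"].values) if not single else float("nan")
            ess_bulk = float(az.ess(ds)["x"].values)
            ess_tail = float(az.ess(ds, method="tail")["x"].values)
            rows.append(
                {"parameter": name, "rhat": rhat,
                 "ess_bulk": ess_bulk, "ess_tail": ess_tail}
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class QQEnvelope:
    """Simultaneous confidence envelope for normal order statistics.

    ``theoretical`` holds the plotting positions (normal quantiles at
    Blom's points); ``lower``/``upper`` bound each order statistic so the
    joint coverage of a standard-normal sample of size ``n`` is at least
    ``level``.  ``inside`` refers to the residual vector the envelope was
    built for.
    """

    n: int
    level: float
    lower: np.ndarray
    upper: np.ndarray
    theoretical: np.ndarray
    observed: np.ndarray
    inside: bool
    halfwidth_multiplier: float

    def contains(self, residuals: np.ndarray) -> bool:
        """True iff every ordered value of ``residuals`` lies inside."""
        x = np.sort(np.asarray(residuals, dtype=float))
        if x.size != self.n:
            raise ValueError(f"expected a sample of size {self.n}, got {x.size}")
        return bool(np.all(x >= self.lower) and np.all(x <= self.upper))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "theoretical": self.theoretical,
                "observed": self.observed,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


def qq_envelope(residuals: np.ndarray, level: float = 0.95,
                mc_draws: int = 2000, seed: int = 0) -> QQEnvelope:
    """Monte-Carlo simultaneous envelope for a normal QQ plot.

    ``mc_draws`` standard-normal samples of size ``n`` are sorted; each
    order statistic gets a band symmetric about its Monte-Carlo mean,
    ``mean_i +/- c * sd_i``, and the common multiplier ``c`` is widened
    until the fraction of simulated samples lying entirely inside the
    band reaches ``level``.  The returned flag is true iff every
    observed ordered residual lies inside the envelope.
    """
    x = np.sort(np.asarray(residuals, dtype=float))
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 residuals")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if mc_draws < 100:
        raise ValueError("mc_draws too small for a stable envelope")

    rng = np.random.default_rng(seed)
    sims = np.sort(rng.standard_normal((mc_draws, n)), axis=1)
    m = sims.mean(axis=0)
    s = sims.std(axis=0)

    def coverage(c: float) -> float:
        return float(np.all(np.abs(sims - m) <= c * s, axis=1).mean())

    # bisect on the multiplier; coverage is nondecreasing in c
    c_lo, c_hi = 0.5, 8.0
    while coverage(c_hi) < level:  # pragma: no cover - c_hi=8 covers in practice
        c_hi *= 2
    for _ in range(40):
        mid = 0.5 * (c_lo + c_hi)
        if coverage(mid) >= level:
            c_hi = mid
        else:
            c_lo = mid
    c = c_hi
    lo, hi = m - c * s, m + c * s

    theoretical = ndtri((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    inside = bool(np.all(x >= lo) and np.all(x <= hi))
    return QQEnvelope(
        n=n, level=level, lower=lo, upper=hi, theoretical=theoretical,
        observed=x, inside=inside, halfwidth_multiplier=float(c),
    )
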