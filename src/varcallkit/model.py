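"""Bayesian hierarchical two-component mixture model of variant function.

Observation model, for measurement ``i`` of variant ``v`` in batch ``b``::

    y_i = x_i' gamma + beta_b + eta_v + eps_i,     eps_i ~ N(0, sigma_e^2)
    beta_b ~ N(0, sigma_b^2)                       (batch random effect)
    eta_v | Z_v = 0 ~ N(mu0, tau0^2)               (neutral component)
    eta_v | Z_v = 1 ~ N(mu1, tau1^2)               (pathogenic component)
    Z_v ~ Bernoulli(pi)  for unlabelled variants; Z_v fixed otherwise

with the identifiability constraint ``mu1 < mu0``: the pathogenic
component sits at lower log-activity.  The posterior probability of
pathogenicity of an unlabelled variant (PrDel) is the posterior mean of
its component indicator ``Z_v``.

Inference is by blocked Gibbs sampling.  Component membership and the
variant effect are updated jointly (``Z_v`` from the marginal likelihood
with ``eta_v`` integrated out analytically, then ``eta_v`` from its
conditional), which avoids the slow mixing of a one-at-a-time scheme.
Location parameters and random effects have conjugate normal updates;
``mu1 < mu0`` is enforced with truncated-normal draws; the four scale
parameters carry half-normal priors and are updated by slice sampling;
``pi`` has a conjugate Beta update.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri

from .assay_io import AssayDataset, Control, parse_variant

__all__ = [
    "Label",
    "Labels",
    "ModelSpec",
    "PosteriorFit",
    "VariantPosterior",
    "ConvergenceWarning",
    "fit",
    "prdel",
    "eta_summary",
    "standardized_residuals",
]


class Label(enum.Enum):
    NEUTRAL = "NEUTRAL"
    PATHOGENIC = "PATHOGENIC"
    UNKNOWN = "UNKNOWN"


class ConvergenceWarning(UserWarning):
    """Raised (as a warning) when chains have not mixed."""


@dataclass(frozen=True)
class Labels:
    """Per-variant classification status used to anchor the mixture.

    Control aliases are forced: any variant measured with the WT control
    flag is NEUTRAL and any variant with the NEG flag is PATHOGENIC.
    """

    mapping: dict[str, Label]

    @classmethod
    def for_dataset(
        cls, dataset: AssayDataset, known: dict[str, Label] | None = None
    ) -> "Labels":
        """Build a label table covering every variant in ``dataset``.

        ``known`` supplies reference-panel labels; all other non-control
        variants are UNKNOWN.  Controls are forced regardless of ``known``.
        """
        known = dict(known or {})
        mapping: dict[str, Label] = {}
        control_of: dict[str, Control] = {}
        for m in dataset.measurements:
            if m.control is not Control.NONE:
                control_of[m.variant] = m.control
        for v in dataset.variants:
            if control_of.get(v) is Control.WT:
                mapping[v] = Label.NEUTRAL
            elif control_of.get(v) is Control.NEG:
                mapping[v] = Label.PATHOGENIC
            else:
                mapping[v] = known.get(v, Label.UNKNOWN)
        return cls(mapping=mapping)

    def require_covering(self, dataset: AssayDataset) -> None:
        missing = [v for v in dataset.variants if v not in self.mapping]
        if missing:
            raise KeyError(f"variants without a label entry: {missing}")

    def __getitem__(self, variant: str) -> Label:
        return self.mapping[variant]


@dataclass(frozen=True)
class ModelSpec:
    """Priors, constraints and MCMC controls.

    The neutral-component mean prior is centred at 0 because activities
    are wild-type-centred by normalization; the pathogenic-component mean
    prior is centred at the observed mean activity of the negative
    control (``mu1_loc=None``) unless overridden.  All scale parameters
    carry half-normal priors.
    """

    mu0_loc: float = 0.0
    mu0_scale: float = 1.0
    mu1_loc: float | None = None  # None -> anchor at mean NEG_CONTROL activity
    mu1_scale: float = 1.0
    tau0_scale: float = 1.0
    tau1_scale: float = 1.0
    sigma_b_scale: float = 1.0
    sigma_e_scale: float = 1.0
    pi_a: float = 1.0
    pi_b: float = 1.0
    gamma_scale: float = 10.0
    chains: int = 4
    iterations: int = 5000
    burn_in: int = 2500
    thinning: int = 1
    seed: int = 0
    rhat_threshold: float = 1.01
    fix_labels: bool = True  # False: treat reference-panel labels as UNKNOWN

    def __post_init__(self) -> None:
        for name in ("mu0_scale", "mu1_scale", "tau0_scale", "tau1_scale",
                     "sigma_b_scale", "sigma_e_scale", "gamma_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.pi_a <= 0 or self.pi_b <= 0:
            raise ValueError("Beta prior parameters must be > 0")
        if not (0 < self.burn_in < self.iterations):
            raise ValueError("need 0 < burn_in < iterations")
        if self.thinning < 1 or self.chains < 1:
            raise ValueError("thinning and chains must be >= 1")

    @property
    def draws_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning


@dataclass
class PosteriorFit:
    """Posterior draws with shape ``(chains, draws, ...)`` per parameter.

    ``z_fixed`` holds the observed component for labelled variants
    (0 neutral, 1 pathogenic) and -1 for unlabelled ones.
    """

    variant_names: tuple[str, ...]
    batch_names: tuple[str, ...]
    eta: np.ndarray      # (C, D, V)
    z: np.ndarray        # (C, D, V), int8; fixed values repeated for labelled
    beta: np.ndarray     # (C, D, B)
    gamma: np.ndarray    # (C, D, P)
    mu0: np.ndarray      # (C, D)
    mu1: np.ndarray
    tau0: np.ndarray
    tau1: np.ndarray
    sigma_b: np.ndarray
    sigma_e: np.ndarray
    pi: np.ndarray
    z_fixed: np.ndarray  # (V,)
    labels: Labels
    spec: ModelSpec
    seed: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.eta.shape[0] * self.eta.shape[1]

    def variant_index(self, variant: str) -> int:
        try:
            return self.variant_names.index(variant)
        except ValueError:
            raise KeyError(f"variant {variant!r} not in fit") from None

    def scalar_draws(self) -> dict[str, np.ndarray]:
        out = {
            "mu0": self.mu0, "mu1": self.mu1, "tau0": self.tau0,
            "tau1": self.tau1, "sigma_b": self.sigma_b,
            "sigma_e": self.sigma_e, "pi": self.pi,
        }
        for j in range(self.gamma.shape[2]):
            out[f"gamma[{j}]"] = self.gamma[:, :, j]
        return out


@dataclass(frozen=True)
class VariantPosterior:
    """Posterior summary of one variant's function effect."""

    variant: str
    prdel: float
    eta_q2_5: float
    eta_q25: float
    eta_q50: float
    eta_q75: float
    eta_q97_5: float
    label: Label


# --------------------------------------------------------------------------
# sampling primitives


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lower: float = -np.inf, upper: float = np.inf) -> float:
    """One draw from N(mean, sd^2) truncated to (lower, upper), by inverse CDF."""
    a = ndtr((lower - mean) / sd) if np.isfinite(lower) else 0.0
    b = ndtr((upper - mean) / sd) if np.isfinite(upper) else 1.0
    if b - a < 1e-14:  # numerically degenerate: pin to the nearer boundary
        return float(np.clip(mean, lower, upper))
    u = rng.uniform(a, b)
    u = min(max(u, 1e-15), 1 - 1e-15)
    return mean + sd * float(ndtri(u))


def _slice_sample_scale(rng: np.random.Generator, current: float,
                        m: float, ss: float, prior_scale: float,
                        width: float = 0.5, max_steps: int = 50) -> float:
    """Slice-sample a scale parameter s > 0.

    Target: product of ``m`` normal likelihood terms with total squared
    deviation ``ss`` and a half-normal(prior_scale) prior on s.
    """
    def logp(s: float) -> float:
        if s <= 0:
            return -np.inf
        return -m * math.log(s) - ss / (2 * s * s) - s * s / (2 * prior_scale ** 2)

    log_y = logp(current) + math.log(rng.uniform(1e-300, 1.0))
    lo = current - width * rng.uniform()
    hi = lo + width
    steps = max_steps
    while lo > 0 and logp(lo) > log_y and steps > 0:
        lo -= width
        steps -= 1
    lo = max(lo, 1e-10)
    steps = max_steps
    while logp(hi) > log_y and steps > 0:
        hi += width
        steps -= 1
    for _ in range(100):
        prop = rng.uniform(lo, hi)
        if logp(prop) > log_y:
            return prop
        if prop < current:
            lo = prop
        else:
            hi = prop
    return current  # pathological slice; keep state


# --------------------------------------------------------------------------
# the Gibbs sampler


def _prepare(dataset: AssayDataset, labels: Labels, spec: ModelSpec,
             X: np.ndarray | None):
    labels.require_covering(dataset)
    y = dataset.y
    variant_names = dataset.variants
    batch_names = dataset.batches
    v_of = {v: i for i, v in enumerate(variant_names)}
    b_of = {b: i for i, b in enumerate(batch_names)}
    var_idx = np.array([v_of[m.variant] for m in dataset.measurements])
    batch_idx = np.array([b_of[m.batch_id] for m in dataset.measurements])

    z_fixed = np.full(len(variant_names), -1, dtype=np.int8)
    control_names = {
        m.variant for m in dataset.measurements if m.control is not Control.NONE
    }
    for v, i in v_of.items():
        lab = labels[v]
        if lab is Label.UNKNOWN:
            continue
        if spec.fix_labels or v in control_names:
            z_fixed[i] = 1 if lab is Label.PATHOGENIC else 0

    if X is None:
        X = np.zeros((len(y), 0))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != len(y):
        raise ValueError("covariate matrix row count must match measurements")

    neg_mask = dataset.control_mask(Control.NEG)
    if spec.mu1_loc is not None:
        m_neg = spec.mu1_loc
    elif neg_mask.any():
        m_neg = float(y[neg_mask].mean())
    else:
        m_neg = -2.0  # no negative control to anchor on; generic impaired level
    return y, var_idx, batch_idx, var_idx.size, z_fixed, X, m_neg


def _run_chain(rng: np.random.Generator, y, var_idx, batch_idx, z_fixed, X,
               m_neg, spec: ModelSpec):
    n = y.size
    V = z_fixed.size
    B = int(batch_idx.max()) + 1
    P = X.shape[1]
    n_v = np.bincount(var_idx, minlength=V).astype(float)
    n_b = np.bincount(batch_idx, minlength=B).astype(float)
    unknown = z_fixed < 0

    # overdispersed initial state
    mu0 = spec.mu0_loc + 0.3 * rng.standard_normal()
    mu1 = m_neg + 0.3 * rng.standard_normal()
    if mu1 >= mu0:
        mu1 = mu0 - 0.5 - abs(mu1 - mu0)
    tau0 = abs(rng.normal(0.3, 0.1)) + 0.05
    tau1 = abs(rng.normal(0.3, 0.1)) + 0.05
    sigma_b = abs(rng.normal(0.3, 0.1)) + 0.05
    sigma_e = abs(rng.normal(0.3, 0.1)) + 0.05
    pi = rng.uniform(0.2, 0.8)
    beta = np.zeros(B)
    gamma = np.zeros(P)
    eta = np.bincount(var_idx, weights=y, minlength=V) / np.maximum(n_v, 1)
    z = np.where(z_fixed >= 0, z_fixed,
                 (np.abs(eta - m_neg) < np.abs(eta - 0)).astype(np.int8))
    z = z.astype(np.int8)

    D = spec.draws_per_chain
    out = {
        "eta": np.empty((D, V)), "z": np.empty((D, V), dtype=np.int8),
        "beta": np.empty((D, B)), "gamma": np.empty((D, P)),
        "mu0": np.empty(D), "mu1": np.empty(D), "tau0": np.empty(D),
        "tau1": np.empty(D), "sigma_b": np.empty(D), "sigma_e": np.empty(D),
        "pi": np.empty(D),
    }

    XtX = X.T @ X if P else None
    d = 0
    for it in range(spec.iterations):
        xg = X @ gamma if P else 0.0
        y_g = y - xg

        # batch random effects
        r = y_g - eta[var_idx]
        s_b = np.bincount(batch_idx, weights=r, minlength=B)
        prec_b = n_b / sigma_e ** 2 + 1.0 / sigma_b ** 2
        beta = s_b / sigma_e ** 2 / prec_b + rng.standard_normal(B) / np.sqrt(prec_b)

        # joint (Z, eta) update
        r = y_g - beta[batch_idx]
        s_v = np.bincount(var_idx, weights=r, minlength=V)
        rbar = s_v / n_v
        se2n = sigma_e ** 2 / n_v
        lm0 = -0.5 * np.log(tau0 ** 2 + se2n) - (rbar - mu0) ** 2 / (2 * (tau0 ** 2 + se2n))
        lm1 = -0.5 * np.log(tau1 ** 2 + se2n) - (rbar - mu1) ** 2 / (2 * (tau1 ** 2 + se2n))
        logit = lm1 - lm0 + math.log(pi) - math.log1p(-pi)
        p1 = 1.0 / (1.0 + np.exp(-np.clip(logit, -700, 700)))
        z_new = (rng.uniform(size=V) < p1).astype(np.int8)
        z = np.where(unknown, z_new, z_fixed).astype(np.int8)

        tau_z = np.where(z == 1, tau1, tau0)
        mu_z = np.where(z == 1, mu1, mu0)
        prec_v = n_v / sigma_e ** 2 + 1.0 / tau_z ** 2
        eta = (s_v / sigma_e ** 2 + mu_z / tau_z ** 2) / prec_v \
            + rng.standard_normal(V) / np.sqrt(prec_v)

        # component means, mu1 < mu0 enforced by truncation
        in0 = z == 0
        m0, m1 = int(in0.sum()), int((~in0).sum())
        prec = m0 / tau0 ** 2 + 1.0 / spec.mu0_scale ** 2
        mean = (eta[in0].sum() / tau0 ** 2 + spec.mu0_loc / spec.mu0_scale ** 2) / prec
        mu0 = _truncnorm(rng, mean, 1.0 / math.sqrt(prec), lower=mu1)
        prec = m1 / tau1 ** 2 + 1.0 / spec.mu1_scale ** 2
        mean = (eta[~in0].sum() / tau1 ** 2 + m_neg / spec.mu1_scale ** 2) / prec
        mu1 = _truncnorm(rng, mean, 1.0 / math.sqrt(prec), upper=mu0)

        # recentering sweep: the likelihood is invariant under
        # (beta - c, eta + c, mu0 + c, mu1 + c); sample c from its full
        # conditional under the priors to break the induced slow mixing
        prec_c = B / sigma_b ** 2 + 1.0 / spec.mu0_scale ** 2 + 1.0 / spec.mu1_scale ** 2
        mean_c = (
            beta.sum() / sigma_b ** 2
            - (mu0 - spec.mu0_loc) / spec.mu0_scale ** 2
            - (mu1 - m_neg) / spec.mu1_scale ** 2
        ) / prec_c
        c = mean_c + rng.standard_normal() / math.sqrt(prec_c)
        beta -= c
        eta += c
        mu0 += c
        mu1 += c
        r = r + c  # keep r = y - x'gamma - beta[batch] consistent post-sweep

        # scale parameters, half-normal priors
        tau0 = _slice_sample_scale(rng, tau0, m0,
                                   float(((eta[in0] - mu0) ** 2).sum()),
                                   spec.tau0_scale)
        tau1 = _slice_sample_scale(rng, tau1, m1,
                                   float(((eta[~in0] - mu1) ** 2).sum()),
                                   spec.tau1_scale)
        sigma_b = _slice_sample_scale(rng, sigma_b, B, float((beta ** 2).sum()),
                                      spec.sigma_b_scale)
        eps = r - eta[var_idx]
        sigma_e = _slice_sample_scale(rng, sigma_e, n, float((eps ** 2).sum()),
                                      spec.sigma_e_scale)

        # mixture weight
        k1 = int(z.sum())
        pi = rng.beta(spec.pi_a + k1, spec.pi_b + V - k1)

        # fixed-effect coefficients
        if P:
            resid = y - beta[batch_idx] - eta[var_idx]
            A = XtX / sigma_e ** 2 + np.eye(P) / spec.gamma_scale ** 2
            b_vec = X.T @ resid / sigma_e ** 2
            L = np.linalg.cholesky(A)
            mean = np.linalg.solve(A, b_vec)
            gamma = mean + np.linalg.solve(L.T, rng.standard_normal(P))

        if it >= spec.burn_in and (it - spec.burn_in) % spec.thinning == 0:
            out["eta"][d] = eta
            out["z"][d] = z
            out["beta"][d] = beta
            out["gamma"][d] = gamma
            out["mu0"][d] = mu0
            out["mu1"][d] = mu1
            out["tau0"][d] = tau0
            out["tau1"][d] = tau1
            out["sigma_b"][d] = sigma_b
            out["sigma_e"][d] = sigma_e
            out["pi"][d] = pi
            d += 1
    return out


def fit(dataset: AssayDataset, labels: Labels, spec: ModelSpec | None = None,
        X: np.ndarray | None = None) -> PosteriorFit:
    """Fit the hierarchical mixture model by blocked Gibbs sampling.

    ``X`` is an optional per-measurement covariate matrix for fixed
    effects (amino-acid/construct context); default none.  A dataset with
    no UNKNOWN variant is valid (pure calibration fit).  Non-convergence
    (split-Rhat above ``spec.rhat_threshold``) raises a
    :class:`ConvergenceWarning` warning, never silent success.
    """
    spec = spec or ModelSpec()
    y, var_idx, batch_idx, n, z_fixed, Xmat, m_neg = _prepare(
        dataset, labels, spec, X
    )
    seqs = np.random.SeedSequence(spec.seed).spawn(spec.chains)
    chains = [
        _run_chain(np.random.default_rng(s), y, var_idx, batch_idx, z_fixed,
                   Xmat, m_neg, spec)
        for s in seqs
    ]
    stacked = {k: np.stack([c[k] for c in chains]) for k in chains[0]}
    result = PosteriorFit(
        variant_names=dataset.variants,
        batch_names=dataset.batches,
        z_fixed=z_fixed,
        labels=labels,
        spec=spec,
        seed=spec.seed,
        **stacked,
    )
    assert bool(np.all(result.mu1 < result.mu0)), "ordering constraint violated"

    from .diagnostics import convergence_report  # local import, no cycle at load

    if spec.chains >= 2:
        report = convergence_report(result)
        result.diagnostics["rhat_max"] = float(np.nanmax(report["rhat"].values))
        result.diagnostics["ess_min"] = float(np.nanmin(report["ess_bulk"].values))
        if result.diagnostics["rhat_max"] > spec.rhat_threshold:
            worst = report.sort_values("rhat", ascending=False).head(3)
            warnings.warn(
                "chains may not have converged: max split-Rhat "
                f"{result.diagnostics['rhat_max']:.4f} > {spec.rhat_threshold} "
                f"(worst: {', '.join(worst['parameter'])})",
                ConvergenceWarning,
                stacklevel=2,
            )
    return result


# --------------------------------------------------------------------------
# posterior summaries


def prdel(fit: PosteriorFit, variant: str) -> float:
    """Posterior probability of pathogenicity: mean of the Z draws.

    Exactly 0.0 or 1.0 for variants whose label was fixed during fitting.
    """
    i = fit.variant_index(variant)
    if fit.z_fixed[i] >= 0:
        return float(fit.z_fixed[i])
    return float(fit.z[:, :, i].mean())


def _sort_key(variant: str):
    try:
        spec = parse_variant(variant)
        return (0, min(spec.positions), variant)
    except Exception:
        return (1, 0, variant)  # controls and unparseable labels go last


def eta_summary(fit: PosteriorFit) -> list[VariantPosterior]:
    """Per-variant posterior quantiles of the function effect eta,
    ordered by protein position (non-variant labels last)."""
    qs = np.quantile(
        fit.eta.reshape(-1, fit.eta.shape[2]),
        [0.025, 0.25, 0.5, 0.75, 0.975],
        axis=0,
    )
    order = sorted(range(len(fit.variant_names)),
                   key=lambda i: _sort_key(fit.variant_names[i]))
    out = []
    for i in order:
        v = fit.variant_names[i]
        out.append(
            VariantPosterior(
                variant=v,
                prdel=prdel(fit, v),
                eta_q2_5=float(qs[0, i]),
                eta_q25=float(qs[1, i]),
                eta_q50=float(qs[2, i]),
                eta_q75=float(qs[3, i]),
                eta_q97_5=float(qs[4, i]),
                label=fit.labels[v],
            )
        )
    return out


def standardized_residuals(fit: PosteriorFit, dataset: AssayDataset,
                           X: np.ndarray | None = None) -> np.ndarray:
    """Standardized residuals averaged over posterior uncertainty.

    For each draw, ``(y - x'gamma - beta_b - eta_v) / sigma_e``; the
    returned vector is the per-measurement mean over all retained draws.
    """
    y = dataset.y
    v_of = {v: i for i, v in enumerate(fit.variant_names)}
    b_of = {b: i for i, b in enumerate(fit.batch_names)}
    var_idx = np.array([v_of[m.variant] for m in dataset.measurements])
    batch_idx = np.array([b_of[m.batch_id] for m in dataset.measurements])
    P = fit.gamma.shape[2]
    if P and X is None:
        raise ValueError("fit used covariates; pass the same X")
    Xmat = np.asarray(X, dtype=float) if P else None

    C, D = fit.eta.shape[0], fit.eta.shape[1]
    acc = np.zeros(y.size)
    chunk = max(1, 200_000 // max(y.size, 1))
    for c in range(C):
        for start in range(0, D, chunk):
            sl = slice(start, min(start + chunk, D))
            fitted = (fit.beta[c, sl][:, batch_idx]
                      + fit.eta[c, sl][:, var_idx])
            if P:
                fitted = fitted + fit.gamma[c, sl] @ Xmat.T
            res = (y[None, :] - fitted) / fit.sigma_e[c, sl][:, None]
            acc += res.sum(axis=0)
    return acc / (C * D)
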