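"""Synthetic reporter-assay datasets with known ground truth.

The generator reproduces the statistical structure the model assumes: a
bimodal population of variant effects (neutral component near wild-type
activity, pathogenic component at strongly reduced activity), additive
batch offsets on the log scale, replicate-level residual noise, and the
assay design in which every batch carries a wild-type and a negative
control and every variant is measured in triplicate in each of two
independent experiments.

Default parameters are declared fixture constants describing a
well-separated assay (component means 0 and -2 with component SDs 0.25,
batch SD 0.2, residual SD 0.3), not estimates of any real dataset.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .assay_io import AssayDataset, Control, Measurement, normalize_activities
from .model import Label, Labels, PosteriorFit

__all__ = ["GeneratorConfig", "SyntheticTruth", "generate", "recovery_report",
           "WT_NAME", "NEG_NAME"]

WT_NAME = "WT"
NEG_NAME = "NEG_CONTROL"

# plausible BRCT-region positions for auto-generated variant labels
_POSITIONS = np.arange(1396, 1864)
_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth parameters and design of the simulated assay."""

    n_variants: int = 60
    frac_pathogenic: float = 0.3
    mu0: float = 0.0
    mu1: float = -2.0
    tau0: float = 0.25
    tau1: float = 0.25
    sigma_b: float = 0.2
    sigma_e: float = 0.3
    n_experiments: int = 2
    batches_per_experiment: int = 2
    replicates: int = 3
    n_labeled: int = 10
    seed: int = 1
    emit_raw: bool = False  # emit firefly/renilla pairs instead of y

    def __post_init__(self) -> None:
        if self.mu1 > self.mu0:
            raise ValueError("mu1 must not exceed mu0 (pathogenic = lower activity)")
        for name in ("tau0", "tau1", "sigma_b", "sigma_e"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.frac_pathogenic <= 1:
            raise ValueError("frac_pathogenic must lie in [0, 1]")
        if self.replicates < 1 or self.n_experiments < 1 or self.batches_per_experiment < 1:
            raise ValueError("design counts must be >= 1")
        if not 0 <= self.n_labeled <= self.n_variants:
            raise ValueError("n_labeled must lie in [0, n_variants]")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth paired with a generated dataset."""

    z: dict[str, int]          # variant -> component (0 neutral, 1 pathogenic)
    eta: dict[str, float]      # variant -> true effect (controls included)
    beta: dict[str, float]     # batch -> true offset
    config: GeneratorConfig

    def to_json(self) -> str:
        return json.dumps(
            {"z": self.z, "eta": self.eta, "beta": self.beta,
             "config": asdict(self.config)},
            indent=2,
        )


class GeneratorConfigError(ValueError):
    pass


def _variant_names(rng: np.random.Generator, n: int) -> list[str]:
    names: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        pos = int(rng.choice(_POSITIONS))
        ref, alt = rng.choice(list(_AA), size=2, replace=False)
        label = f"{ref}{pos}{alt}"
        if label not in names:
            names.add(label)
            out.append(label)
    return out


def generate(config: GeneratorConfig | None = None
             ) -> tuple[AssayDataset, SyntheticTruth, Labels]:
    """Simulate an assay dataset, its ground truth, and a label table.

    Every batch carries WT (eta = 0 by the normalization convention) and
    a negative control whose eta is a single shared draw from the
    pathogenic component (one biological allele, shared across batches).
    ``n_labeled`` variants are marked with their true label (half
    pathogenic, half neutral where the realized components allow);
    everything else is UNKNOWN.  Output is reproducible: the same seed
    yields the identical dataset.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)

    names = _variant_names(rng, config.n_variants)
    z = (rng.uniform(size=config.n_variants) < config.frac_pathogenic).astype(int)
    eta = np.where(
        z == 1,
        rng.normal(config.mu1, config.tau1, size=config.n_variants),
        rng.normal(config.mu0, config.tau0, size=config.n_variants),
    )
    eta_neg = float(rng.normal(config.mu1, config.tau1))

    # reference-panel labels: half pathogenic, half neutral where possible
    want_path = config.n_labeled // 2
    want_neut = config.n_labeled - want_path
    path_pool = [i for i in range(config.n_variants) if z[i] == 1]
    neut_pool = [i for i in range(config.n_variants) if z[i] == 0]
    if want_path > len(path_pool) and want_neut > len(neut_pool):
        raise GeneratorConfigError("not enough variants to label")
    if want_path > len(path_pool):
        if config.frac_pathogenic == 0 and want_path > 0:
            raise GeneratorConfigError(
                "pathogenic labels requested but frac_pathogenic is 0"
            )
        want_neut += want_path - len(path_pool)
        want_path = len(path_pool)
    if want_neut > len(neut_pool):
        want_path += want_neut - len(neut_pool)
        want_neut = len(neut_pool)
        if want_path > len(path_pool):
            raise GeneratorConfigError("not enough variants to label")
    labeled_idx = (
        list(rng.choice(path_pool, size=want_path, replace=False))
        + list(rng.choice(neut_pool, size=want_neut, replace=False))
    )

    batch_names = [
        f"e{e + 1}b{b + 1}"
        for e in range(config.n_experiments)
        for b in range(config.batches_per_experiment)
    ]
    beta = rng.normal(0.0, config.sigma_b, size=len(batch_names))

    all_names = names + [WT_NAME, NEG_NAME]
    all_eta = np.concatenate([eta, [0.0, eta_neg]])
    controls = {WT_NAME: Control.WT, NEG_NAME: Control.NEG}

    measurements: list[Measurement] = []
    for bi, batch in enumerate(batch_names):
        experiment = batch.split("b")[0]
        for vi, name in enumerate(all_names):
            noise = rng.normal(0.0, config.sigma_e, size=config.replicates)
            for r in range(config.replicates):
                yval = beta[bi] + all_eta[vi] + noise[r]
                if config.emit_raw:
                    renilla = 1e5
                    measurements.append(
                        Measurement(
                            variant=name, batch_id=batch,
                            experiment_id=experiment, replicate=r + 1,
                            control=controls.get(name, Control.NONE),
                            firefly=renilla * float(np.exp(yval)),
                            renilla=renilla,
                        )
                    )
                else:
                    measurements.append(
                        Measurement(
                            variant=name, batch_id=batch,
                            experiment_id=experiment, replicate=r + 1,
                            control=controls.get(name, Control.NONE),
                            normalized_activity=float(yval),
                        )
                    )
    dataset = AssayDataset(measurements=tuple(measurements))

    truth = SyntheticTruth(
        z={**{names[i]: int(z[i]) for i in range(config.n_variants)},
           WT_NAME: 0, NEG_NAME: 1},
        eta={**{names[i]: float(eta[i]) for i in range(config.n_variants)},
             WT_NAME: 0.0, NEG_NAME: eta_neg},
        beta=dict(zip(batch_names, map(float, beta))),
        config=config,
    )
    known = {
        names[i]: (Label.PATHOGENIC if z[i] == 1 else Label.NEUTRAL)
        for i in labeled_idx
    }
    labels = Labels.for_dataset(dataset, known)
    return dataset, truth, labels


_RECOVERY_PARAMS = ("mu0", "mu1", "tau0", "tau1", "sigma_b", "sigma_e", "pi")


def recovery_report(fit: PosteriorFit, truth: SyntheticTruth,
                    threshold: float = 0.5) -> dict:
    """Compare a posterior fit against the generating truth.

    Reports the misclassification rate of unlabelled variants at the
    given PrDel threshold and, for each model parameter, the posterior
    median error and whether the central 95% credible interval covers
    the generating value.
    """
    from .model import prdel as _prdel

    fit_variants = set(fit.variant_names)
    truth_variants = set(truth.z)
    if fit_variants != truth_variants:
        raise ValueError(
            "fit and truth variant sets differ: "
            f"{sorted(fit_variants ^ truth_variants)[:5]} ..."
        )

    unknown = [v for i, v in enumerate(fit.variant_names) if fit.z_fixed[i] < 0]
    wrong = sum(
        1 for v in unknown
        if (1 if _prdel(fit, v) > threshold else 0) != truth.z[v]
    )
    cfg = truth.config
    true_pi = cfg.frac_pathogenic
    truths = {
        "mu0": cfg.mu0, "mu1": cfg.mu1, "tau0": cfg.tau0, "tau1": cfg.tau1,
        "sigma_b": cfg.sigma_b, "sigma_e": cfg.sigma_e, "pi": true_pi,
    }
    params = {}
    for name in _RECOVERY_PARAMS:
        draws = getattr(fit, name).ravel()
        lo, med, hi = np.quantile(draws, [0.025, 0.5, 0.975])
        params[name] = {
            "truth": truths[name],
            "posterior_median": float(med),
            "error": float(med - truths[name]),
            "ci95": [float(lo), float(hi)],
            "covered": bool(lo <= truths[name] <= hi),
        }
    return {
        "n_unlabeled": len(unknown),
        "n_misclassified": wrong,
        "misclassification_rate": wrong / len(unknown) if unknown else 0.0,
        "threshold": threshold,
        "parameters": params,
    }
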