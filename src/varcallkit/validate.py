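"""Validation of the classifier: leave-one-out cross-validation, exact
binomial confidence bounds on classification metrics, and concordance
with in-silico predictors.

The leave-one-out exercise refits the full model once per reference-panel
variant with only that variant's label masked to UNKNOWN, asking whether
the assay data alone recovers the known classification.  Metric
uncertainty uses the exact (Clopper-Pearson) binomial interval obtained
by inverting the binomial CDF; for x = n successes its two-sided 95%
lower bound is (0.025)^(1/n).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import model as _model
from .assay_io import AssayDataset
from .model import Label, Labels, ModelSpec, PosteriorFit

__all__ = [
    "ReferencePanel",
    "ProportionEstimate",
    "MetricReport",
    "PredictorCalls",
    "clopper_pearson",
    "loo_cv",
    "binary_call",
    "confusion_metrics",
    "binarize_predictor",
    "concordance",
]


@dataclass(frozen=True)
class ReferencePanel:
    """Known pathogenic/neutral variants anchoring and validating the model."""

    entries: tuple[tuple[str, Label], ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for v, truth in self.entries:
            if v in seen:
                raise ValueError(f"variant {v!r} appears twice in the panel")
            seen.add(v)
            if truth not in (Label.PATHOGENIC, Label.NEUTRAL):
                raise ValueError(f"panel label for {v!r} must be PATHOGENIC or NEUTRAL")

    @property
    def variants(self) -> tuple[str, ...]:
        return tuple(v for v, _ in self.entries)

    def truth(self, variant: str) -> Label:
        for v, t in self.entries:
            if v == variant:
                return t
        raise KeyError(variant)

    def as_labels(self) -> dict[str, Label]:
        return dict(self.entries)


def _derive_seed(master_seed: int, *parts: str) -> int:
    """Stable sub-seed from the master seed and string context (< 2^31)."""
    h = hashlib.sha256(("|".join([str(master_seed), *parts])).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


# --------------------------------------------------------------------------
# exact binomial intervals and metric reports


def clopper_pearson(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial interval for ``x`` successes in ``n`` trials.

    Endpoints are the standard beta-quantile form of the inverted
    binomial CDF: lower = Beta(alpha/2; x, n-x+1), upper =
    Beta(1-alpha/2; x+1, n-x), with the conventions lower=0 at x=0 and
    upper=1 at x=n.
    """
    if not 0 <= x <= n or n < 1:
        raise ValueError(f"need 0 <= x <= n, n >= 1; got x={x}, n={n}")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lower, upper


@dataclass(frozen=True)
class ProportionEstimate:
    point: float | None
    lower: float | None
    upper: float | None
    x: int
    n: int

    @property
    def defined(self) -> bool:
        return self.point is not None


def _proportion(x: int, n: int, level: float) -> ProportionEstimate:
    if n == 0:
        return ProportionEstimate(None, None, None, x, n)
    lo, hi = clopper_pearson(x, n, level)
    return ProportionEstimate(x / n, lo, hi, x, n)


@dataclass(frozen=True)
class MetricReport:
    """Confusion counts and the five standard proportions with exact CIs.

    Metrics whose denominator is empty (e.g., sensitivity with no
    pathogenic truths) are reported as undefined, never as zero.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: ProportionEstimate
    specificity: ProportionEstimate
    ppv: ProportionEstimate
    npv: ProportionEstimate
    accuracy: ProportionEstimate
    level: float = 0.95

    def to_json(self) -> str:
        def enc(p: ProportionEstimate):
            return {"point": p.point, "lower": p.lower, "upper": p.upper,
                    "x": p.x, "n": p.n}

        return json.dumps(
            {
                "counts": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
                "level": self.level,
                "sensitivity": enc(self.sensitivity),
                "specificity": enc(self.specificity),
                "ppv": enc(self.ppv),
                "npv": enc(self.npv),
                "accuracy": enc(self.accuracy),
            },
            indent=2,
        )


def binary_call(prdel: float, threshold: float = 0.5) -> Label:
    """Dichotomize PrDel: PATHOGENIC iff strictly above the threshold."""
    if not 0 <= prdel <= 1:
        raise ValueError(f"PrDel must lie in [0, 1], got {prdel}")
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    return Label.PATHOGENIC if prdel > threshold else Label.NEUTRAL


def confusion_metrics(
    calls: list[tuple[str, Label]],
    panel: ReferencePanel,
    level: float = 0.95,
) -> MetricReport:
    """Sensitivity, specificity, PPV, NPV and accuracy with exact intervals."""
    call_of = dict(calls)
    missing = [v for v in panel.variants if v not in call_of]
    if missing:
        raise KeyError(f"calls missing for panel variants: {missing}")
    tp = fp = tn = fn = 0
    for v, truth in panel.entries:
        called_path = call_of[v] is Label.PATHOGENIC
        if truth is Label.PATHOGENIC:
            tp += called_path
            fn += not called_path
        else:
            fp += called_path
            tn += not called_path
    return MetricReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=_proportion(tp, tp + fn, level),
        specificity=_proportion(tn, tn + fp, level),
        ppv=_proportion(tp, tp + fp, level),
        npv=_proportion(tn, tn + fn, level),
        accuracy=_proportion(tp + tn, tp + fp + tn + fn, level),
        level=level,
    )


# --------------------------------------------------------------------------
# leave-one-out cross-validation


def loo_cv(
    dataset: AssayDataset,
    panel: ReferencePanel,
    spec: ModelSpec | None = None,
    X: np.ndarray | None = None,
    full_fit: PosteriorFit | None = None,
) -> pd.DataFrame:
    """Leave-one-out cross-validation over the reference panel.

    For each panel variant the model is refit from scratch with that
    variant's label masked to UNKNOWN (all other panel labels stay
    fixed); the masked-fit PrDel and posterior-median eta are returned
    alongside the full-fit eta.  Per-refit seeds are derived
    deterministically from the master seed and the variant label, so any
    single refit is independently reproducible.
    """
    spec = spec or ModelSpec()
    present = set(dataset.variants)
    absent = [v for v in panel.variants if v not in present]
    if absent:
        raise KeyError(f"panel variants absent from dataset: {absent}")

    panel_labels = panel.as_labels()
    if full_fit is None:
        full_fit = _model.fit(
            dataset, Labels.for_dataset(dataset, panel_labels), spec, X=X
        )

    rows = []
    for v in panel.variants:
        masked = dict(panel_labels)
        del masked[v]
        loo_spec = ModelSpec(
            **{**spec.__dict__, "seed": _derive_seed(spec.seed, "loo", v)}
        )
        f = _model.fit(dataset, Labels.for_dataset(dataset, masked), loo_spec, X=X)
        i = f.variant_index(v)
        j = full_fit.variant_index(v)
        rows.append(
            {
                "variant": v,
                "truth": panel.truth(v).value,
                "prdel_loo": _model.prdel(f, v),
                "eta_loo": float(np.median(f.eta[:, :, i])),
                "eta_full": float(np.median(full_fit.eta[:, :, j])),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# external predictor concordance


DAMAGING, BENIGN, MISSING = "DAMAGING", "BENIGN", "MISSING"

#: Categorical code maps for the supported tools.  PolyPhen-2's
#: "possibly damaging" (P) is pooled with damaging, matching the pooling
#: of damaging/deleterious/disease-causing terms across tools.
DEFAULT_PREDICTOR_SCHEMES: dict[str, dict] = {
    "SIFT": {"codes": {"D": DAMAGING, "T": BENIGN}},
    "PolyPhen2": {"codes": {"D": DAMAGING, "P": DAMAGING, "B": BENIGN}},
    "PolyPhen2_HDIV": {"codes": {"D": DAMAGING, "P": DAMAGING, "B": BENIGN}},
    "PolyPhen2_HVAR": {"codes": {"D": DAMAGING, "P": DAMAGING, "B": BENIGN}},
    "MutationTaster2": {"codes": {"A": DAMAGING, "D": DAMAGING,
                                  "N": BENIGN, "P": BENIGN}},
    "CADD": {"cutoff": 20.0},
}


@dataclass(frozen=True)
class PredictorCalls:
    """Binarized calls of one in-silico prediction tool."""

    tool: str
    raw: dict[str, object]
    calls: dict[str, str]  # variant -> DAMAGING | BENIGN | MISSING


def binarize_predictor(
    raw: dict[str, object],
    tool: str,
    scheme: dict[str, dict] | None = None,
) -> PredictorCalls:
    """Binarize a tool's per-variant codes or scores to DAMAGING/BENIGN.

    Categorical tools map single-letter codes; CADD-style tools compare
    a phred-scaled score against a cutoff (default 20).  Missing values
    (None or NaN) become MISSING; unmapped codes are an error.
    """
    scheme = scheme or DEFAULT_PREDICTOR_SCHEMES
    if tool not in scheme:
        raise KeyError(f"no binarization mapping for tool {tool!r}")
    cfg = scheme[tool]
    calls: dict[str, str] = {}
    for variant, value in raw.items():
        if value is None or (isinstance(value, float) and np.isnan(value)):
            calls[variant] = MISSING
        elif "codes" in cfg:
            code = str(value)
            if code not in cfg["codes"]:
                raise ValueError(
                    f"tool {tool!r}: unmapped code {code!r} for {variant!r}"
                )
            calls[variant] = cfg["codes"][code]
        else:
            calls[variant] = DAMAGING if float(value) >= cfg["cutoff"] else BENIGN
    return PredictorCalls(tool=tool, raw=dict(raw), calls=calls)


FCLASS_GROUPS = {"fClass1-2": (1, 2), "fClass3": (3,), "fClass4-5": (4, 5)}


def concordance(
    fclass_calls: list[tuple[str, int]],
    predictors: list[PredictorCalls],
) -> pd.DataFrame:
    """Concordance of fClass groups {1-2, 3, 4-5} with each predictor.

    Rows: (tool, fClass group); columns: fraction DAMAGING, fraction
    BENIGN (among predicted variants), count MISSING, and n.
    """
    if not predictors:
        raise ValueError("need at least one predictor")
    rows = []
    any_overlap = False
    for pred in predictors:
        for group, members in FCLASS_GROUPS.items():
            variants = [v for v, fc in fclass_calls if fc in members]
            called = [pred.calls.get(v, MISSING) for v in variants]
            overlap = [c for c in called if c != MISSING]
            any_overlap = any_overlap or bool(overlap)
            n_pred = len(overlap)
            rows.append(
                {
                    "tool": pred.tool,
                    "group": group,
                    "n": len(variants),
                    "n_missing": len(called) - n_pred,
                    "frac_damaging": (
                        sum(c == DAMAGING for c in overlap) / n_pred if n_pred else np.nan
                    ),
                    "frac_benign": (
                        sum(c == BENIGN for c in overlap) / n_pred if n_pred else np.nan
                    ),
                }
            )
    if not any_overlap:
        raise ValueError("no overlap between fClass calls and predictor calls")
    return pd.DataFrame(rows)
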