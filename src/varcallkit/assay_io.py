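"""Parsing, validation and normalization of dual-luciferase reporter assay data.

The raw observable is a pair of luminescence readings per well: firefly
luciferase (driven by the protein construct under test) and Renilla
luciferase (a constitutively expressed transfection control).  The
quantity carried forward to modelling is the natural-log activity of the
firefly/Renilla ratio relative to the wild-type construct measured in the
same batch:

    y = ln[ (firefly / renilla) / GM_WT(batch) ]

where ``GM_WT(batch)`` is the geometric mean of the wild-type
firefly/Renilla ratios of that batch.  Centering on the within-batch
wild type removes the batch-level multiplicative scale, so wild-type
measurements have mean log-activity zero in every batch by construction.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "Control",
    "VariantSpec",
    "Measurement",
    "AssayDataset",
    "ValidationReport",
    "parse_variant",
    "read_assay_table",
    "normalize_activities",
    "validate_dataset",
]

#: One-letter codes of the 20 standard amino acids.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


class Control(enum.Enum):
    """Role of a measurement within a batch."""

    NONE = "none"
    WT = "WT"
    NEG = "NEG"


class VariantParseError(ValueError):
    """A variant label could not be parsed."""


class AssayLoadError(ValueError):
    """A tabular assay file failed validation on load."""


class NormalizationError(ValueError):
    """A batch could not be normalized (e.g., no wild-type control)."""


@dataclass(frozen=True)
class VariantSpec:
    """A missense variant, possibly compound (multiple substitutions in cis).

    Compound labels such as ``"C1787S/G1788D"`` denote substitutions carried
    on one construct; they are classified as a single unit with a single
    latent function effect.
    """

    label: str
    substitutions: tuple[tuple[str, int, str], ...]
    construct: str | None = None

    def __post_init__(self) -> None:
        if not self.substitutions:
            raise VariantParseError(f"{self.label!r}: no substitutions")
        for ref, pos, alt in self.substitutions:
            if pos < 1:
                raise VariantParseError(
                    f"{self.label!r}: position must be >= 1, got {pos}"
                )
            if ref == alt:
                raise VariantParseError(
                    f"{self.label!r}: ref and alt amino acid are identical ({ref})"
                )

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(pos for _, pos, _ in self.substitutions)

    @property
    def is_compound(self) -> bool:
        return len(self.substitutions) > 1


def parse_variant(label: str, construct: str | None = None) -> VariantSpec:
    """Parse a variant label like ``"M1775R"`` or ``"C1787S/G1788D"``.

    Raises :class:`VariantParseError` naming the offending token on
    malformed input.
    """
    if not label or not label.strip():
        raise VariantParseError("empty variant label")
    subs: list[tuple[str, int, str]] = []
    for token in label.strip().split("/"):
        token = token.strip()
        if len(token) < 3:
            raise VariantParseError(f"malformed variant token {token!r}")
        ref, alt = token[0], token[-1]
        if ref not in AMINO_ACIDS:
            raise VariantParseError(
                f"malformed variant token {token!r}: unknown amino acid {ref!r}"
            )
        if alt not in AMINO_ACIDS:
            raise VariantParseError(
                f"malformed variant token {token!r}: unknown amino acid {alt!r}"
            )
        try:
            pos = int(token[1:-1])
        except ValueError:
            raise VariantParseError(
                f"malformed variant token {token!r}: missing or non-numeric position"
            ) from None
        if pos < 1:
            raise VariantParseError(
                f"malformed variant token {token!r}: position must be >= 1"
            )
        subs.append((ref, pos, alt))
    return VariantSpec(label=label.strip(), substitutions=tuple(subs), construct=construct)


@dataclass(frozen=True)
class Measurement:
    """One well of the reporter assay.

    Exactly one of ``(firefly, renilla)`` or ``normalized_activity`` is
    populated.  ``batch_id`` identifies the unit sharing controls (one
    transfection/plate); ``experiment_id`` identifies the independent
    repetition it belongs to.
    """

    variant: str
    batch_id: str
    experiment_id: str
    replicate: int
    control: Control = Control.NONE
    firefly: float | None = None
    renilla: float | None = None
    normalized_activity: float | None = None
    construct: str | None = None
    row: int | None = None  # source row for error reporting

    def __post_init__(self) -> None:
        has_raw = self.firefly is not None or self.renilla is not None
        has_norm = self.normalized_activity is not None
        if has_raw == has_norm:
            raise AssayLoadError(
                f"measurement for {self.variant!r}: exactly one of the raw "
                "firefly/renilla pair or normalized_activity must be given"
            )
        if has_raw:
            if self.firefly is None or self.renilla is None:
                raise AssayLoadError(
                    f"measurement for {self.variant!r}: firefly and renilla "
                    "must be given together"
                )
            if self.firefly < 0:
                raise AssayLoadError(
                    f"measurement for {self.variant!r}: negative firefly reading"
                )
            if self.renilla <= 0:
                raise AssayLoadError(
                    f"measurement for {self.variant!r}: renilla must be > 0"
                )
        if self.replicate < 1:
            raise AssayLoadError(
                f"measurement for {self.variant!r}: replicate must be >= 1"
            )

    @property
    def is_normalized(self) -> bool:
        return self.normalized_activity is not None

    @property
    def ratio(self) -> float:
        if self.firefly is None or self.renilla is None:
            raise AssayLoadError(f"{self.variant!r}: no raw pair present")
        return self.firefly / self.renilla


@dataclass(frozen=True)
class AssayDataset:
    """Normalized log-activity measurements, indexed by variant x batch x replicate."""

    measurements: tuple[Measurement, ...]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, int]] = set()
        for m in self.measurements:
            key = (m.variant, m.batch_id, m.replicate)
            if key in seen:
                raise AssayLoadError(
                    f"duplicated (variant, batch, replicate) key {key}"
                )
            seen.add(key)

    @property
    def variants(self) -> tuple[str, ...]:
        out: dict[str, None] = {}
        for m in self.measurements:
            out.setdefault(m.variant, None)
        return tuple(out)

    @property
    def batches(self) -> tuple[str, ...]:
        out: dict[str, None] = {}
        for m in self.measurements:
            out.setdefault(m.batch_id, None)
        return tuple(out)

    @property
    def y(self) -> np.ndarray:
        """Normalized log-activity vector, one entry per measurement."""
        vals = [m.normalized_activity for m in self.measurements]
        if any(v is None for v in vals):
            raise NormalizationError("dataset contains un-normalized measurements")
        return np.asarray(vals, dtype=float)

    def control_mask(self, control: Control) -> np.ndarray:
        return np.asarray([m.control is control for m in self.measurements])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.measurements:
            rows.append(
                {
                    "variant": m.variant,
                    "batch_id": m.batch_id,
                    "experiment_id": m.experiment_id,
                    "replicate": m.replicate,
                    "control": m.control.value,
                    "y": m.normalized_activity,
                    "construct": m.construct,
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


_REQUIRED_COLUMNS = {"variant", "batch_id", "experiment_id", "replicate"}


def read_assay_table(path, dialect: str = "tsv") -> list[Measurement]:
    """Read a TSV/CSV of assay measurements into :class:`Measurement` rows.

    The table must carry either a ``firefly``/``renilla`` column pair or a
    ``normalized_activity`` column.  An optional ``control`` column holds
    ``none``/``WT``/``NEG``; an optional ``construct`` column names the
    expression context.  Row numbers (1-based, excluding the header) are
    kept for error reporting.
    """
    if dialect not in ("tsv", "csv"):
        raise AssayLoadError(f"unknown dialect {dialect!r}")
    sep = "\t" if dialect == "tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except FileNotFoundError:
        raise
    missing = _REQUIRED_COLUMNS - set(df.columns)
    if missing:
        raise AssayLoadError(f"missing required column(s): {sorted(missing)}")
    if "y" in df.columns and "normalized_activity" not in df.columns:
        df = df.rename(columns={"y": "normalized_activity"})
    has_raw = "firefly" in df.columns and "renilla" in df.columns
    has_norm = "normalized_activity" in df.columns
    if not has_raw and not has_norm:
        raise AssayLoadError(
            "table must provide firefly/renilla columns or a normalized_activity column"
        )

    def _num(row_no: int, name: str, value) -> float | None:
        if value is None or (isinstance(value, float) and math.isnan(value)) or (
            isinstance(value, str) and not value.strip()
        ):
            return None
        try:
            return float(value)
        except (TypeError, ValueError):
            raise AssayLoadError(
                f"row {row_no}: non-numeric value {value!r} in column {name!r}"
            ) from None

    measurements: list[Measurement] = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        control = Control(str(rec.get("control", "none") or "none"))
        firefly = _num(i, "firefly", rec.get("firefly")) if has_raw else None
        renilla = _num(i, "renilla", rec.get("renilla")) if has_raw else None
        norm = _num(i, "normalized_activity", rec.get("normalized_activity")) if has_norm else None
        if firefly is not None and norm is not None:
            raise AssayLoadError(
                f"row {i}: both a raw pair and normalized_activity are populated"
            )
        try:
            replicate = int(rec["replicate"])
        except (TypeError, ValueError):
            raise AssayLoadError(
                f"row {i}: non-numeric replicate {rec['replicate']!r}"
            ) from None
        try:
            measurements.append(
                Measurement(
                    variant=str(rec["variant"]),
                    batch_id=str(rec["batch_id"]),
                    experiment_id=str(rec["experiment_id"]),
                    replicate=replicate,
                    control=control,
                    firefly=firefly,
                    renilla=renilla,
                    normalized_activity=norm,
                    construct=rec.get("construct") if isinstance(rec.get("construct"), str) else None,
                    row=i,
                )
            )
        except AssayLoadError as exc:
            raise AssayLoadError(f"row {i}: {exc}") from None
    return measurements


def normalize_activities(
    measurements: list[Measurement] | tuple[Measurement, ...],
    wt_center: str = "geometric",
) -> AssayDataset:
    """Convert raw firefly/Renilla pairs to wild-type-relative log activity.

    For each batch the wild-type firefly/Renilla ratios define a centering
    constant (their geometric mean by default, arithmetic mean as an
    alternative); every measurement's ratio is divided by it and
    log-transformed.  Measurements that already carry
    ``normalized_activity`` pass through unchanged, which makes the
    operation idempotent.
    """
    if wt_center not in ("geometric", "arithmetic"):
        raise NormalizationError(f"unknown wt_center {wt_center!r}")
    raw = [m for m in measurements if not m.is_normalized]
    centers: dict[str, float] = {}
    for batch_id in {m.batch_id for m in raw}:
        wt_ratios = [
            m.ratio
            for m in raw
            if m.batch_id == batch_id and m.control is Control.WT
        ]
        if not wt_ratios:
            raise NormalizationError(
                f"batch {batch_id!r} has raw measurements but no WT control"
            )
        if any(r <= 0 for r in wt_ratios):
            raise NormalizationError(
                f"batch {batch_id!r}: non-positive WT firefly/renilla ratio"
            )
        if wt_center == "geometric":
            centers[batch_id] = math.exp(
                sum(math.log(r) for r in wt_ratios) / len(wt_ratios)
            )
        else:
            centers[batch_id] = sum(wt_ratios) / len(wt_ratios)

    out: list[Measurement] = []
    for m in measurements:
        if m.is_normalized:
            out.append(m)
            continue
        if m.ratio <= 0:
            raise NormalizationError(
                f"{m.variant!r} in batch {m.batch_id!r}: non-positive "
                "firefly/renilla ratio cannot be log-transformed"
            )
        y = math.log(m.ratio / centers[m.batch_id])
        out.append(
            replace(m, firefly=None, renilla=None, normalized_activity=y)
        )
    return AssayDataset(measurements=tuple(out))


@dataclass
class ValidationReport:
    """Report-only summary of replication and control coverage."""

    n_measurements: int
    n_variants: int
    n_batches: int
    under_replicated: dict[str, dict] = field(default_factory=dict)
    batches_missing_wt: list[str] = field(default_factory=list)
    batches_missing_neg: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.under_replicated or self.batches_missing_wt or self.batches_missing_neg
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_measurements": self.n_measurements,
                "n_variants": self.n_variants,
                "n_batches": self.n_batches,
                "under_replicated": self.under_replicated,
                "batches_missing_wt": self.batches_missing_wt,
                "batches_missing_neg": self.batches_missing_neg,
                "ok": self.ok,
            },
            indent=2,
        )


def validate_dataset(
    dataset: AssayDataset,
    min_replicates: int = 3,
    min_experiments: int = 2,
) -> ValidationReport:
    """Check the replication design: each variant tested in at least
    ``min_replicates`` replicates in each of at least ``min_experiments``
    independent experiments, and every batch carrying both controls.

    The dataset is never mutated; offenders are listed, not removed.
    """
    per_variant: dict[str, dict[str, int]] = {}
    for m in dataset.measurements:
        if m.control is not Control.NONE:
            continue
        per_variant.setdefault(m.variant, {}).setdefault(m.experiment_id, 0)
        per_variant[m.variant][m.experiment_id] += 1

    under: dict[str, dict] = {}
    for variant, exps in per_variant.items():
        good_exps = [e for e, n in exps.items() if n >= min_replicates]
        if len(good_exps) < min_experiments:
            under[variant] = {
                "experiments": len(exps),
                "experiments_fully_replicated": len(good_exps),
                "replicates_per_experiment": dict(sorted(exps.items())),
            }

    missing_wt, missing_neg = [], []
    for batch_id in dataset.batches:
        batch = [m for m in dataset.measurements if m.batch_id == batch_id]
        if not any(m.control is Control.WT for m in batch):
            missing_wt.append(batch_id)
        if not any(m.control is Control.NEG for m in batch):
            missing_neg.append(batch_id)

    return ValidationReport(
        n_measurements=len(dataset.measurements),
        n_variants=len(per_variant),
        n_batches=len(dataset.batches),
        under_replicated=under,
        batches_missing_wt=missing_wt,
        batches_missing_neg=missing_neg,
    )
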