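"""Five-tier functional classification (fClass) of posterior pathogenicity.

PrDel, the posterior probability that a variant's function effect arises
from the pathogenic mixture component, is partitioned into five tiers
mirroring the five-tier clinical (IARC-style) scheme:

    fClass 1  non-pathogenic          PrDel <  0.001
    fClass 2  likely not pathogenic   0.001 <= PrDel <= 0.05
    fClass 3  uncertain (VUS)         0.05  <  PrDel <= 0.95
    fClass 4  likely pathogenic       0.95  <  PrDel <= 0.99
    fClass 5  pathogenic              PrDel >  0.99

The published inequalities leave PrDel exactly 0.001 unassigned; this
implementation closes the fClass 2 lower boundary there (configurable),
preferring "likely not pathogenic" over "not pathogenic" for the tie.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

__all__ = ["ClassificationScheme", "ClassSummary", "fclass", "summarize_classes"]

UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class ClassificationScheme:
    """Ordered PrDel thresholds partitioning [0, 1] into fClass 1-5."""

    t1: float = 0.001
    t2: float = 0.05
    t3: float = 0.95
    t4: float = 0.99
    #: class assigned at PrDel == t1 exactly (the printed inequalities
    #: leave it open); 2 by default.
    t1_boundary_class: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.t1 < self.t2 < self.t3 < self.t4 < 1):
            raise ValueError("thresholds must satisfy 0 < t1 < t2 < t3 < t4 < 1")
        if self.t1_boundary_class not in (1, 2):
            raise ValueError("t1_boundary_class must be 1 or 2")


def fclass(prdel: float, scheme: ClassificationScheme | None = None) -> int:
    """Map a posterior probability of pathogenicity to fClass 1-5."""
    scheme = scheme or ClassificationScheme()
    if not 0 <= prdel <= 1:
        raise ValueError(f"PrDel must lie in [0, 1], got {prdel}")
    if prdel < scheme.t1:
        return 1
    if prdel == scheme.t1:
        return scheme.t1_boundary_class
    if prdel <= scheme.t2:
        return 2
    if prdel <= scheme.t3:
        return 3
    if prdel <= scheme.t4:
        return 4
    return 5


@dataclass
class ClassSummary:
    """Classification landscape: per-class counts, VUS reduction among
    previously unclassified variants, and a cross-tab against prior classes."""

    class_counts: dict[int, int]
    n_unclassified_prior: int
    n_unclassified_remaining_vus: int
    reduction_percent: int | None
    cross_tab: dict[str, dict[int, int]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "class_counts": {str(k): v for k, v in sorted(self.class_counts.items())},
                "n_unclassified_prior": self.n_unclassified_prior,
                "n_unclassified_remaining_vus": self.n_unclassified_remaining_vus,
                "reduction_percent": self.reduction_percent,
                "cross_tab": {
                    p: {str(k): v for k, v in sorted(c.items())}
                    for p, c in sorted(self.cross_tab.items())
                },
            },
            indent=2,
        )


def summarize_classes(
    calls: list[tuple[str, int]],
    prior: dict[str, str] | None = None,
) -> ClassSummary:
    """Summarize fClass calls against prior (e.g., IARC) classifications.

    Among variants previously UNCLASSIFIED, the VUS-reduction percentage
    is ``100 * (1 - n_remaining_fClass3 / n_unclassified)``, rounded to
    the nearest integer.  ``prior`` maps variant to a prior class string
    or ``UNCLASSIFIED``; when omitted, every variant counts as
    previously unclassified.
    """
    if not calls:
        raise ValueError("no calls to summarize")
    if prior is None:
        prior = {v: UNCLASSIFIED for v, _ in calls}
    missing = [v for v, _ in calls if v not in prior]
    if missing:
        raise KeyError(f"variants missing from the prior map: {missing}")

    counts: dict[int, int] = {k: 0 for k in range(1, 6)}
    cross: dict[str, dict[int, int]] = {}
    n_unclass = n_vus_left = 0
    for variant, fc in calls:
        if fc not in counts:
            raise ValueError(f"invalid fClass {fc!r} for {variant!r}")
        counts[fc] += 1
        p = prior[variant]
        cross.setdefault(p, {k: 0 for k in range(1, 6)})[fc] += 1
        if p == UNCLASSIFIED:
            n_unclass += 1
            if fc == 3:
                n_vus_left += 1

    reduction = (
        int(round(100.0 * (1.0 - n_vus_left / n_unclass))) if n_unclass else None
    )
    return ClassSummary(
        class_counts=counts,
        n_unclassified_prior=n_unclass,
        n_unclassified_remaining_vus=n_vus_left,
        reduction_percent=reduction,
        cross_tab=cross,
    )
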