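"""Rule-based malignancy classification of nodule records.

Three decision rules, scored against the cytology/histology label:

* **GSU rule** — malignant iff at least one suspicious grey-scale
  feature is present (microcalcification, hypoechogenicity, irregular
  margins, tall-to-width ratio > 1).
* **Combined-VI rule** — malignant iff peripheral, central *and* overall
  VI are each >= their respective cut-offs (inclusive).
* **Combined VI + GSU rule** — the conjunction of the two.

The regional VIs are taken at a chosen offset level (default: the
study's optimum, 22%); the overall VI is that of the representative
frame and is offset-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from . import study
from .cohort import (
    ConfusionCounts,
    DiagnosticMetrics,
    NoduleRecord,
    diagnostic_metrics,
)
from .errors import ValidationError

logger = logging.getLogger(__name__)

Rule = Callable[[NoduleRecord], bool]


@dataclass(frozen=True)
class CutoffSet:
    """VI cut-offs (%) for the conjunctive rule.

    Defaults are the study-derived optima at the 22% offset; override
    them for data from a different scanner, protocol or population.
    """

    peripheral_cut: float = study.DEFAULT_CUTOFFS[0]
    central_cut: float = study.DEFAULT_CUTOFFS[1]
    overall_cut: float = study.DEFAULT_CUTOFFS[2]

    def __post_init__(self) -> None:
        for name in ("peripheral_cut", "central_cut", "overall_cut"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValidationError(f"{name} must be in [0, 100], got {v}")


@dataclass(frozen=True)
class DiagnosticReport:
    rule_name: str
    counts: ConfusionCounts
    metrics: DiagnosticMetrics
    per_nodule_calls: Mapping[str, bool]


def gsu_rule(record: NoduleRecord) -> bool:
    """Malignant iff any suspicious GSU feature is present."""
    if record.gsu is None:
        raise ValidationError(f"{record.nodule_id}: GSU features missing")
    return record.gsu.any_suspicious()


def combined_vi_rule(
    record: NoduleRecord,
    cutoffs: CutoffSet | None = None,
    offset_pct: float = float(study.OPTIMUM_OFFSET),
) -> bool:
    """Malignant iff all three VIs are >= their cut-offs (inclusive).

    A record whose central (or peripheral) VI is undefined — the region
    was empty at this offset — is conservatively called benign and
    flagged: the rule requires all three indices to reach their cut-offs
    and an absent index cannot.
    """
    cutoffs = cutoffs or CutoffSet()
    if record.overall_vi is None:
        raise ValidationError(f"{record.nodule_id}: overall VI missing")
    if offset_pct not in record.vi_by_offset:
        raise ValidationError(
            f"{record.nodule_id}: no VI measured at offset {offset_pct}%"
        )
    peripheral, central = record.vi_by_offset[offset_pct]
    if peripheral is None or central is None:
        logger.warning(
            "%s: undefined %s VI at offset %g%% -> classified benign",
            record.nodule_id,
            "central" if central is None else "peripheral",
            offset_pct,
        )
        return False
    return (
        peripheral >= cutoffs.peripheral_cut
        and central >= cutoffs.central_cut
        and record.overall_vi >= cutoffs.overall_cut
    )


def combined_vi_gsu_rule(
    record: NoduleRecord,
    cutoffs: CutoffSet | None = None,
    offset_pct: float = float(study.OPTIMUM_OFFSET),
) -> bool:
    """Malignant iff the GSU rule *and* the combined-VI rule both fire."""
    return gsu_rule(record) and combined_vi_rule(record, cutoffs, offset_pct)


def make_rule(
    name: str,
    cutoffs: CutoffSet | None = None,
    offset_pct: float = float(study.OPTIMUM_OFFSET),
) -> Rule:
    """Bind one of the named rules ('gsu', 'combined_vi',
    'combined_vi_gsu') to a cut-off set and offset level."""
    if name == "gsu":
        return gsu_rule
    if name == "combined_vi":
        return lambda r: combined_vi_rule(r, cutoffs, offset_pct)
    if name == "combined_vi_gsu":
        return lambda r: combined_vi_gsu_rule(r, cutoffs, offset_pct)
    raise ValidationError(f"unknown rule {name!r}")


def score_rule(
    records: Sequence[NoduleRecord], rule: Rule, rule_name: str = "rule"
) -> DiagnosticReport:
    """Apply *rule* to every record and tally performance against the
    pathology labels."""
    if len(records) == 0:
        raise ValidationError("empty cohort")
    calls = {r.nodule_id: bool(rule(r)) for r in records}
    tp = sum(1 for r in records if r.malignant and calls[r.nodule_id])
    fn = sum(1 for r in records if r.malignant and not calls[r.nodule_id])
    fp = sum(1 for r in records if not r.malignant and calls[r.nodule_id])
    tn = sum(1 for r in records if not r.malignant and not calls[r.nodule_id])
    counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    return DiagnosticReport(
        rule_name=rule_name,
        counts=counts,
        metrics=diagnostic_metrics(counts),
        per_nodule_calls=calls,
    )
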