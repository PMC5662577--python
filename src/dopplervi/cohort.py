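"""Cohort-level statistics.

Between-group comparisons of vascular indices per offset level, the
optimum-offset search, ROC cut-off derivation and diagnostic-performance
arithmetic.  Everything here operates on summary statistics or plain
per-nodule tables, so it is equally usable on measured cohorts and on
published group summaries.

No multiple-testing correction is applied anywhere in this module; the
offset search deliberately screens nine correlated tests at a fixed
per-test alpha (documented in the methods note).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .errors import SchemaError, ValidationError

TTestVariant = Literal["welch", "pooled"]

#: Names of the four binary grey-scale ultrasound (GSU) features, in
#: canonical column order.
GSU_FEATURES = ("microcalcification", "hypoechoic", "irregular_margins", "tall_to_width_gt_1")

_GSU_COLUMNS = {
    "microcalcification": "gsu_microcalc",
    "hypoechoic": "gsu_hypoechoic",
    "irregular_margins": "gsu_irregular",
    "tall_to_width_gt_1": "gsu_tall",
}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (the convention of clinical tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GSUFeatures:
    """The four suspicious grey-scale ultrasound features of a nodule."""

    microcalcification: bool
    hypoechoic: bool
    irregular_margins: bool
    tall_to_width_gt_1: bool

    def any_suspicious(self) -> bool:
        return (
            self.microcalcification
            or self.hypoechoic
            or self.irregular_margins
            or self.tall_to_width_gt_1
        )

    def __getitem__(self, name: str) -> bool:
        if name not in GSU_FEATURES:
            raise ValidationError(f"unknown GSU feature {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class NoduleRecord:
    """One nodule: VI profile, GSU features and the pathology label.

    ``vi_by_offset`` maps an offset level (percent) to the
    ``(peripheral_vi, central_vi)`` pair at that offset; either entry may
    be ``None`` when the region was empty.  ``overall_vi`` is the VI of
    the whole nodule on the representative frame (offset-independent).
    """

    nodule_id: str
    malignant: bool
    overall_vi: float | None
    vi_by_offset: Mapping[float, tuple[float | None, float | None]]
    gsu: GSUFeatures


@dataclass(frozen=True)
class GroupSummary:
    """Size, mean and SD of a VI distribution within one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"group size must be >= 1, got {self.n}")
        if self.sd < 0:
            raise ValidationError(f"sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class RegionalGroupSummaries:
    """Benign/malignant summaries for both regions at one offset level."""

    peripheral_benign: GroupSummary
    peripheral_malignant: GroupSummary
    central_benign: GroupSummary
    central_malignant: GroupSummary


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity/specificity/NPV/PPV/accuracy, each in percent.

    PPV is ``None`` when no positive call was made (tp + fp = 0), and
    NPV when no negative call was made — undefined, not zero.
    """

    sensitivity: float
    specificity: float
    npv: float | None
    ppv: float | None
    accuracy: float

    def rounded(self, ndigits: int = 1) -> "DiagnosticMetrics":
        r = lambda v: None if v is None else round_half_up(v, ndigits)
        return DiagnosticMetrics(
            sensitivity=r(self.sensitivity),  # type: ignore[arg-type]
            specificity=r(self.specificity),  # type: ignore[arg-type]
            npv=r(self.npv),
            ppv=r(self.ppv),
            accuracy=r(self.accuracy),  # type: ignore[arg-type]
        )


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class OffsetSearchResult:
    """Outcome of the optimum-offset search.

    ``selected`` is the smallest qualifying offset (``None`` when no
    offset reaches significance in both regions); ``qualifying`` lists
    them all; ``p_values`` maps every tested offset to its
    ``(peripheral_p, central_p)`` pair.
    """

    selected: float | None
    qualifying: tuple[float, ...]
    p_values: Mapping[float, tuple[float, float]]


@dataclass(frozen=True)
class RocResult:
    cutoff: float
    sensitivity: float  # fraction in [0, 1]
    specificity: float  # fraction in [0, 1]
    auc: float
    youden: float


@dataclass(frozen=True)
class ChiSquareResult:
    chi_square: float
    p: float
    prevalence_benign: float  # percent
    prevalence_malignant: float  # percent


# ---------------------------------------------------------------------------
# Two-sample location tests from summary statistics
# ---------------------------------------------------------------------------


def two_sample_t(
    a: GroupSummary, b: GroupSummary, variant: TTestVariant = "welch"
) -> TTestResult:
    """Two-sample t test of mean(a) - mean(b) from summary statistics.

    ``welch`` (default) does not assume equal variances and uses the
    Welch–Satterthwaite degrees of freedom; ``pooled`` is the classical
    equal-variance Student test.  Two-tailed p.

    Degenerate case: both SDs zero.  With equal means the groups are
    indistinguishable and ``t = 0, p = 1`` by convention; with unequal
    means the separation is infinite and ``p = 0``.
    """
    if a.n < 2 or b.n < 2:
        raise ValidationError("two_sample_t requires n >= 2 in both groups")
    va, vb = a.sd**2, b.sd**2
    diff = a.mean - b.mean
    if va == 0.0 and vb == 0.0:
        if diff == 0.0:
            return TTestResult(t=0.0, df=float(a.n + b.n - 2), p=1.0)
        return TTestResult(
            t=math.copysign(math.inf, diff), df=float(a.n + b.n - 2), p=0.0
        )
    if variant == "welch":
        qa, qb = va / a.n, vb / b.n
        se2 = qa + qb
        df = se2**2 / (qa**2 / (a.n - 1) + qb**2 / (b.n - 1))
    elif variant == "pooled":
        df = float(a.n + b.n - 2)
        sp2 = ((a.n - 1) * va + (b.n - 1) * vb) / df
        se2 = sp2 * (1.0 / a.n + 1.0 / b.n)
    else:
        raise ValidationError(f"unknown t-test variant {variant!r}")
    t = diff / math.sqrt(se2)
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=float(df), p=p)


def optimum_offset(
    summaries: Mapping[float, RegionalGroupSummaries],
    alpha: float = 0.05,
    variant: TTestVariant = "welch",
) -> OffsetSearchResult:
    """Select the offset level separating benign from malignant nodules
    in *both* regions.

    An offset qualifies when the malignant-vs-benign test gives
    ``p < alpha`` for the peripheral *and* the central VI.  With several
    qualifying offsets the smallest is selected (all are reported); with
    none, ``selected`` is ``None``.
    """
    if len(summaries) == 0:
        raise ValidationError("at least one offset level is required")
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    p_values: dict[float, tuple[float, float]] = {}
    qualifying: list[float] = []
    for pct in sorted(summaries):
        s = summaries[pct]
        p_per = two_sample_t(s.peripheral_malignant, s.peripheral_benign, variant).p
        p_cen = two_sample_t(s.central_malignant, s.central_benign, variant).p
        p_values[pct] = (p_per, p_cen)
        if p_per < alpha and p_cen < alpha:
            qualifying.append(pct)
    return OffsetSearchResult(
        selected=qualifying[0] if qualifying else None,
        qualifying=tuple(qualifying),
        p_values=p_values,
    )


def refine_offset_search(
    coarse: Sequence[float],
    evaluate,
    alpha: float = 0.05,
) -> OffsetSearchResult:
    """Two-stage offset search mirroring a coarse-grid-then-unit-refine
    protocol.

    ``evaluate(offsets)`` must return a mapping offset ->
    :class:`RegionalGroupSummaries` for the requested levels (typically a
    closure over a cohort re-measured at those offsets).  The coarse grid
    is scanned first; if no coarse offset qualifies, the unit grid
    between the best coarse neighbours (the pair bracketing the largest
    combined evidence) is scanned as well and the union is evaluated.
    """
    coarse = sorted(float(c) for c in coarse)
    coarse_summaries = evaluate(coarse)
    result = optimum_offset(coarse_summaries, alpha=alpha)
    if result.selected is not None or len(coarse) < 2:
        return result
    # best coarse level = smallest max(p_peripheral, p_central)
    worst_p = {pct: max(ps) for pct, ps in result.p_values.items()}
    best = min(coarse, key=lambda pct: worst_p[pct])
    i = coarse.index(best)
    neighbours = [coarse[j] for j in (i - 1, i + 1) if 0 <= j < len(coarse)]
    lo = min([best] + neighbours)
    hi = max([best] + neighbours)
    fine = [float(v) for v in np.arange(math.ceil(lo), math.floor(hi) + 1)]
    extra = [v for v in fine if v not in coarse]
    all_summaries = dict(coarse_summaries)
    if extra:
        all_summaries.update(evaluate(extra))
    return optimum_offset(all_summaries, alpha=alpha)


def summarize_cohort(
    records: Sequence[NoduleRecord],
    offsets: Sequence[float] | None = None,
) -> dict[float, RegionalGroupSummaries]:
    """Per-offset benign/malignant group summaries of a measured cohort.

    Records with a missing (``None``) VI at an offset are excluded from
    that offset's summary for that region; sample SDs use ddof=1.
    """
    if len(records) == 0:
        raise ValidationError("empty cohort")
    if offsets is None:
        offsets = sorted({pct for r in records for pct in r.vi_by_offset})
    out: dict[float, RegionalGroupSummaries] = {}
    for pct in offsets:
        cells: dict[str, GroupSummary] = {}
        for region_idx, region in enumerate(("peripheral", "central")):
            for malignant in (False, True):
                vals = [
                    r.vi_by_offset[pct][region_idx]
                    for r in records
                    if r.malignant == malignant and pct in r.vi_by_offset
                ]
                vals = np.array([v for v in vals if v is not None], dtype=float)
                if len(vals) < 2:
                    raise ValidationError(
                        f"fewer than 2 {region} values in the "
                        f"{'malignant' if malignant else 'benign'} group at "
                        f"offset {pct}"
                    )
                cells[f"{region}_{'malignant' if malignant else 'benign'}"] = GroupSummary(
                    n=len(vals), mean=float(vals.mean()), sd=float(vals.std(ddof=1))
                )
        out[float(pct)] = RegionalGroupSummaries(**cells)
    return out


# ---------------------------------------------------------------------------
# ROC cut-off
# ---------------------------------------------------------------------------


def roc_cutoff(
    scores: Sequence[float], labels: Sequence[bool]
) -> RocResult:
    """Optimum VI cut-off by the Youden index.

    Decision rule: positive iff ``score >= cutoff``.  Candidate cut-offs
    are the observed score values; the cut-off maximizing
    ``J = sensitivity + specificity - 1`` wins, ties resolved toward the
    lower cut-off.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValidationError("scores and labels must be equal-length 1-D")
    if not np.all(np.isfinite(s)):
        raise ValidationError("scores must be finite")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present")
    candidates = np.unique(s)  # ascending
    # positive iff score >= c
    sens = np.array([(s[y] >= c).mean() for c in candidates])
    spec = np.array([(s[~y] < c).mean() for c in candidates])
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # first max = lowest cutoff on ties
    return RocResult(
        cutoff=float(candidates[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        auc=float(roc_auc_score(y, s)),
        youden=float(j[best]),
    )


def roc_points(scores: Sequence[float], labels: Sequence[bool]) -> pd.DataFrame:
    """Sensitivity/specificity at every observed cut-off (for plotting)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    candidates = np.unique(s)
    return pd.DataFrame(
        {
            "cutoff": candidates,
            "sensitivity": [(s[y] >= c).mean() for c in candidates],
            "specificity": [(s[~y] < c).mean() for c in candidates],
        }
    )


# ---------------------------------------------------------------------------
# Diagnostic-performance arithmetic
# ---------------------------------------------------------------------------


def diagnostic_metrics(counts: ConfusionCounts) -> DiagnosticMetrics:
    """The five standard test metrics, in percent (full precision;
    use :meth:`DiagnosticMetrics.rounded` for 1-decimal table cells)."""
    if counts.tp + counts.fn < 1:
        raise ValidationError("no positive cases (tp + fn = 0)")
    if counts.tn + counts.fp < 1:
        raise ValidationError("no negative cases (tn + fp = 0)")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    return DiagnosticMetrics(
        sensitivity=100.0 * tp / (tp + fn),
        specificity=100.0 * tn / (tn + fp),
        npv=None if tn + fn == 0 else 100.0 * tn / (tn + fn),
        ppv=None if tp + fp == 0 else 100.0 * tp / (tp + fp),
        accuracy=100.0 * (tp + tn) / counts.total,
    )


def counts_from_rates(
    sensitivity: float, specificity: float, n_pos: int, n_neg: int
) -> ConfusionCounts:
    """Reconstruct integer confusion counts from published rates.

    ``tp = round(sens/100 * n_pos)`` and ``tn = round(spec/100 * n_neg)``
    with half-up rounding; fn/fp by complement.  Used to close the loop
    on published performance tables: rates -> counts -> recomputed
    metrics must reproduce every cell of an internally consistent table.
    """
    for name, rate in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= rate <= 100.0:
            raise ValidationError(f"{name} must be in [0, 100], got {rate}")
    if n_pos < 1 or n_neg < 1:
        raise ValidationError("n_pos and n_neg must be >= 1")
    tp = int(round_half_up(sensitivity / 100.0 * n_pos, 0))
    tn = int(round_half_up(specificity / 100.0 * n_neg, 0))
    return ConfusionCounts(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)


# ---------------------------------------------------------------------------
# GSU feature comparison
# ---------------------------------------------------------------------------


def chi_square_2x2(
    k_malignant: int, n_malignant: int, k_benign: int, n_benign: int,
    correction: bool = False,
) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 feature-by-group table.

    No continuity correction by default (set ``correction=True`` for
    Yates).  A margin of zero (feature present in everyone or no one)
    makes the statistic undefined and raises."""
    table = np.array(
        [
            [k_malignant, n_malignant - k_malignant],
            [k_benign, n_benign - k_benign],
        ]
    )
    if table.min() < 0:
        raise ValidationError("counts exceed group sizes")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("chi-square undefined: a table margin is zero")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)


def gsu_feature_test(
    records: Sequence[NoduleRecord], feature: str, correction: bool = False
) -> ChiSquareResult:
    """Compare one GSU feature's prevalence between benign and malignant
    nodules with a 2x2 chi-square test."""
    if feature not in GSU_FEATURES:
        raise ValidationError(
            f"unknown GSU feature {feature!r}; expected one of {GSU_FEATURES}"
        )
    mal = [r for r in records if r.malignant]
    ben = [r for r in records if not r.malignant]
    if not mal or not ben:
        raise ValidationError("both benign and malignant groups must be non-empty")
    k_m = sum(r.gsu[feature] for r in mal)
    k_b = sum(r.gsu[feature] for r in ben)
    chi2, p = chi_square_2x2(k_m, len(mal), k_b, len(ben), correction=correction)
    return ChiSquareResult(
        chi_square=chi2,
        p=p,
        prevalence_benign=100.0 * k_b / len(ben),
        prevalence_malignant=100.0 * k_m / len(mal),
    )


# ---------------------------------------------------------------------------
# Cohort table I/O
# ---------------------------------------------------------------------------
# CSV schema: nodule_id, malignant (0/1), overall_vi, then
# peripheral_vi_<n> / central_vi_<n> per offset level n, then
# gsu_microcalc, gsu_hypoechoic, gsu_irregular, gsu_tall (0/1 each).

_PERIPH_RE = re.compile(r"^peripheral_vi_(\d+(?:\.\d+)?)$")


def cohort_to_frame(records: Sequence[NoduleRecord]) -> pd.DataFrame:
    offsets = sorted({pct for r in records for pct in r.vi_by_offset})
    rows = []
    for r in records:
        row: dict[str, object] = {
            "nodule_id": r.nodule_id,
            "malignant": int(r.malignant),
            "overall_vi": np.nan if r.overall_vi is None else r.overall_vi,
        }
        for pct in offsets:
            per, cen = r.vi_by_offset.get(pct, (None, None))
            key = f"{pct:g}"
            row[f"peripheral_vi_{key}"] = np.nan if per is None else per
            row[f"central_vi_{key}"] = np.nan if cen is None else cen
        for feat, col in _GSU_COLUMNS.items():
            row[col] = int(r.gsu[feat])
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_cohort(df: pd.DataFrame) -> list[NoduleRecord]:
    required = {"nodule_id", "malignant", "overall_vi", *_GSU_COLUMNS.values()}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"cohort table is missing columns: {sorted(missing)}")
    offsets = []
    for col in df.columns:
        m = _PERIPH_RE.match(col)
        if m:
            key = m.group(1)
            if f"central_vi_{key}" not in df.columns:
                raise SchemaError(f"column central_vi_{key} missing")
            offsets.append(key)
    records = []
    for _, row in df.iterrows():
        vi_by_offset = {}
        for key in offsets:
            per = row[f"peripheral_vi_{key}"]
            cen = row[f"central_vi_{key}"]
            vi_by_offset[float(key)] = (
                None if pd.isna(per) else float(per),
                None if pd.isna(cen) else float(cen),
            )
        records.append(
            NoduleRecord(
                nodule_id=str(row["nodule_id"]),
                malignant=bool(int(row["malignant"])),
                overall_vi=None if pd.isna(row["overall_vi"]) else float(row["overall_vi"]),
                vi_by_offset=vi_by_offset,
                gsu=GSUFeatures(**{f: bool(int(row[c])) for f, c in _GSU_COLUMNS.items()}),
            )
        )
    return records


def write_cohort(records: Sequence[NoduleRecord], path: str | Path) -> None:
    cohort_to_frame(records).to_csv(Path(path), index=False)


def read_cohort(path: str | Path) -> list[NoduleRecord]:
    try:
        df = pd.read_csv(Path(path))
    except pd.errors.ParserError as exc:
        raise SchemaError(f"{path}: cannot parse as CSV") from exc
    return frame_to_cohort(df)
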