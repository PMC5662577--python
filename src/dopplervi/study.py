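"""Reference values from the originating clinical study.

These constants summarise the prospective cohort of 111 thyroid nodules
(84 benign, 27 malignant; SuperLinear SL15-4 probe, PRF 1000 Hz) on
which the regional-vascularity method was developed.  They serve three
purposes: as defaults for the synthetic cohort generator, as the fixed
inputs of the optimum-offset and table-closure recomputations, and as
the shipped default cut-offs of the rule-based classifier.  They are
*study-derived values*, not universal physiology — users applying the
classifier to their own scanner/population should re-derive cut-offs.

A note on the 23%-offset row: in the published summary table that row's
four cells are printed in a different order from every other row (as
printed, the benign central mean would exceed the benign peripheral mean
and the significance marks would flip).  The values below follow the
column order of the other eight rows, under which the row is consistent
with its neighbours and with its own significance marks.
"""

from __future__ import annotations

from .cohort import GroupSummary, RegionalGroupSummaries

N_BENIGN = 84
N_MALIGNANT = 27

#: Offset levels evaluated in the study: the 5%-interval coarse grid,
#: plus the unit refinement 21-24 between the coarse levels whose
#: significance pattern flipped.
OFFSET_LEVELS: tuple[int, ...] = (5, 10, 15, 20, 21, 22, 23, 24, 25)

#: The offset level the study selected (both regions significant).
OPTIMUM_OFFSET = 22


def _rgs(pb, pm, cb, cm) -> RegionalGroupSummaries:
    return RegionalGroupSummaries(
        peripheral_benign=GroupSummary(N_BENIGN, *pb),
        peripheral_malignant=GroupSummary(N_MALIGNANT, *pm),
        central_benign=GroupSummary(N_BENIGN, *cb),
        central_malignant=GroupSummary(N_MALIGNANT, *cm),
    )


#: Mean +/- SD of peripheral and central VI (%) per offset level and group.
REGIONAL_VI_SUMMARIES: dict[float, RegionalGroupSummaries] = {
    5.0: _rgs((21.7, 20.3), (23.5, 19.3), (15.2, 15.3), (23.4, 17.7)),
    10.0: _rgs((21.4, 19.6), (25.3, 18.7), (13.5, 14.6), (23.3, 18.0)),
    15.0: _rgs((20.0, 18.4), (24.0, 16.6), (12.4, 14.5), (22.3, 19.3)),
    20.0: _rgs((18.7, 17.1), (25.0, 17.0), (12.0, 14.7), (21.6, 20.1)),
    21.0: _rgs((18.4, 16.9), (25.0, 17.1), (11.9, 14.9), (21.3, 20.1)),
    22.0: _rgs((18.2, 16.7), (26.5, 16.2), (11.9, 15.1), (21.7, 19.6)),
    23.0: _rgs((17.9, 16.5), (24.9, 17.1), (11.9, 15.4), (20.9, 20.3)),
    24.0: _rgs((17.8, 16.4), (24.9, 17.2), (11.9, 15.6), (20.6, 20.1)),
    25.0: _rgs((17.7, 16.3), (26.6, 18.7), (11.9, 16.0), (20.4, 20.1)),
}

#: Overall (whole-nodule, representative-frame) VI summaries per group.
OVERALL_VI_BENIGN = GroupSummary(N_BENIGN, 16.6, 1.8)
OVERALL_VI_MALIGNANT = GroupSummary(N_MALIGNANT, 23.8, 4.6)

#: Prevalence (fraction) of each suspicious GSU feature per group.
GSU_PREVALENCE_BENIGN: dict[str, float] = {
    "microcalcification": 0.071,
    "hypoechoic": 0.333,
    "irregular_margins": 0.167,
    "tall_to_width_gt_1": 0.131,
}
GSU_PREVALENCE_MALIGNANT: dict[str, float] = {
    "microcalcification": 0.778,
    "hypoechoic": 0.926,
    "irregular_margins": 0.556,
    "tall_to_width_gt_1": 0.593,
}

#: ROC-derived optimum cut-offs (%) at the 22% offset:
#: (peripheral, central, overall).
DEFAULT_CUTOFFS: tuple[float, float, float] = (19.7, 9.1, 20.2)

#: Published diagnostic performance of the three single-index tests at
#: the 22% offset (sens, spec, npv, ppv, accuracy, all %), keyed by index.
SINGLE_VI_PERFORMANCE: dict[str, dict[str, float]] = {
    "peripheral_vi": dict(cutoff=19.7, sensitivity=74.1, specificity=60.7,
                          npv=87.9, ppv=37.7, accuracy=64.0),
    "central_vi": dict(cutoff=9.1, sensitivity=74.1, specificity=60.7,
                       npv=87.9, ppv=37.7, accuracy=64.0),
    "overall_vi": dict(cutoff=20.2, sensitivity=74.1, specificity=69.0,
                       npv=89.2, ppv=43.5, accuracy=70.3),
}

#: Published diagnostic performance of the three decision rules.
RULE_PERFORMANCE: dict[str, dict[str, float]] = {
    "gsu": dict(sensitivity=96.3, specificity=46.4, npv=97.5, ppv=36.6,
                accuracy=58.6),
    "combined_vi": dict(sensitivity=70.4, specificity=71.4, npv=88.2,
                        ppv=44.2, accuracy=71.2),
    "combined_vi_gsu": dict(sensitivity=66.7, specificity=83.3, npv=88.6,
                            ppv=56.3, accuracy=79.3),
}
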