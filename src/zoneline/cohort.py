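"""Batch evaluation and paired statistical comparison of segmentation cohorts.

Mirrors the analysis layout of inter-reader validation studies: each test
case has a model prediction and one or two independent reference
delineations, metrics are computed per structure for every pairing
(model-vs-reader-1, model-vs-reader-2, reader-1-vs-reader-2), cohorts are
summarised as median and inter-quartile range, and each model-vs-reader
metric is compared against the inter-reader baseline on the same cases with
the paired two-sided Wilcoxon signed-rank test.  A Shapiro-Wilk normality
screen on the paired differences is recorded alongside (it motivates the
non-parametric choice); no multiple-testing correction is applied.

Conventions pinned for reproducibility: quartiles use linear interpolation
between order statistics; Wilcoxon discards zero differences (``wilcox``
zero handling) and reports p = 1 when every difference is zero; distance
metrics of structures empty in either volume are reported as NaN and
dropped pairwise from the tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GeometryMismatchError
from .metrics import MetricReport, centerline, cld, dsc, pssd, surface_dsc
from .volumes import LabelVolume

__all__ = [
    "evaluate_case",
    "summarise_cohort",
    "structure_volumes",
    "CohortSummary",
    "STRUCTURES",
]

#: Structures evaluated per case; "prostate" is the union of all
#: non-background labels.
STRUCTURES = ("prostate", "PZ", "CZ", "TZ", "AFS", "urethra")

DEFAULT_PERCENTILES = (50.0, 80.0, 95.0)


def _structure_mask(vol: LabelVolume, structure: str) -> np.ndarray:
    if structure == "prostate":
        return vol.foreground()
    return vol.mask(vol.schema.code_of(structure))


def evaluate_case(
    pred: LabelVolume,
    ref: LabelVolume,
    tau_mm: float = 1.0,
    percentiles: Sequence[float] = DEFAULT_PERCENTILES,
) -> MetricReport:
    """Compute DSC, SDSC(τ) and pSSD for every structure, plus CLD for the urethra.

    Empty-structure conventions: DSC and SDSC are 1 when the structure is
    empty in both volumes and 0 when empty in exactly one; pSSD and CLD are
    NaN unless both are non-empty.
    """
    if not pred.geometry.same_grid(ref.geometry):
        raise GeometryMismatchError("prediction and reference are on different grids")
    geom = pred.geometry
    report = MetricReport(tau_mm=tau_mm)
    for structure in STRUCTURES:
        a = _structure_mask(pred, structure)
        b = _structure_mask(ref, structure)
        report.dsc[structure] = dsc(a, b)
        report.sdsc[structure] = surface_dsc(a, b, geom, tau_mm)
        both = a.any() and b.any()
        report.pssd[structure] = {
            float(p): (pssd(a, b, geom, p) if both else float("nan")) for p in percentiles
        }
        if structure == "urethra":
            report.cld[structure] = (
                cld(centerline(a, geom), centerline(b, geom)) if both else float("nan")
            )
    return report


def _report_rows(pairing: str, case_id, report: MetricReport):
    for s in report.dsc:
        yield pairing, case_id, s, "DSC", report.dsc[s]
        yield pairing, case_id, s, f"SDSC({report.tau_mm:g}mm)", report.sdsc[s]
        for p, v in report.pssd[s].items():
            yield pairing, case_id, s, f"pSSD_P{p:g}", v
    for s, v in report.cld.items():
        yield pairing, case_id, s, "CLD", v


@dataclass
class CohortSummary:
    """Per-case table, median/IQR summary and paired-comparison p-values."""

    per_case: pd.DataFrame  # pairing, case, structure, metric, value
    summary: pd.DataFrame  # pairing, structure, metric, n, median, q1, q3
    comparisons: pd.DataFrame  # pairing, structure, metric, n, shapiro_p, wilcoxon_p


def _paired_wilcoxon(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Two-sided Wilcoxon signed-rank p and Shapiro-Wilk p of the differences."""
    diff = x - y
    ok = np.isfinite(diff)
    diff = diff[ok]
    n = int(diff.size)
    if n < 2:
        return float("nan"), float("nan"), n
    shapiro_p = float(stats.shapiro(diff).pvalue) if n >= 3 and np.ptp(diff) > 0 else float("nan")
    if not np.any(diff != 0):
        return 1.0, shapiro_p, n  # no evidence of any difference
    w_p = float(
        stats.wilcoxon(diff, zero_method="wilcox", alternative="two-sided").pvalue
    )
    return w_p, shapiro_p, n


def summarise_cohort(
    reports: Mapping[str, Sequence[MetricReport]],
    baseline: str = "R1-vs-R2",
) -> CohortSummary:
    """Summarise a cohort of per-case metric reports across pairings.

    ``reports`` maps a pairing name (e.g. ``"model-vs-R1"``) to the ordered
    list of per-case reports; all pairings must cover the same cases in the
    same order.  Every non-baseline pairing is tested against ``baseline``
    per structure and metric with the paired Wilcoxon signed-rank test.
    """
    lengths = {k: len(v) for k, v in reports.items()}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"pairings cover different case counts: {lengths}")
    if min(lengths.values()) < 2:
        raise ValueError("at least 2 cases per pairing are required")

    rows = []
    for pairing, reps in reports.items():
        for case_id, rep in enumerate(reps):
            rows.extend(_report_rows(pairing, case_id, rep))
    per_case = pd.DataFrame(rows, columns=["pairing", "case", "structure", "metric", "value"])

    summary = (
        per_case.dropna(subset=["value"])
        .groupby(["pairing", "structure", "metric"], sort=False)["value"]
        .agg(
            n="count",
            median="median",
            q1=lambda v: float(np.percentile(v, 25)),
            q3=lambda v: float(np.percentile(v, 75)),
        )
        .reset_index()
    )

    comp_rows = []
    if baseline in reports:
        table = per_case.pivot_table(
            index=["case", "structure", "metric"], columns="pairing", values="value", dropna=False
        )
        for pairing in reports:
            if pairing == baseline:
                continue
            for (structure, metric), grp in table.groupby(level=["structure", "metric"]):
                w_p, shapiro_p, n = _paired_wilcoxon(
                    grp[pairing].to_numpy(float), grp[baseline].to_numpy(float)
                )
                if n > 0:  # skip structure/metric combos that were never computed
                    comp_rows.append((pairing, structure, metric, n, shapiro_p, w_p))
    comparisons = pd.DataFrame(
        comp_rows, columns=["pairing", "structure", "metric", "n", "shapiro_p", "wilcoxon_p"]
    )
    return CohortSummary(per_case, summary, comparisons)


def structure_volumes(labels: LabelVolume) -> pd.DataFrame:
    """Per-structure volume in cm³ and proportion of the whole-gland volume.

    The prostate volume is the union of all non-background structures;
    proportions of the individual structures sum to 1 over the gland.
    """
    vox_cm3 = labels.geometry.voxel_volume_mm3 / 1000.0
    rows = []
    prostate_vox = int(np.count_nonzero(labels.foreground()))
    rows.append(("prostate", prostate_vox * vox_cm3, 1.0 if prostate_vox else float("nan")))
    for code in labels.schema.sorted_codes:
        if code == 0:
            continue
        n = int(np.count_nonzero(labels.data == code))
        prop = n / prostate_vox if prostate_vox else float("nan")
        rows.append((labels.schema.name_of(code), n * vox_cm3, prop))
    return pd.DataFrame(rows, columns=["structure", "volume_cm3", "proportion"])
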