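"""Ventricular hemodynamics from 2-D geometry, and group-level reporting.

The larval zebrafish ventricle is approximated as an ellipsoid of revolution
about its major (longitudinal) axis, so a single 2-D view gives

    Volume = (pi/6) * D_major * D_minor**2.

From end-diastolic and end-systolic diameters/areas follow fractional
shortening (FS), fractional area change (FAC), end-diastolic and end-systolic
volumes (EDV/ESV), stroke volume SV = EDV − ESV, ejection fraction
EF = SV / EDV, and cardiac output CO = SV × HR. Group effects are reported as
fold changes of group means with two-tailed Student's t-tests (paired for
within-larva designs, unpaired otherwise).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GeometryTrace

__all__ = [
    "HemodynamicsRecord",
    "GroupComparison",
    "ellipsoid_volume",
    "compute_record",
    "compare_groups",
    "compare_groups_from_summary",
    "round_half_away",
    "load_drug_study_means",
    "drug_study_fold_changes",
]

UM3_PER_PL = 1.0e6  # 1 pL = 10^6 um^3


def ellipsoid_volume(major_um: float, minor_um: float) -> float:
    """Ellipsoid-of-revolution volume in pL from diameters in µm."""
    major = np.asarray(major_um, dtype=float)
    minor = np.asarray(minor_um, dtype=float)
    if np.any(major <= 0) or np.any(minor <= 0):
        raise ValueError("diameters must be positive")
    vol_um3 = (math.pi / 6.0) * major * minor ** 2
    out = vol_um3 / UM3_PER_PL
    return float(out) if out.ndim == 0 else out


@dataclass
class HemodynamicsRecord:
    """Per-larva ventricular function summary."""

    fs_major: float
    fs_minor: float
    fac: float
    edv_pl: float
    esv_pl: float
    sv_pl: float
    hr_bpm: float
    co_nl_min: float
    ef: float
    av_ratio: float  # ventricular HR / atrial HR; NaN when the atrium was not resolved

    def to_dict(self) -> dict:
        return asdict(self)


def _paired_extrema(geom: GeometryTrace) -> list[tuple[int, int]]:
    """(ED frame, following ES frame) index pairs, in temporal order."""
    ed_idx = np.nonzero(geom.phase == "ED")[0]
    es_idx = np.nonzero(geom.phase == "ES")[0]
    pairs = []
    for i_es in es_idx:
        prior = ed_idx[ed_idx < i_es]
        if prior.size:
            pairs.append((int(prior[-1]), int(i_es)))
    return pairs


def compute_record(geom: GeometryTrace, hr_bpm: float,
                   atrial_hr_bpm: float | None = None,
                   n_pairs: int = 3) -> HemodynamicsRecord:
    """Derive the hemodynamic record from labelled diastole/systole frames.

    Diameters and areas are averaged over the first ``n_pairs`` valid
    end-diastole/end-systole pairs (three in routine practice) before any
    ratio or volume is formed. A pair whose systolic measurement exceeds the
    diastolic one is flagged and excluded.
    """
    if hr_bpm <= 0:
        raise ValueError("heart rate must be positive")
    pairs = _paired_extrema(geom)
    if not pairs:
        raise ValueError("geometry trace has no labelled diastole/systole pair")

    valid = []
    for i_ed, i_es in pairs:
        if (geom.major_um[i_es] > geom.major_um[i_ed]
                or geom.minor_um[i_es] > geom.minor_um[i_ed]
                or geom.area_um2[i_es] > geom.area_um2[i_ed]):
            warnings.warn(
                f"systolic exceeds diastolic in pair (frames {i_ed}, {i_es}); "
                "pair excluded", stacklevel=2)
            continue
        valid.append((i_ed, i_es))
    if not valid:
        raise ValueError("no valid diastole/systole pairs")
    valid = valid[:n_pairs]

    ed = np.array([(geom.major_um[i], geom.minor_um[i], geom.area_um2[i]) for i, _ in valid])
    es = np.array([(geom.major_um[j], geom.minor_um[j], geom.area_um2[j]) for _, j in valid])
    dd_major, dd_minor, a_d = ed.mean(axis=0)
    ds_major, ds_minor, a_s = es.mean(axis=0)

    fs_major = (dd_major - ds_major) / dd_major
    fs_minor = (dd_minor - ds_minor) / dd_minor
    fac = (a_d - a_s) / a_d
    edv = ellipsoid_volume(dd_major, dd_minor)
    esv = ellipsoid_volume(ds_major, ds_minor)
    sv = edv - esv
    ef = sv / edv
    co = sv * hr_bpm / 1000.0  # pL/beat * beats/min -> nL/min
    av = hr_bpm / atrial_hr_bpm if atrial_hr_bpm else math.nan
    return HemodynamicsRecord(fs_major, fs_minor, fac, edv, esv, sv, hr_bpm, co, ef, av)


@dataclass
class GroupComparison:
    """Two-group summary: means, SDs, fold change, Student's t."""

    metric: str
    control_mean: float
    control_sd: float
    control_n: int
    treated_mean: float
    treated_sd: float
    treated_n: int
    fold_change: float  # treated mean / control mean
    t_stat: float
    p_value: float
    paired: bool


def compare_groups(control, treated, paired: bool = False,
                   metric: str = "") -> GroupComparison:
    """Compare two groups of per-larva metric values.

    Fold change is the ratio of group means (treated/control); the test is a
    two-tailed Student's t — paired for repeated measures on the same larvae
    (requires equal lengths), otherwise unpaired with pooled variance.
    """
    c = np.asarray(control, dtype=float)
    t = np.asarray(treated, dtype=float)
    if c.size < 2 or t.size < 2:
        raise ValueError("need n >= 2 per group")
    if paired and c.size != t.size:
        raise ValueError("paired comparison requires equal group sizes")
    if c.std(ddof=1) == 0 and t.std(ddof=1) == 0 and not paired:
        raise ValueError("zero variance in both groups")
    if paired:
        if np.all(t - c == 0):  # no within-pair differences: t = 0, p = 1
            return GroupComparison(metric, float(c.mean()), float(c.std(ddof=1)),
                                   c.size, float(t.mean()), float(t.std(ddof=1)),
                                   t.size, float(t.mean() / c.mean()), 0.0, 1.0,
                                   paired)
        res = stats.ttest_rel(t, c)
    else:
        res = stats.ttest_ind(t, c, equal_var=True)
    return GroupComparison(
        metric, float(c.mean()), float(c.std(ddof=1)), int(c.size),
        float(t.mean()), float(t.std(ddof=1)), int(t.size),
        float(t.mean() / c.mean()), float(res.statistic), float(res.pvalue), paired,
    )


def compare_groups_from_summary(control_mean: float, control_sd: float, control_n: int,
                                treated_mean: float, treated_sd: float, treated_n: int,
                                metric: str = "") -> GroupComparison:
    """Comparison from published summary statistics (mean, SD, n).

    Only the unpaired pooled-variance t is computable from summaries (a
    paired t needs the within-subject correlation); the fold change of means
    is defined either way.
    """
    if control_mean == 0:
        raise ValueError("control mean is zero; fold change undefined")
    fold = treated_mean / control_mean
    if control_n >= 2 and treated_n >= 2 and (control_sd > 0 or treated_sd > 0):
        res = stats.ttest_ind_from_stats(treated_mean, treated_sd, treated_n,
                                         control_mean, control_sd, control_n,
                                         equal_var=True)
        t_stat, p = float(res.statistic), float(res.pvalue)
    else:
        t_stat, p = math.nan, math.nan
    return GroupComparison(metric, control_mean, control_sd, control_n,
                           treated_mean, treated_sd, treated_n,
                           fold, t_stat, p, paired=False)


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (the convention of printed clinical tables)."""
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def load_drug_study_means() -> pd.DataFrame:
    """Packaged transcription of the published drug-study group statistics.

    Columns: experiment (propranolol | terfenadine), group (control |
    treated), metric, mean, sd, n. The file is a transcription of printed
    summary statistics, shipped so fold-change reports can be reproduced
    without the original recordings.
    """
    with resources.files("cardiolum.data").joinpath("drug_study_group_means.csv").open() as fh:
        return pd.read_csv(fh)


def drug_study_fold_changes() -> pd.DataFrame:
    """Fold changes (treated/control) recomputed from the packaged group means.

    Returns one row per experiment x metric with the fold change of means,
    its 2-d.p. rounding (half away from zero), and the unpaired-t p value
    where it is computable from summaries.
    """
    df = load_drug_study_means()
    rows = []
    for (exp, metric), sub in df.groupby(["experiment", "metric"], sort=False):
        piv = sub.set_index("group")
        if not {"control", "treated"} <= set(piv.index):
            continue
        cmp_ = compare_groups_from_summary(
            piv.loc["control", "mean"], piv.loc["control", "sd"], int(piv.loc["control", "n"]),
            piv.loc["treated", "mean"], piv.loc["treated", "sd"], int(piv.loc["treated", "n"]),
            metric=metric,
        )
        rows.append({
            "experiment": exp, "metric": metric,
            "control_mean": cmp_.control_mean, "treated_mean": cmp_.treated_mean,
            "fold_change": cmp_.fold_change,
            "fold_change_2dp": round_half_away(cmp_.fold_change, 2),
            "p_unpaired": cmp_.p_value,
        })
    return pd.DataFrame(rows)
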