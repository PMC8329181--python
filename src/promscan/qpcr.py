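"""Efficiency-corrected relative qPCR quantification.

Relative expression uses the efficiency-corrected form of the 2^-dCt method
(the Pfaffl ratio): ratio = E_target^(-Ct_target) / E_ref^(-Ct_ref), where E
is the per-cycle amplification factor (2 = perfect doubling).  Fold changes
between conditions use 2^-ddCt, or its efficiency-corrected ratio-of-ratios
form.  Technical replicates are averaged on the Ct scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QpcrMeasurement",
    "RelativeExpression",
    "parse_efficiency",
    "ratio_dct",
    "fold_change_ddct",
    "calibrate",
    "average_replicates",
    "fold_change_table",
    "replicate_ttest",
]


def parse_efficiency(value) -> float:
    """Accept an amplification factor (1..2) or a percent string ('95%' -> 1.95)."""
    if isinstance(value, str) and value.strip().endswith("%"):
        return 1.0 + float(value.strip().rstrip("%")) / 100.0
    return float(value)


@dataclass
class QpcrMeasurement:
    target: str
    sample: str
    ct: float
    efficiency: float  # per-cycle amplification factor; 2 = 100% efficiency

    def __post_init__(self) -> None:
        self.efficiency = parse_efficiency(self.efficiency)
        if self.ct <= 0:
            raise ValueError(f"{self.target}/{self.sample}: Ct must be > 0")
        if not 1.0 <= self.efficiency <= 2.0:
            warnings.warn(
                f"{self.target}/{self.sample}: efficiency {self.efficiency} "
                "outside [1, 2]"
            )


@dataclass
class RelativeExpression:
    target: str
    sample: str
    ratio: float
    calibrator: str


def ratio_dct(ct_target: float, eff_target, ct_ref: float, eff_ref) -> float:
    """Efficiency-corrected relative expression E_t^(-Ct_t) / E_r^(-Ct_r).

    With both efficiencies 2 this reduces to 2^-dCt exactly.  Computed in log
    space to avoid under/overflow at large Ct.
    """
    et, er = parse_efficiency(eff_target), parse_efficiency(eff_ref)
    if et <= 1.0 or er <= 1.0:
        warnings.warn("efficiency <= 1: no amplification; ratio flagged")
    log2_ratio = -ct_target * math.log2(et) + ct_ref * math.log2(er)
    return 2.0 ** log2_ratio


def average_replicates(ct_values) -> float:
    """Technical replicates are averaged on the Ct (log) scale."""
    return float(np.mean(np.asarray(ct_values, dtype=float)))


def fold_change_ddct(
    sample_measurements: dict[str, QpcrMeasurement],
    control_measurements: dict[str, QpcrMeasurement],
    reference_gene: str,
    target_gene: str | None = None,
    efficiency_corrected: bool = True,
) -> float:
    """Fold change of target in sample vs control, normalized to a reference gene.

    Measurements are keyed by gene name; each dict must contain the reference
    gene and exactly one other gene (or ``target_gene`` names it).  Classic
    2^-ddCt when ``efficiency_corrected`` is False; otherwise the Pfaffl
    ratio-of-ratios E_t^dCt_t(control-sample) / E_r^dCt_r(control-sample).
    """
    for label, cond in (("sample", sample_measurements), ("control", control_measurements)):
        if reference_gene not in cond:
            raise KeyError(f"reference gene {reference_gene!r} missing in {label}")
    if target_gene is None:
        others = set(sample_measurements) - {reference_gene}
        if len(others) != 1:
            raise ValueError("target_gene must be named when several targets present")
        target_gene = others.pop()
    ts, tc = sample_measurements[target_gene], control_measurements[target_gene]
    rs, rc = sample_measurements[reference_gene], control_measurements[reference_gene]
    if efficiency_corrected:
        log2_fc = (tc.ct - ts.ct) * math.log2(ts.efficiency) - (
            rc.ct - rs.ct
        ) * math.log2(rs.efficiency)
        return 2.0 ** log2_fc
    ddct = (ts.ct - rs.ct) - (tc.ct - rc.ct)
    return 2.0 ** (-ddct)


def calibrate(ratios: dict[str, float], calibrator_id: str) -> list[RelativeExpression]:
    """Scale ratios so the calibrator maps to exactly 1."""
    if calibrator_id not in ratios:
        raise KeyError(f"calibrator {calibrator_id!r} absent")
    base = ratios[calibrator_id]
    if not base > 0:
        raise ValueError(f"calibrator {calibrator_id!r} ratio must be > 0")
    return [
        RelativeExpression(target=k, sample=k, ratio=v / base, calibrator=calibrator_id)
        for k, v in ratios.items()
    ]


def fold_change_table(
    measurements: pd.DataFrame,
    reference_gene: str,
    control_sample: str,
    efficiency_corrected: bool = True,
) -> pd.DataFrame:
    """Per-sample, per-target fold changes from a tidy measurement table.

    Expects columns (sample, target, ct, efficiency[, replicate]); replicates
    are averaged on the Ct scale first.
    """
    req = {"sample", "target", "ct", "efficiency"}
    if not req <= set(measurements.columns):
        raise ValueError(f"measurement table needs columns {sorted(req)}")
    df = measurements.copy()
    df["efficiency"] = df["efficiency"].map(parse_efficiency)
    avg = (
        df.groupby(["sample", "target"], as_index=False)
        .agg(ct=("ct", "mean"), efficiency=("efficiency", "mean"))
    )

    def bundle(sample: str) -> dict[str, QpcrMeasurement]:
        sub = avg[avg["sample"] == sample]
        return {
            r.target: QpcrMeasurement(r.target, sample, r.ct, r.efficiency)
            for r in sub.itertuples()
        }

    control = bundle(control_sample)
    rows = []
    for sample in avg["sample"].unique():
        cond = bundle(sample)
        for target in cond:
            if target == reference_gene:
                continue
            fc = fold_change_ddct(
                cond, control, reference_gene, target_gene=target,
                efficiency_corrected=efficiency_corrected,
            )
            rows.append({"sample": sample, "target": target, "fold_change": fc})
    return pd.DataFrame(rows, columns=["sample", "target", "fold_change"])


def replicate_ttest(fold_changes_a, fold_changes_b) -> tuple[float, float]:
    """Two-tailed unpaired t-test on replicate fold changes (routine support)."""
    t, p = stats.ttest_ind(
        np.asarray(fold_changes_a, float), np.asarray(fold_changes_b, float)
    )
    return float(t), float(p)
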