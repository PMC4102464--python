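"""qRT-PCR comparison arithmetic and genome-size utilities.

Linearized delta-CT expression, delta-delta-CT standardization against a
calibrator sample, log-log OLS regression with named exclusions, and the
picogram-to-base-pair genome size conversion (1 pg diploid DNA = 978 Mbp).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PG_TO_BP = 978e6  # base pairs per picogram of diploid nuclear DNA


@dataclass(frozen=True)
class QPCRRecord:
    sample_id: str
    gene: str
    ct_target: float
    ct_control: float
    efficiency: float

    def __post_init__(self) -> None:
        if self.ct_target <= 0 or self.ct_control <= 0:
            raise ValueError("CT values must be positive")
        if not 0 < self.efficiency < 1.5:
            raise ValueError("amplification efficiency out of range")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    f_stat: float
    p: float
    n: int
    excluded: tuple[str, ...] = ()


def linearize_qpcr(delta_ct: float, efficiency: float) -> float:
    """(1 + E)^dCT: CT differences on a linear expression scale."""
    if efficiency <= -1:
        raise ValueError("efficiency must exceed -1")
    return (1.0 + efficiency) ** delta_ct


def ddct_standardize(
    records: Iterable[QPCRRecord], calibrator: str
) -> dict[tuple[str, str], float]:
    """Relative expression per (sample, gene) by the delta-delta-CT method.

    dCT = CT_control - CT_target (higher expression -> larger value);
    ddCT = dCT_sample - dCT_calibrator; relative expression = (1+E)^ddCT.
    The calibrator sample's value is 1 for every gene.
    """
    recs = list(records)
    by_gene: dict[str, list[QPCRRecord]] = {}
    for r in recs:
        by_gene.setdefault(r.gene, []).append(r)
    out: dict[tuple[str, str], float] = {}
    for gene, rows in by_gene.items():
        cal = [r for r in rows if r.sample_id == calibrator]
        if not cal:
            raise ValueError(f"calibrator {calibrator!r} missing for gene {gene}")
        dct_cal = cal[0].ct_control - cal[0].ct_target
        for r in rows:
            ddct = (r.ct_control - r.ct_target) - dct_cal
            out[(r.sample_id, gene)] = linearize_qpcr(ddct, r.efficiency)
    return out


def regress_loglog(
    x: Sequence[float],
    y: Sequence[float],
    labels: Sequence[str] | None = None,
    exclusions: Iterable[str] = (),
    log_transform: bool = True,
) -> RegressionResult:
    """OLS of log10(y) on log10(x) after removing labelled exclusions.

    With ``log_transform=False`` the fit is on the raw scale (used for the
    outlier-excluded fold-change regression).  F = (r2/(1-r2)) * (n-2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if labels is None:
        labels = [str(i) for i in range(len(x))]
    excluded = tuple(e for e in exclusions if e in labels)
    keep = [i for i, lab in enumerate(labels) if lab not in set(excluded)]
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 points after exclusions")
    if log_transform:
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("log-log regression requires positive values")
        x, y = np.log10(x), np.log10(y)
    fit = stats.linregress(x, y)
    r2 = fit.rvalue**2
    n = len(x)
    f_stat = math.inf if r2 >= 1.0 else (r2 / (1.0 - r2)) * (n - 2)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(r2),
        f_stat=float(f_stat),
        p=float(fit.pvalue),
        n=n,
        excluded=excluded,
    )


def pg_to_haploid_bp(two_c_pg: float) -> float:
    """Haploid genome length in bp from a 2C mass in pg."""
    if two_c_pg <= 0:
        raise ValueError("2C mass must be positive")
    return (two_c_pg / 2.0) * PG_TO_BP


def mean_se(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and standard error (n-1 denominator SD / sqrt(n))."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    return float(v.mean()), float(v.std(ddof=1) / math.sqrt(v.size))


def read_qpcr_table(path) -> list[QPCRRecord]:
    """Load a qPCR TSV (sample, gene, ct_target, ct_control, efficiency)."""
    df = pd.read_csv(path, sep="\t")
    return [
        QPCRRecord(
            str(r["sample"]), str(r["gene"]),
            float(r["ct_target"]), float(r["ct_control"]), float(r["efficiency"]),
        )
        for _, r in df.iterrows()
    ]
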