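"""RPKM quantification and relative-difference differential calling.

Unique-read counts become RPKM values; genes with fewer than 10 reads in any
sample are removed; per-population purple-vs-white relative differences
RD = (P - W) / max(P, W) are combined across two populations into a mean RD
and a consistency statistic (RD_pop1 - RD_pop2); genes pass as differentially
expressed when |mean RD| exceeds 0.5 with |consistency| under 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_MIN_READS = 10
DEFAULT_RD_CUTOFF = 0.5
DEFAULT_CONSISTENCY_CUTOFF = 0.25

#: sample layout: (purple, white) per population
POPULATION_PAIRS = {"pop1": ("pop1_p", "pop1_w"), "pop2": ("pop2_p", "pop2_w")}


@dataclass(frozen=True)
class Thresholds:
    rd_cutoff: float = DEFAULT_RD_CUTOFF
    consistency_cutoff: float = DEFAULT_CONSISTENCY_CUTOFF
    min_reads: int = DEFAULT_MIN_READS

    def __post_init__(self) -> None:
        if self.rd_cutoff <= 0 or self.consistency_cutoff <= 0 or self.min_reads <= 0:
            raise ValueError("thresholds must be positive")


def rpkm(count: float, gene_length_bp: float, total_unique_mapped: float) -> float:
    """Reads per kilobase of (non-n) gene length per million unique reads."""
    if gene_length_bp <= 0:
        raise ValueError("gene length must be positive")
    if total_unique_mapped <= 0:
        raise ValueError("total unique mapped reads must be positive")
    return count / ((gene_length_bp / 1000.0) * (total_unique_mapped / 1e6))


def rpkm_matrix(counts: pd.DataFrame, lengths: Mapping[str, float]) -> pd.DataFrame:
    """RPKM for a genes x samples count matrix.

    Per-sample totals are the column sums of ``counts`` (unique reads only);
    ``lengths`` are non-n consensus lengths in bp.
    """
    totals = counts.sum(axis=0)
    lens = pd.Series({g: lengths[g] for g in counts.index}, dtype=float)
    if (lens <= 0).any():
        raise ValueError("all gene lengths must be positive")
    if (totals <= 0).any():
        raise ValueError("every sample needs at least one unique read")
    return counts.div(lens / 1000.0, axis=0).div(totals / 1e6, axis=1)


def low_count_filter(counts: pd.DataFrame, min_reads: int = DEFAULT_MIN_READS) -> pd.Index:
    """Genes with at least ``min_reads`` unique reads in every sample."""
    return counts.index[(counts >= min_reads).all(axis=1)]


def relative_difference(p: float, w: float) -> float:
    """RD = (P - W) / max(P, W); in [-1, 1], positive iff P > W."""
    m = max(p, w)
    if m <= 0:
        raise ValueError("RD undefined when both values are zero")
    return (p - w) / m


def consistency(rd_pop1: float, rd_pop2: float) -> float:
    """Signed difference of the two population RDs."""
    return rd_pop1 - rd_pop2


def classify_differential(
    rpkms: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
    population_pairs: Mapping[str, tuple[str, str]] = POPULATION_PAIRS,
) -> pd.DataFrame:
    """Per-gene differential table from a genes x samples RPKM matrix.

    Columns: rd_<pop> for each population, consistency, mean_rd, fold-change
    purple/white per population, and a class in {P>W, W>P, not_DE,
    inconsistent}.  Input genes must already have passed the low-count
    filter (RD is undefined at 0/0).
    """
    pops = list(population_pairs)
    if len(pops) != 2:
        raise ValueError("exactly two population pairs expected")
    out = pd.DataFrame(index=rpkms.index)
    for pop, (p_col, w_col) in population_pairs.items():
        p, w = rpkms[p_col], rpkms[w_col]
        out[f"rd_{pop}"] = [relative_difference(a, b) for a, b in zip(p, w)]
        out[f"fold_{pop}"] = p / w.replace(0, np.nan)
    rd1, rd2 = out[f"rd_{pops[0]}"], out[f"rd_{pops[1]}"]
    out["consistency"] = rd1 - rd2
    out["mean_rd"] = (rd1 + rd2) / 2.0
    consistent = out["consistency"].abs() < thresholds.consistency_cutoff
    cls = np.where(
        (out["mean_rd"] > thresholds.rd_cutoff) & consistent, "P>W",
        np.where(
            (out["mean_rd"] < -thresholds.rd_cutoff) & consistent, "W>P",
            np.where(out["mean_rd"].abs() > thresholds.rd_cutoff, "inconsistent",
                     "not_DE"),
        ),
    )
    out["class"] = cls
    return out


def fold_change_profile(
    depth_p: Sequence[float],
    depth_w: Sequence[float],
    window: int = 1,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-position purple/white depth ratio with a gene-average annotation.

    Depths are averaged in non-overlapping windows; the ratio uses a
    pseudocount guard so zero white depth stays finite.  The ``gene_average``
    column repeats the ratio of whole-gene mean depths.
    """
    dp = np.asarray(depth_p, dtype=float)
    dw = np.asarray(depth_w, dtype=float)
    if dp.shape != dw.shape:
        raise ValueError("depth vectors must have equal length")
    if window < 1:
        raise ValueError("window must be >= 1")
    n_win = len(dp) // window
    if n_win == 0:
        raise ValueError("depth vectors shorter than one window")
    wp = dp[: n_win * window].reshape(n_win, window).mean(axis=1)
    ww = dw[: n_win * window].reshape(n_win, window).mean(axis=1)
    ratio = (wp + pseudocount) / (ww + pseudocount)
    gene_avg = (dp.mean() + pseudocount) / (dw.mean() + pseudocount)
    return pd.DataFrame(
        {
            "position": np.arange(n_win) * window,
            "depth_p": wp,
            "depth_w": ww,
            "ratio": ratio,
            "gene_average": gene_avg,
        }
    )


def expression_table(counts: pd.DataFrame, rpkms: pd.DataFrame) -> pd.DataFrame:
    """Long-format (gene, sample, count, rpkm) report table."""
    long_counts = counts.stack().rename("count")
    long_rpkm = rpkms.stack().rename("rpkm")
    out = pd.concat([long_counts, long_rpkm], axis=1).reset_index()
    out.columns = ["gene_id", "sample", "count", "rpkm"]
    return out
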