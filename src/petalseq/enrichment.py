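"""Top-fraction study-set selection and hypergeometric GO term enrichment.

Study sets are the top 2% of consistently differential genes per direction;
the null (population) set is every filtered gene outside the study sets.
Terms are tested with the exact hypergeometric tail and Benjamini-Hochberg
adjusted, reported at q < 0.01 (significant) and q < 0.05 (marginal) tiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from ._util import round_half_up

DEFAULT_TOP_FRACTION = 0.02
TIER_SIGNIFICANT = 0.01
TIER_MARGINAL = 0.05


@dataclass(frozen=True)
class StudySet:
    direction: str  # "P>W" or "W>P"
    genes: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.genes)


def study_set_size(eligible_count: int, fraction: float = DEFAULT_TOP_FRACTION) -> int:
    """round(fraction x eligible), with half-up ties."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    return int(round_half_up(fraction * eligible_count))


def select_top_fraction(
    differential: pd.DataFrame,
    direction: str,
    fraction: float = DEFAULT_TOP_FRACTION,
    consistency_cutoff: float = 0.25,
) -> StudySet:
    """Top-``fraction`` genes by mean RD among the consistency-eligible set.

    Ranking is by mean RD, descending for P>W and ascending for W>P, with a
    deterministic lexicographic tie-break on gene id.
    """
    if direction not in ("P>W", "W>P"):
        raise ValueError("direction must be 'P>W' or 'W>P'")
    eligible = differential[differential["consistency"].abs() < consistency_cutoff]
    if eligible.empty:
        raise ValueError("no genes within the consistency cutoff")
    n = study_set_size(len(eligible), fraction)
    sign = -1.0 if direction == "P>W" else 1.0
    order = sorted(eligible.index, key=lambda g: (sign * eligible.at[g, "mean_rd"], g))
    return StudySet(direction, tuple(order[:n]))


def build_null_set(
    filtered_genes: Iterable[str], study_sets: Sequence[StudySet]
) -> set[str]:
    """Filtered genes minus all study-set genes; study sets must not overlap."""
    study: set[str] = set()
    for s in study_sets:
        overlap = study & set(s.genes)
        if overlap:
            raise ValueError(f"study sets overlap: {sorted(overlap)[:5]}")
        study |= set(s.genes)
    return set(filtered_genes) - study


def hypergeom_test(k: int, n: int, K: int, N: int, side: str = "enrichment") -> float:
    """Exact hypergeometric tail probability.

    Enrichment: P(X >= k); depletion: P(X <= k), for X ~ Hypergeometric(N
    population, K annotated, n drawn).
    """
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise ValueError(f"inconsistent counts k={k} n={n} K={K} N={N}")
    if side == "enrichment":
        return float(hypergeom.sf(k - 1, N, K, n))
    if side == "depletion":
        return float(hypergeom.cdf(k, N, K, n))
    raise ValueError("side must be 'enrichment' or 'depletion'")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_enrichment(
    study: StudySet,
    null_set: Iterable[str],
    annotations: pd.DataFrame,
    side: str = "enrichment",
    min_population_count: int = 2,
) -> pd.DataFrame:
    """Term-by-term hypergeometric test of a study set against study + null.

    Genes without any annotation are excluded from both study and population;
    terms annotated to fewer than ``min_population_count`` population genes
    are not tested.  Returns a table with raw p, BH q, and a tier column.
    """
    annotated = set(annotations["gene_id"])
    study_genes = [g for g in study.genes if g in annotated]
    population = (set(study_genes) | (set(null_set) & annotated))
    ann = annotations[annotations["gene_id"].isin(population)]
    by_term = ann.groupby("term_id")["gene_id"].apply(set)
    N, n = len(population), len(study_genes)
    study_set = set(study_genes)
    rows = []
    for term, genes in by_term.items():
        K = len(genes)
        if K < min_population_count:
            continue
        k = len(genes & study_set)
        p = hypergeom_test(k, n, K, N, side)
        rows.append((term, k, n, K, N, p))
    out = pd.DataFrame(rows, columns=["term_id", "k", "n", "K", "N", "p"])
    if out.empty:
        out["q"] = []
        out["tier"] = []
        out["direction"] = []
        return out
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["tier"] = np.where(
        out["q"] < TIER_SIGNIFICANT, "significant",
        np.where(out["q"] < TIER_MARGINAL, "marginal", "ns"),
    )
    out["direction"] = study.direction
    return out.sort_values(["q", "term_id"]).reset_index(drop=True)
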