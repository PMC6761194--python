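"""Cohort-level quantification and WT/KO comparison.

Per-sample density tables (rows keyed by sample, layer, query and size
class) are combined into cohort summaries: group means, percent differences
and two-tailed unpaired t-tests per cell, astrocyte-association fractions
(tripartite density over the matching bipartite density), the excitation/
inhibition ratio, and conversions between embedded-tissue and
unprocessed-tissue densities via the linear shrinkage factor.

The t-test is Student's pooled-variance test by default — appropriate for
the very small group sizes typical of these experiments (3–4 animals per
genotype) — with Welch's variant selectable.  Raw p-values are reported
per cell without multiple-testing correction by default; Benjamini–Hochberg
adjustment is available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("synquery")

DENSITY_KEY = ["sample", "layer", "query", "size_class"]


def make_density_table(rows: Sequence[dict]) -> pd.DataFrame:
    """Tidy density table: one row per (sample, layer, query, size_class)."""
    frame = pd.DataFrame(rows, columns=[*DENSITY_KEY, "density"])
    if (frame["density"] < 0).any():
        raise ValueError("densities must be >= 0")
    return frame


# ---------------------------------------------------------------------------
# Scalar derived quantities
# ---------------------------------------------------------------------------

def astro_association_fraction(density_tripartite: float,
                               density_bipartite: float) -> float | None:
    """Fraction of synapses adjacent to an astrocytic process.

    Ratio of the tripartite (astrocyte-requiring) density to the matching
    bipartite density from the same sample, layer and synapse type.  A zero
    bipartite density leaves the fraction undefined (None); values above 1
    — possible only through detection noise — are clipped with a warning.
    """
    if density_bipartite <= 0:
        return None
    frac = density_tripartite / density_bipartite
    if frac > 1:
        logger.warning("association fraction %.3f > 1; clipping", frac)
        frac = 1.0
    return frac


def excitation_inhibition_ratio(excitatory_density: float,
                                inhibitory_density: float) -> float | None:
    """E/I ratio: glutamatergic over GABAergic synapse density."""
    if inhibitory_density <= 0:
        return None
    return excitatory_density / inhibitory_density


def shrinkage_volumetric(linear_fraction: float) -> float:
    """Volumetric shrinkage v = 1 − (1 − l)³ from linear shrinkage l."""
    if not 0 <= linear_fraction < 1:
        raise ValueError("linear shrinkage fraction must lie in [0, 1)")
    return 1.0 - (1.0 - linear_fraction) ** 3


def density_to_unprocessed(density_embedded: float,
                           linear_fraction: float) -> float:
    """Convert a per-µm³ density in embedded (shrunken) tissue to unprocessed.

    Dehydration and resin embedding shrink each linear dimension by l, so a
    unit volume of embedded tissue corresponds to 1/(1−l)³ of unprocessed
    tissue and the density deflates by (1−l)³.
    """
    if density_embedded < 0:
        raise ValueError("density must be >= 0")
    if not 0 <= linear_fraction < 1:
        raise ValueError("linear shrinkage fraction must lie in [0, 1)")
    return density_embedded * (1.0 - linear_fraction) ** 3


def percent_difference(wt_mean: float, ko_mean: float) -> float | None:
    """Percent change of KO relative to WT: 100 · (ko − wt) / wt."""
    if wt_mean == 0:
        return None
    return 100.0 * (ko_mean - wt_mean) / wt_mean


def unpaired_ttest(group_a: Sequence[float], group_b: Sequence[float],
                   welch: bool = False) -> tuple[float, float]:
    """Two-tailed unpaired t-test; Student's pooled-variance by default.

    Degenerate inputs (zero pooled variance) give p = 1 for equal means and
    p = 0 otherwise.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two samples")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") * np.sign(a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Cohort comparison
# ---------------------------------------------------------------------------

@dataclass
class CohortResult:
    """Cell-by-cell WT/KO comparison plus the retained per-sample data."""

    summary: pd.DataFrame          # one row per (layer, query, size_class)
    per_sample: pd.DataFrame       # the input table with group labels
    groups: dict[str, str] = field(default_factory=dict)


def compare_cohorts(density_table: pd.DataFrame, groups: dict[str, str],
                    group_a: str = "WT", group_b: str = "KO",
                    welch: bool = False, bh_correct: bool = False) -> CohortResult:
    """Compare two cohorts cell by cell.

    ``density_table`` is tidy per make_density_table; ``groups`` maps sample
    ids to group labels.  For every (layer, query, size_class) cell present
    in both groups the summary holds group means and SDs, the percent
    difference (B relative to A), the two-tailed t statistic and p-value,
    and the group sizes.  Cells missing a group, or with fewer than two
    samples on either side, are reported with NaN statistics rather than
    imputed.  Output row order is deterministic and independent of the
    input's sample ordering.
    """
    tbl = density_table.copy()
    unknown = set(tbl["sample"]) - set(groups)
    if unknown:
        raise ValueError(f"samples without a group label: {sorted(unknown)}")
    tbl["group"] = tbl["sample"].map(groups)
    n_a = tbl.loc[tbl["group"] == group_a, "sample"].nunique()
    n_b = tbl.loc[tbl["group"] == group_b, "sample"].nunique()
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least two samples")

    rows = []
    for (layer, query, size_class), cell in tbl.groupby(
            ["layer", "query", "size_class"], sort=True):
        va = cell.loc[cell["group"] == group_a, "density"].to_numpy()
        vb = cell.loc[cell["group"] == group_b, "density"].to_numpy()
        rec = {"layer": layer, "query": query, "size_class": size_class,
               f"mean_{group_a.lower()}": va.mean() if len(va) else np.nan,
               f"mean_{group_b.lower()}": vb.mean() if len(vb) else np.nan,
               f"sd_{group_a.lower()}": va.std(ddof=1) if len(va) > 1 else np.nan,
               f"sd_{group_b.lower()}": vb.std(ddof=1) if len(vb) > 1 else np.nan,
               f"n_{group_a.lower()}": len(va), f"n_{group_b.lower()}": len(vb),
               "percent_diff": np.nan, "t": np.nan, "p": np.nan}
        if len(va) >= 2 and len(vb) >= 2:
            pd_ = percent_difference(va.mean(), vb.mean())
            rec["percent_diff"] = np.nan if pd_ is None else pd_
            rec["t"], rec["p"] = unpaired_ttest(va, vb, welch=welch)
        rows.append(rec)
    summary = pd.DataFrame(rows)
    if bh_correct and len(summary):
        mask = summary["p"].notna()
        p = summary.loc[mask, "p"].to_numpy()
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(adj)
        out[order] = np.clip(adj, 0, 1)
        summary.loc[mask, "p_adj"] = out
    return CohortResult(summary=summary, per_sample=tbl, groups=dict(groups))
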