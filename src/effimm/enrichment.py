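"""Metagenomic gene-family abundance normalisation and group enrichment.

The pipeline consumes per-sample HMM hit tables for T6SS structural and
toxin/immunity gene families, normalises hit counts per sequencing depth
and per Bacteroidales relative abundance (hits per million Bacteroidales
reads), tests disease-group enrichment per family with the Kruskal-Wallis
rank test under Benjamini-Hochberg FDR control, fits per-group ordinary
least-squares slopes of toxin-family abundance against a structural marker
gene (Ntox15 per TssB), and assesses longitudinal trends through
per-subject slopes.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .synthdata import HitTable, STRUCTURAL_FAMILIES

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "SlopeFit",
    "TrendResult",
    "read_domtblout",
    "read_hit_tsv",
    "normalize_hits",
    "group_enrichment",
    "slope_by_group",
    "longitudinal_trend",
    "aggregate_structural",
]

DEFAULT_BLACKLIST = {"TssH"}  # AAA+ ATPase: prone to off-target HMM hits


@dataclasses.dataclass
class SlopeFit:
    group: str
    slope: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    intercept: Optional[float]
    n: int
    undefined: bool = False


@dataclasses.dataclass
class TrendResult:
    subject_slopes: pd.DataFrame    # columns: subject, group, slope, n_points
    group_tests: pd.DataFrame       # columns: group, n_subjects, statistic, p_value


EnrichmentResult = pd.DataFrame  # per-family rows; see group_enrichment


# ---------------------------------------------------------------------------
# Input
# ---------------------------------------------------------------------------

def read_domtblout(
    path: str | Path,
    family: Optional[str] = None,
    evalue_threshold: float = 1e-5,
) -> int:
    """Count hits in an hmmsearch ``--domtblout`` file.

    One hit per distinct target sequence whose full-sequence E-value passes
    the threshold; multiple domains on one target count once.
    """
    targets: Set[str] = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split()
            if len(fields) < 13:
                raise ValueError(f"{path}: malformed domtblout line: {line[:60]!r}")
            query_name = fields[3]
            if family is not None and query_name != family:
                continue
            full_evalue = float(fields[6])
            if full_evalue <= evalue_threshold:
                targets.add(fields[0])
    return len(targets)


def read_hit_tsv(path: str | Path) -> pd.DataFrame:
    """Read a plain (sample, family, count) TSV into a sample x family matrix."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "family", "count"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    return df.pivot_table(index="sample", columns="family", values="count",
                          aggfunc="sum", fill_value=0)


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

def normalize_hits(table: HitTable, scale: float = 1e6) -> pd.DataFrame:
    """Hits per ``scale`` reads, corrected for Bacteroidales relative abundance.

    ``value = count / (read_total * abundance) * scale``.  Samples with zero
    or missing abundance are dropped with a warning.
    """
    if (table.counts.values < 0).any():
        raise ValueError("negative hit counts")
    ab = table.bact_abundance.reindex(table.counts.index)
    good = ab.notna() & (ab > 0)
    if not good.all():
        dropped = list(table.counts.index[~good])
        logger.warning("dropping %d samples with zero/missing Bacteroidales abundance: %s",
                       len(dropped), dropped[:5])
    counts = table.counts.loc[good]
    denom = table.read_totals.reindex(counts.index) * ab.loc[good]
    return counts.div(denom, axis=0) * scale


def aggregate_structural(
    normalized: pd.DataFrame,
    structural_families: Sequence[str] = tuple(STRUCTURAL_FAMILIES),
    blacklist: Set[str] = frozenset(DEFAULT_BLACKLIST),
) -> pd.Series:
    """Per-sample sum of normalized values over the structural family set."""
    fams = [f for f in structural_families if f in normalized.columns and f not in blacklist]
    if not fams:
        raise ValueError("no structural families present after blacklist")
    return normalized[fams].sum(axis=1)


# ---------------------------------------------------------------------------
# Enrichment testing
# ---------------------------------------------------------------------------

def kruskal_wallis(groups_values: Sequence[np.ndarray]) -> Tuple[float, float]:
    """Kruskal-Wallis H (mid-rank ties, chi-square approximation).

    Returns ``(H, p)``; degenerate all-identical input gives ``(0, 1)``.
    """
    flat = np.concatenate(groups_values)
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    try:
        h, p = scipy.stats.kruskal(*groups_values)
    except ValueError:
        return 0.0, 1.0
    return float(h), float(p)


def group_enrichment(
    normalized: pd.DataFrame,
    groups: pd.Series,
    families: Optional[Sequence[str]] = None,
) -> EnrichmentResult:
    """Per-family Kruskal-Wallis group test with BH FDR over the family set.

    Returns a frame indexed by family with columns ``H, p_value, q_value,
    direction`` plus ``median_<group>`` per group.  ``direction`` is the
    group with the largest median normalized value.
    """
    groups = groups.reindex(normalized.index)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    level_counts = groups.value_counts()
    if (level_counts >= 2).sum() < 2:
        raise ValueError("need at least 2 groups with at least 2 samples each")
    families = list(families) if families is not None else list(normalized.columns)

    levels = sorted(level_counts.index)
    rows = []
    for fam in families:
        vals = [normalized.loc[groups == g, fam].to_numpy() for g in levels]
        h, p = kruskal_wallis(vals)
        medians = {f"median_{g}": float(np.median(v)) for g, v in zip(levels, vals)}
        direction = max(levels, key=lambda g: medians[f"median_{g}"])
        rows.append({"family": fam, "H": h, "p_value": p, "direction": direction, **medians})
    out = pd.DataFrame(rows).set_index("family")
    out["q_value"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    return out


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (exposed for direct use and testing)."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Slopes and trends
# ---------------------------------------------------------------------------

def slope_by_group(
    effector: pd.Series,
    structural: pd.Series,
    groups: pd.Series,
    with_intercept: bool = True,
    alpha: float = 0.05,
) -> List[SlopeFit]:
    """Per-group OLS slope of effector-family abundance on a structural marker.

    95% confidence intervals come from the t-distribution of the slope
    estimate.  A group whose predictor has zero variance yields an
    undefined fit (flagged).
    """
    idx = effector.index.intersection(structural.index).intersection(groups.index)
    fits: List[SlopeFit] = []
    for g in sorted(groups.loc[idx].unique()):
        mask = groups.loc[idx] == g
        x = structural.loc[idx][mask].to_numpy(dtype=float)
        y = effector.loc[idx][mask].to_numpy(dtype=float)
        if len(x) < 3:
            fits.append(SlopeFit(g, None, None, None, None, len(x), undefined=True))
            continue
        if np.ptp(x) == 0:
            fits.append(SlopeFit(g, None, None, None, None, len(x), undefined=True))
            continue
        X = sm.add_constant(x) if with_intercept else x.reshape(-1, 1)
        model = sm.OLS(y, X).fit()
        k = 1 if with_intercept else 0
        ci = model.conf_int(alpha=alpha)
        fits.append(SlopeFit(
            group=g,
            slope=float(model.params[k]),
            ci_low=float(ci[k][0]),
            ci_high=float(ci[k][1]),
            intercept=float(model.params[0]) if with_intercept else 0.0,
            n=len(x),
        ))
    return fits


def longitudinal_trend(
    values: pd.Series,
    subjects: pd.Series,
    weeks: pd.Series,
    groups: pd.Series,
    min_points: int = 3,
) -> TrendResult:
    """Per-subject OLS slope over time, then a per-group signed-rank test vs 0.

    Subjects with fewer than ``min_points`` time points are excluded
    (logged).  The group-level test is the Wilcoxon signed-rank test of the
    subject slopes against zero, a deliberately simple stand-in for a full
    longitudinal mixed model.
    """
    df = pd.DataFrame({"value": values, "subject": subjects, "week": weeks, "group": groups})
    slope_rows = []
    for (subject, group), sub in df.groupby(["subject", "group"]):
        if sub["week"].nunique() < min_points:
            logger.info("subject %s excluded: only %d time points", subject, sub["week"].nunique())
            continue
        slope = float(np.polyfit(sub["week"].to_numpy(dtype=float),
                                 sub["value"].to_numpy(dtype=float), 1)[0])
        slope_rows.append({"subject": subject, "group": group, "slope": slope, "n_points": len(sub)})
    subject_slopes = pd.DataFrame(slope_rows)

    test_rows = []
    for g, sub in subject_slopes.groupby("group"):
        s = sub["slope"].to_numpy()
        if len(s) < 2 or np.allclose(s, 0):
            stat, p = np.nan, 1.0
        else:
            stat, p = scipy.stats.wilcoxon(s)
        test_rows.append({"group": g, "n_subjects": len(s), "statistic": float(stat), "p_value": float(p)})
    return TrendResult(subject_slopes=subject_slopes, group_tests=pd.DataFrame(test_rows))
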