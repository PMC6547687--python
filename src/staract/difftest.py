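"""Differential allelic activity: Mann-Whitney per SNP, BH across SNPs.

For every SNP whose two alleles both carry at least three scored
measurements, the pooled per-measurement scores of the minor allele are
compared with those of the major allele by a two-sided Mann-Whitney U
test; p-values are corrected across all tested SNPs by Benjamini-Hochberg
and called significant at FDR 0.10.  The allelic effect is summarized as
``fold_change = 2**(mean_minor - mean_major)``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .activity import MIN_MEASUREMENTS, aggregate_alleles

DEFAULT_FDR = 0.10
#: largest per-group n at which the exact U null distribution is used
EXACT_MAX_N = 8


def test_snp(
    major_scores: Sequence[float], minor_scores: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U of minor vs. major measurement scores.

    Uses the exact null distribution when both groups have at most
    :data:`EXACT_MAX_N` observations and there are no ties, otherwise the
    normal approximation with tie and continuity corrections.  Returns
    ``(U, p)`` with U the statistic of the minor-allele sample.
    """
    major = np.asarray(major_scores, dtype=float)
    minor = np.asarray(minor_scores, dtype=float)
    if major.size == 0 or minor.size == 0:
        raise ValueError("both score lists must be non-empty")
    pooled = np.concatenate([major, minor])
    has_ties = np.unique(pooled).size < pooled.size
    small = major.size <= EXACT_MAX_N and minor.size <= EXACT_MAX_N
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        minor, major, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def adjust_bh(
    p_values: Sequence[float], fdr: float = DEFAULT_FDR
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: q-values plus significance flags.

    ``q_i = min_{j: p_(j) >= p_(i)} m * p_(j) / j`` clipped to 1; a SNP is
    significant iff ``q <= fdr``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return q, q <= fdr


def differential_table(
    measurements: pd.DataFrame, fdr: float = DEFAULT_FDR
) -> tuple[pd.DataFrame, dict]:
    """Test every SNP scored on both alleles; return the results table.

    Only SNPs whose major and minor alleles each have at least three
    measurements enter testing; the BH family size is the number of SNPs
    tested.  The summary also reports the overall Spearman correlation of
    major vs. minor mean scores across tested SNPs — a global concordance
    check, since most alleles should act alike.
    """
    alleles, _ = aggregate_alleles(measurements)
    wide = alleles.pivot(index="snp_id", columns="allele", values="mean_score")
    if "major" not in wide.columns or "minor" not in wide.columns:
        tested_ids: list[str] = []
    else:
        tested_ids = list(wide.dropna(subset=["major", "minor"]).index)

    by_group = {
        key: grp["score"].to_numpy()
        for key, grp in measurements.groupby(["snp_id", "allele"])
    }
    rows = []
    for snp_id in tested_ids:
        major = by_group[(snp_id, "major")]
        minor = by_group[(snp_id, "minor")]
        u, p = test_snp(major, minor)
        mean_major = float(major.mean())
        mean_minor = float(minor.mean())
        rows.append(
            {
                "snp_id": snp_id,
                "mean_major": mean_major,
                "mean_minor": mean_minor,
                "fold_change": float(2.0 ** (mean_minor - mean_major)),
                "n_major": int(major.size),
                "n_minor": int(minor.size),
                "u_statistic": u,
                "p_raw": p,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "snp_id",
            "mean_major",
            "mean_minor",
            "fold_change",
            "n_major",
            "n_minor",
            "u_statistic",
            "p_raw",
        ],
    )
    if len(table):
        q, sig = adjust_bh(table["p_raw"].to_numpy(), fdr=fdr)
        table["q_bh"] = q
        table["significant"] = sig
        table = table.sort_values(
            ["q_bh", "p_raw", "snp_id"], kind="mergesort"
        ).reset_index(drop=True)
        rho = float(
            stats.spearmanr(table["mean_major"], table["mean_minor"])[0]
        ) if len(table) >= 3 else float("nan")
    else:
        table["q_bh"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
        rho = float("nan")
    summary = {
        "n_tested": int(len(table)),
        "n_significant": int(table["significant"].sum()) if len(table) else 0,
        "fdr": fdr,
        "spearman_major_vs_minor": rho,
    }
    return table, summary
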