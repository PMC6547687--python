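"""Per-barcode activity scores and per-allele averages.

The activity score of one (variant, allele, barcode, replicate)
measurement is

    score = log2( (rna / rna_total) / (dna / dna_total) )

with totals taken over all assigned reads of that replicate's pool, so the
score is invariant to sequencing depth.  A measurement is only scored when
it has at least 10 DNA reads and at least 1 RNA read; an allele is only
reported when at least three measurements (barcode x replicate pairs,
pooled across replicates) survive that filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MIN_DNA_READS = 10
MIN_RNA_READS = 1
MIN_MEASUREMENTS = 3


class ActivityError(ValueError):
    """Missing or unusable pool totals."""


def pool_totals_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate assigned-read totals computed from a count table."""
    totals = (
        counts.groupby("replicate", as_index=False)
        .agg(dna_total=("dna_reads", "sum"), rna_total=("rna_reads", "sum"))
    )
    return totals


def score_measurements(
    counts: pd.DataFrame, totals: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Score every measurement passing the DNA>=10 / RNA>=1 filter.

    ``totals`` must have columns replicate, dna_total, rna_total; when
    omitted they are computed from ``counts`` itself (appropriate when the
    table already holds every assigned read of the experiment).
    """
    if totals is None:
        totals = pool_totals_from_counts(counts)
    totals = totals.set_index("replicate")
    reps_needed = set(counts["replicate"].unique())
    missing = reps_needed - set(totals.index)
    if missing:
        raise ActivityError(f"no pool totals for replicate(s) {sorted(missing)}")
    if ((totals.loc[sorted(reps_needed)] <= 0).any(axis=None)):
        raise ActivityError("pool totals must be positive for every replicate used")

    keep = (counts["dna_reads"] >= MIN_DNA_READS) & (
        counts["rna_reads"] >= MIN_RNA_READS
    )
    meas = counts.loc[keep, ["snp_id", "allele", "barcode", "replicate"]].copy()
    sub = counts.loc[keep]
    dna_tot = totals["dna_total"].reindex(sub["replicate"]).to_numpy(dtype=float)
    rna_tot = totals["rna_total"].reindex(sub["replicate"]).to_numpy(dtype=float)
    rna_prop = sub["rna_reads"].to_numpy(dtype=float) / rna_tot
    dna_prop = sub["dna_reads"].to_numpy(dtype=float) / dna_tot
    meas["score"] = np.log2(rna_prop / dna_prop)
    return meas.reset_index(drop=True)


def aggregate_alleles(
    measurements: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average measurements into per-allele activities.

    Returns ``(alleles, dropped)``: alleles with >= 3 measurements get a
    mean score; under-sampled alleles land in ``dropped`` with their
    measurement count (the bottlenecking losses the screen reports).
    """
    grouped = (
        measurements.groupby(["snp_id", "allele"], as_index=False)
        .agg(n_measurements=("score", "size"), mean_score=("score", "mean"))
    )
    keep = grouped["n_measurements"] >= MIN_MEASUREMENTS
    alleles = grouped.loc[keep].reset_index(drop=True)
    dropped = grouped.loc[~keep].reset_index(drop=True)
    return alleles, dropped


def replicate_concordance(measurements: pd.DataFrame) -> pd.DataFrame:
    """Pairwise replicate correlations of per-replicate mean allele scores.

    For each replicate pair, alleles scored in both replicates contribute
    their within-replicate mean score; pairs sharing fewer than 3 alleles
    are flagged with NaN correlations.
    """
    per_rep = (
        measurements.groupby(["snp_id", "allele", "replicate"])["score"]
        .mean()
        .unstack("replicate")
    )
    reps = list(per_rep.columns)
    rows = []
    for i, r1 in enumerate(reps):
        for r2 in reps[i + 1 :]:
            both = per_rep[[r1, r2]].dropna()
            row = {"replicate_a": r1, "replicate_b": r2, "n_shared": len(both)}
            if len(both) >= 3:
                row["pearson_r"] = float(stats.pearsonr(both[r1], both[r2])[0])
                row["spearman_rho"] = float(stats.spearmanr(both[r1], both[r2])[0])
            else:
                row["pearson_r"] = np.nan
                row["spearman_rho"] = np.nan
            rows.append(row)
    return pd.DataFrame(
        rows, columns=["replicate_a", "replicate_b", "n_shared", "pearson_r", "spearman_rho"]
    )
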