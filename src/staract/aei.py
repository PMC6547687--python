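"""Allelic expression imbalance (AEI) from paired DNA/cDNA allele counts.

A heterozygous sample's two alleles are amplified from genomic DNA and
from cDNA; the DNA allele ratio calibrates amplification bias, so the
imbalance of one replicate is

    fold = (rna_minor / rna_major) / (dna_minor / dna_major)

tested with a two-sided Fisher's exact test on the 2x2 allele-by-pool
table.  The cohort arm averages each patient's minor-allele fraction over
technical replicates within DNA and within RNA, then compares the two
per-patient fraction sets with a two-sided Mann-Whitney U test (exact for
small cohorts); the effect size is the median per-patient fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class AeiError(ValueError):
    """Inconsistent amplicon design or unusable counts."""


@dataclass
class ReplicateAei:
    sample: str
    replicate: str
    fold: float  # NaN when a denominator count is zero
    fisher_p: float
    fold_defined: bool


def classify_amplicon_reads(
    reads, major_amplicon: str, minor_amplicon: str
) -> dict[str, int]:
    """Count perfect major/minor amplicon reads; everything else is discarded.

    The two expected amplicons must be equal-length and differ at exactly
    one base (the SNP).  A read counts for an allele only when it exactly
    equals that amplicon over the amplicon's length; shorter reads and any
    mismatch (an indel shifts every downstream base, so it can never match)
    are discarded.  Returns ``{"major": ..., "minor": ..., "discarded": ...}``.
    """
    major_amplicon = major_amplicon.upper()
    minor_amplicon = minor_amplicon.upper()
    if len(major_amplicon) != len(minor_amplicon):
        raise AeiError("expected amplicons must be the same length")
    diffs = sum(a != b for a, b in zip(major_amplicon, minor_amplicon))
    if diffs != 1:
        raise AeiError(
            f"expected amplicons must differ at exactly the SNP base, found {diffs} differences"
        )
    n = len(major_amplicon)
    out = {"major": 0, "minor": 0, "discarded": 0}
    for read in reads:
        window = read.upper()[:n]
        if len(window) < n:
            out["discarded"] += 1
        elif window == major_amplicon:
            out["major"] += 1
        elif window == minor_amplicon:
            out["minor"] += 1
        else:
            out["discarded"] += 1
    return out


def replicate_aei(
    dna_major: int, dna_minor: int, rna_major: int, rna_minor: int
) -> tuple[float, float]:
    """Fold and two-sided Fisher exact p for one replicate's 2x2 table.

    fold = (rna_minor/rna_major) / (dna_minor/dna_major); NaN when a
    denominator (rna_major or dna_minor... any required count) is zero.
    The test is defined whenever both pools have at least one read.
    """
    counts = (dna_major, dna_minor, rna_major, rna_minor)
    if any(c < 0 for c in counts):
        raise AeiError("counts must be non-negative")
    if dna_major + dna_minor < 1 or rna_major + rna_minor < 1:
        raise AeiError("each pool needs at least one read")
    if min(counts) >= 1:
        fold = (rna_minor / rna_major) / (dna_minor / dna_major)
    else:
        fold = float("nan")
    _, p = stats.fisher_exact(
        [[rna_minor, rna_major], [dna_minor, dna_major]], alternative="two-sided"
    )
    return float(fold), float(p)


def replicate_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`replicate_aei` to every row of an AEI count table."""
    rows = []
    for r in counts.itertuples(index=False):
        fold, p = replicate_aei(r.dna_major, r.dna_minor, r.rna_major, r.rna_minor)
        rows.append(
            {
                "sample": r.sample,
                "replicate": r.replicate,
                "fold": fold,
                "fisher_p": p,
                "fold_defined": bool(np.isfinite(fold)),
            }
        )
    return pd.DataFrame(rows)


def cohort_aei(counts: pd.DataFrame) -> tuple[float, float, pd.DataFrame]:
    """Cohort-level AEI across patients with technical replicates.

    Per patient, the minor-allele fraction in DNA and in RNA is averaged
    over technical replicates; the two per-patient fraction sets are
    compared by a two-sided Mann-Whitney U test (exact null distribution
    for cohorts of <= 9 without ties).  Patients missing a pool entirely
    are excluded.  Returns ``(median_aei, mw_p, per_patient)`` where the
    median AEI is the median over patients of the per-patient fold
    (RNA odds / DNA odds of the averaged fractions).
    """
    rows = []
    for sample, grp in counts.groupby("sample"):
        dna_tot = grp["dna_major"] + grp["dna_minor"]
        rna_tot = grp["rna_major"] + grp["rna_minor"]
        if (dna_tot <= 0).all() or (rna_tot <= 0).all():
            continue  # missing pool: excluded
        ok_dna = dna_tot > 0
        ok_rna = rna_tot > 0
        dna_frac = float((grp.loc[ok_dna, "dna_minor"] / dna_tot[ok_dna]).mean())
        rna_frac = float((grp.loc[ok_rna, "rna_minor"] / rna_tot[ok_rna]).mean())
        if dna_frac in (0.0, 1.0) or rna_frac in (0.0, 1.0):
            fold = float("nan")
        else:
            fold = (rna_frac / (1 - rna_frac)) / (dna_frac / (1 - dna_frac))
        rows.append(
            {
                "sample": sample,
                "dna_minor_fraction": dna_frac,
                "rna_minor_fraction": rna_frac,
                "fold": fold,
            }
        )
    per_patient = pd.DataFrame(rows)
    if len(per_patient) < 2:
        raise AeiError("cohort test needs at least two patients with both pools")
    dna = per_patient["dna_minor_fraction"].to_numpy()
    rna = per_patient["rna_minor_fraction"].to_numpy()
    # exact null for small cohorts, even with ties: deterministic p
    method = "exact" if len(dna) <= 9 else "asymptotic"
    _, p = stats.mannwhitneyu(
        rna, dna, alternative="two-sided", method=method, use_continuity=True
    )
    median_aei = float(np.nanmedian(per_patient["fold"]))
    return median_aei, float(p), per_patient
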