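"""Activity-quintile enrichment of tested regions in peak sets.

Major-allele regions with measured activity are ranked into quintiles by
mean score (quintile 5 = most active) and overlapped with peak BED files
(H3K27ac, ATAC-seq, ...).  Enrichment of the top quintile against the
remaining regions — and the headline top-vs-bottom-quintile contrast — is
tested with a Pearson chi-square on the 2x2 contingency table, without
continuity correction, Bonferroni-corrected across the datasets supplied
in the run.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pyranges as pr
from scipy import stats

N_QUINTILES = 5


class BedParseError(ValueError):
    """Malformed BED input; message carries the offending line number."""


@dataclass
class EnrichmentResult:
    """One 2x2 enrichment contrast: (a, b) overlap/no in group 1, (c, d) in group 2."""

    dataset: str
    a: int
    b: int
    c: int
    d: int
    fold: float
    chi2: float
    p_raw: float
    p_bonferroni: float
    unreliable: bool = False  # some expected cell < 1

    def as_dict(self) -> dict:
        return {
            "dataset": self.dataset,
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "d": self.d,
            "fold": self.fold,
            "chi2": self.chi2,
            "p_raw": self.p_raw,
            "p_bonferroni": self.p_bonferroni,
            "unreliable": self.unreliable,
        }


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file (extra columns ignored), validating as we go."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: fewer than 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            if start < 0 or end <= start:
                raise BedParseError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})"
                )
            rows.append({"Chromosome": fields[0], "Start": start, "End": end})
    return pd.DataFrame(rows, columns=["Chromosome", "Start", "End"])


def assign_quintiles(regions: pd.DataFrame) -> pd.DataFrame:
    """Rank regions into quintiles by mean score (5 = highest-scoring).

    ``regions`` needs columns snp_id and mean_score (chrom/start/end are
    carried through when present).  Ties are broken by snp_id so the
    partition is deterministic.  Quintile sizes follow a ceil/floor split
    with the remainder going to the highest quintiles first: n = 1,254
    yields sizes 251/251/251/251/250 from the top down.
    """
    n = len(regions)
    if n < N_QUINTILES:
        raise ValueError(f"need at least {N_QUINTILES} regions, got {n}")
    out = regions.sort_values(
        ["mean_score", "snp_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    base, rem = divmod(n, N_QUINTILES)
    sizes = [base + 1 if i < rem else base for i in range(N_QUINTILES)]  # top first
    labels = np.concatenate(
        [np.full(size, N_QUINTILES - i) for i, size in enumerate(sizes)]
    )
    out["quintile"] = labels
    return out


def overlap_flags(
    regions: pd.DataFrame, peak_sets: Mapping[str, pd.DataFrame | str | Path]
) -> pd.DataFrame:
    """Flag, per region and peak dataset, any >=1 bp overlap.

    ``regions`` needs snp_id, chrom, start, end (0-based half-open).
    ``peak_sets`` maps dataset name to a BED path or a frame with
    Chromosome/Start/End columns.  Returns a boolean frame indexed by
    snp_id with one column per dataset plus an ``any`` union column.
    """
    reg_pr = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": regions["chrom"],
                "Start": regions["start"],
                "End": regions["end"],
                "snp_id": regions["snp_id"],
            }
        )
    )
    flags = pd.DataFrame(index=pd.Index(regions["snp_id"], name="snp_id"))
    for name, peaks in peak_sets.items():
        if isinstance(peaks, (str, Path)):
            peaks = read_bed(peaks)
        if len(peaks) == 0:
            flags[name] = False
            continue
        peaks_pr = pr.PyRanges(peaks[["Chromosome", "Start", "End"]])
        hit = reg_pr.overlap(peaks_pr)
        hit_ids = set(hit.df["snp_id"]) if len(hit) else set()
        flags[name] = [s in hit_ids for s in flags.index]
    flags["any"] = flags.any(axis=1) if len(flags.columns) else False
    return flags


def contingency(a: int, b: int, c: int, d: int, dataset: str = "",
                n_datasets: int = 1) -> EnrichmentResult:
    """Fold and Pearson chi-square (no continuity correction) for a 2x2 table."""
    table = np.array([[a, b], [c, d]], dtype=float)
    rate1 = a / (a + b) if (a + b) else np.nan
    rate2 = c / (c + d) if (c + d) else np.nan
    fold = rate1 / rate2 if rate2 else np.inf
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (
        table.sum(axis=1) == 0
    ).any():
        chi2, p, expected = 0.0, 1.0, table
    else:
        chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    return EnrichmentResult(
        dataset=dataset,
        a=a, b=b, c=c, d=d,
        fold=float(fold),
        chi2=float(chi2),
        p_raw=float(p),
        p_bonferroni=float(min(1.0, p * n_datasets)),
        unreliable=bool((np.asarray(expected) < 1).any()),
    )


def quintile_vs_rest(
    flags: pd.DataFrame,
    quintiles: pd.DataFrame,
    datasets: Sequence[str] | None = None,
) -> list[EnrichmentResult]:
    """Top quintile vs. all other ranked regions, per peak dataset.

    Bonferroni multiplier = number of datasets tested in this invocation.
    """
    if datasets is None:
        datasets = [c for c in flags.columns if c != "any"]
    top_ids = set(quintiles.loc[quintiles["quintile"] == N_QUINTILES, "snp_id"])
    ranked_ids = set(quintiles["snp_id"])
    in_top = flags.index.isin(top_ids)
    in_rest = flags.index.isin(ranked_ids) & ~in_top
    results = []
    for name in datasets:
        f = flags[name].to_numpy(dtype=bool)
        a = int((f & in_top).sum())
        b = int((~f & in_top).sum())
        c = int((f & in_rest).sum())
        d = int((~f & in_rest).sum())
        results.append(contingency(a, b, c, d, name, n_datasets=len(datasets)))
    return results


def top_vs_bottom(
    flags: pd.DataFrame, quintiles: pd.DataFrame, dataset: str = "any"
) -> EnrichmentResult:
    """The headline contrast: top vs. bottom quintile on the union flag."""
    top_ids = set(quintiles.loc[quintiles["quintile"] == N_QUINTILES, "snp_id"])
    bot_ids = set(quintiles.loc[quintiles["quintile"] == 1, "snp_id"])
    f = flags[dataset]
    in_top = flags.index.isin(top_ids)
    in_bot = flags.index.isin(bot_ids)
    fv = f.to_numpy(dtype=bool)
    a = int((fv & in_top).sum())
    b = int((~fv & in_top).sum())
    c = int((fv & in_bot).sum())
    d = int((~fv & in_bot).sum())
    return contingency(a, b, c, d, f"top_vs_bottom_{dataset}", n_datasets=1)


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])
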