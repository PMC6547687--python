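"""Synthetic data with the statistical structure of a barcoded STARR-seq screen.

The generative model mirrors how the assay is actually built and read out:

* Each allele receives a small set of degenerate 5-nt barcodes during PCR
  (before cloning), so the barcode set is shared across transfection
  replicates while read sampling is independent per replicate.
* Per-barcode DNA abundance is log-normal (cloning/PCR jackpotting), and
  sequencing reads are Poisson draws from the normalized abundance — a
  log-normal-Poisson mixture that reproduces MPRA overdispersion.
* RNA output multiplies DNA abundance by ``2**(activity + noise)``, so a
  truly differential SNP shifts its minor allele by ``effect_log2``.
* Library bottlenecking is modelled as independent per-barcode dropout.

Ground truth (per-SNP activities and differential flags) is returned
alongside every simulated table so recovery tests can score the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import ADAPTOR3, INSERT_LEN, SNP_OFFSET, OligoDesign, SnpRecord

_BASES = np.frombuffer(b"ACGT", dtype="S1")
BARCODE_LEN = 5


class SimulationError(ValueError):
    """Invalid simulation configuration or inconsistent inputs."""


@dataclass
class SimulationConfig:
    """Knobs of the screen simulator.

    Defaults emulate the screened library's regime: three transfection
    replicates, ~5 distinct barcodes per allele with 20% bottleneck dropout
    (which lands near the reported ~79% allele recovery and ~13
    measurements per allele across replicates), a 2.5-fold
    (``effect_log2 = 1.32``) allelic shift at differential SNPs, and 1e6
    reads per pool per replicate.
    """

    n_snps: int = 200
    frac_differential: float = 0.1
    effect_log2: float = 1.32
    activity_sd: float = 1.0
    barcodes_per_allele: float = 5.0
    dna_abundance_logsd: float = 1.0
    rna_noise_sd: float = 0.5
    n_replicates: int = 3
    dna_depth: int = 1_000_000
    rna_depth: int = 1_000_000
    dropout_prob: float = 0.2
    read_error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_differential", "dropout_prob", "read_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must lie in [0, 1], got {v}")
        if self.dna_depth < 0 or self.rna_depth < 0:
            raise SimulationError("read depths must be >= 0")
        if self.n_replicates < 1:
            raise SimulationError("n_replicates must be >= 1")
        if self.n_snps < 0:
            raise SimulationError("n_snps must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def _random_barcodes(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform 5-mers over ACGT; collisions are allowed (degenerate chemistry)."""
    idx = rng.integers(0, 4, size=(n, BARCODE_LEN))
    return _BASES[idx].view(f"S{BARCODE_LEN}").ravel().astype("U5")


def _truncated_poisson(rng: np.random.Generator, mean: float, n: int) -> np.ndarray:
    """Poisson(mean) conditioned on >= 1 (every allele enters the PCR)."""
    k = rng.poisson(mean, size=n)
    while (zero := k == 0).any():
        k[zero] = rng.poisson(mean, size=int(zero.sum()))
    return k


def simulate_truth(config: SimulationConfig) -> pd.DataFrame:
    """Per-SNP ground truth: baseline activity and the allelic shift."""
    rng = np.random.default_rng(config.seed)
    n = config.n_snps
    is_diff = rng.random(n) < config.frac_differential
    a_major = rng.normal(0.0, config.activity_sd, size=n)
    a_minor = a_major + np.where(is_diff, config.effect_log2, 0.0)
    return pd.DataFrame(
        {
            "snp_id": [f"snp{i:05d}" for i in range(n)],
            "a_major": a_major,
            "a_minor": a_minor,
            "is_differential": is_diff,
        }
    )


def simulate_counts(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the per-barcode DNA/RNA count table for a whole screen.

    Returns ``(counts, truth)``.  ``counts`` has one row per
    (snp_id, allele, barcode, replicate) with at least one read in either
    pool; ``truth`` is the table from :func:`simulate_truth` (same seed, so
    the two are always consistent).
    """
    truth = simulate_truth(config)
    rng = np.random.default_rng((config.seed, 1))

    # Build the barcode library once; it is shared by all replicates.
    lib_rows: list[tuple[str, str, float, str]] = []
    for row in truth.itertuples(index=False):
        for allele, activity in (("major", row.a_major), ("minor", row.a_minor)):
            k = int(_truncated_poisson(rng, config.barcodes_per_allele, 1)[0])
            survived = rng.random(k) >= config.dropout_prob
            k_live = int(survived.sum())
            if k_live == 0:
                continue
            barcodes = _random_barcodes(rng, k_live)
            for bc in barcodes:
                lib_rows.append((row.snp_id, allele, activity, bc))

    if not lib_rows:
        empty = pd.DataFrame(
            columns=["snp_id", "allele", "barcode", "replicate", "dna_reads", "rna_reads"]
        )
        return empty, truth

    lib = pd.DataFrame(lib_rows, columns=["snp_id", "allele", "activity", "barcode"])
    lib["lam"] = rng.lognormal(0.0, config.dna_abundance_logsd, size=len(lib))
    # Identical barcodes on the same allele are indistinguishable molecule
    # classes: merge their abundances.
    lib = (
        lib.groupby(["snp_id", "allele", "barcode"], as_index=False)
        .agg(activity=("activity", "first"), lam=("lam", "sum"))
    )

    lam = lib["lam"].to_numpy()
    act = lib["activity"].to_numpy()
    frames = []
    for rep in range(1, config.n_replicates + 1):
        dna = rng.poisson(lam / lam.sum() * config.dna_depth)
        eps = rng.normal(0.0, config.rna_noise_sd, size=len(lib))
        w = lam * np.exp2(act + eps)
        rna = rng.poisson(w / w.sum() * config.rna_depth)
        frames.append(
            pd.DataFrame(
                {
                    "snp_id": lib["snp_id"],
                    "allele": lib["allele"],
                    "barcode": lib["barcode"],
                    "replicate": f"rep{rep}",
                    "dna_reads": dna,
                    "rna_reads": rna,
                }
            )
        )
    counts = pd.concat(frames, ignore_index=True)
    counts = counts[(counts.dna_reads + counts.rna_reads) >= 1].reset_index(drop=True)
    return counts, truth


def _apply_read_errors(
    seqs: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-base substitution errors on an (n_reads, read_len) byte matrix."""
    if rate <= 0 or seqs.size == 0:
        return seqs
    err = rng.random(seqs.shape) < rate
    if err.any():
        lut = np.zeros(256, dtype=np.uint8)
        for i, b in enumerate(b"ACGT"):
            lut[b] = i
        codes = lut[seqs.view(np.uint8)]
        shift = rng.integers(1, 4, size=int(err.sum()))
        codes[err] = (codes[err] + shift) % 4
        seqs = seqs.copy()
        seqs[err] = _BASES[codes[err]]
    return seqs


def simulate_reads(
    counts: pd.DataFrame,
    designs: Sequence[OligoDesign] | Mapping[tuple[str, str], str],
    config: SimulationConfig,
    out_dir: str | Path,
) -> dict[str, dict[str, Path]]:
    """Emit per-replicate DNA and RNA FASTQ files from a count table.

    Each counted read becomes one synthetic single-end read with layout
    ``insert(196) + adaptor3(17) + barcode(5)`` and constant base quality;
    substitution errors are applied per base at ``config.read_error_rate``.
    Returns ``{replicate: {"dna": path, "rna": path}}``.
    """
    if isinstance(designs, Mapping):
        insert_by_allele = dict(designs)
    else:
        insert_by_allele = {(d.snp_id, d.allele_tag): d.insert for d in designs}
    missing = {
        (s, a)
        for s, a in zip(counts["snp_id"], counts["allele"])
        if (s, a) not in insert_by_allele
    }
    if missing:
        raise SimulationError(f"counts reference unknown designs: {sorted(missing)[:5]}")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng((config.seed, 2))
    read_len = INSERT_LEN + len(ADAPTOR3) + BARCODE_LEN
    qual = "I" * read_len
    paths: dict[str, dict[str, Path]] = {}

    for rep, rep_counts in counts.groupby("replicate", sort=True):
        rep_paths: dict[str, Path] = {}
        for pool, col in (("dna", "dna_reads"), ("rna", "rna_reads")):
            path = out_dir / f"{rep}_{pool}.fastq"
            templates = [
                insert_by_allele[(r.snp_id, r.allele)] + ADAPTOR3 + r.barcode
                for r in rep_counts.itertuples(index=False)
            ]
            reps = rep_counts[col].to_numpy()
            order = rng.permutation(int(reps.sum()))
            expanded = np.repeat(
                np.frombuffer("".join(templates).encode(), dtype="S1").reshape(
                    len(templates), read_len
                ),
                reps,
                axis=0,
            )[order]
            expanded = _apply_read_errors(expanded, config.read_error_rate, rng)
            with open(path, "w") as fh:
                for i, row in enumerate(expanded):
                    fh.write(
                        f"@{rep}_{pool}_{i}\n{row.tobytes().decode()}\n+\n{qual}\n"
                    )
            rep_paths[pool] = path
        paths[str(rep)] = rep_paths
    return paths


def simulate_peaks(
    regions: pd.DataFrame,
    slope: float = 1.0,
    intercept: float = 0.0,
    seed: int = 0,
    peak_halfwidth: int = 250,
) -> pd.DataFrame:
    """Simulate a BED peak set whose overlap probability tracks activity.

    ``regions`` needs columns chrom, start, end, activity.  Each region is
    overlapped by one peak with probability
    ``logistic(intercept + slope * activity)``; emitted peaks are centered
    uniformly inside the region so every emitted interval intersects it by
    at least 1 bp.
    """
    rng = np.random.default_rng(seed)
    p = expit(intercept + slope * regions["activity"].to_numpy())
    hit = rng.random(len(regions)) < p
    rows = []
    for (row, h) in zip(regions.itertuples(index=False), hit):
        if not h:
            continue
        center = int(rng.integers(row.start, row.end))
        rows.append(
            {
                "Chromosome": row.chrom,
                "Start": max(0, center - peak_halfwidth),
                "End": center + peak_halfwidth,
            }
        )
    return pd.DataFrame(rows, columns=["Chromosome", "Start", "End"])


def simulate_features(
    n_regions: int,
    n_features: int,
    n_causal: int,
    noise_sd: float = 1.0,
    seed: int = 0,
    frac_skewed: float = 0.3,
) -> tuple[pd.DataFrame, pd.Series, pd.Series, pd.Series]:
    """Sparse-signal feature matrix for exercising the enhancer model.

    Latent features are standard normal; activity is ``y = Z beta + noise``
    with ``n_causal`` nonzero coefficients of magnitude in [0.5, 1.5] and
    random sign.  A ``frac_skewed`` subset of features is emitted
    exponentiated (right-skewed, like ChIP-seq or CAGE signal) to exercise
    the log-transform path of preprocessing.

    Returns ``(X, y, beta, skew_flags)`` with ``beta`` indexed on the
    latent (pre-exponentiation) scale.
    """
    if n_causal > n_features:
        raise SimulationError("n_causal cannot exceed n_features")
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(n_regions, n_features))
    beta = np.zeros(n_features)
    causal = rng.choice(n_features, size=n_causal, replace=False)
    beta[causal] = rng.uniform(0.5, 1.5, size=n_causal) * rng.choice(
        [-1.0, 1.0], size=n_causal
    )
    y = z @ beta + rng.normal(0.0, noise_sd, size=n_regions)
    names = [f"feat{j:04d}" for j in range(n_features)]
    skewed = np.zeros(n_features, dtype=bool)
    skewed[rng.choice(n_features, size=int(round(frac_skewed * n_features)), replace=False)] = True
    x = z.copy()
    x[:, skewed] = np.exp(z[:, skewed])
    regions = [f"region{i:05d}" for i in range(n_regions)]
    return (
        pd.DataFrame(x, index=regions, columns=names),
        pd.Series(y, index=regions, name="activity"),
        pd.Series(beta, index=names, name="beta"),
        pd.Series(skewed, index=names, name="skewed"),
    )


def simulate_aei(
    n_patients: int = 9,
    true_fold: float = 1.3,
    dna_depth: int = 10_000,
    rna_depth: int = 10_000,
    overdispersion: float = 0.01,
    seed: int = 0,
    n_replicates: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired DNA/cDNA allele counts for a heterozygote cohort.

    Per patient the DNA minor-allele fraction is Beta-distributed around
    0.5 (amplification bias); the RNA minor-allele odds are the DNA odds
    times ``true_fold``.  Each of ``n_replicates`` technical replicates
    draws binomial counts at the stated depths, with replicate-level
    fractions jittered by a Beta with sd ``overdispersion``.

    Returns ``(counts, truth)`` where truth holds the per-patient latent
    fractions.
    """
    rng = np.random.default_rng(seed)
    # concentration 200 -> sd(p_dna) ~ 0.035 around 0.5
    p_dna = rng.beta(100.0, 100.0, size=n_patients)
    odds_rna = p_dna / (1 - p_dna) * true_fold
    p_rna = odds_rna / (1 + odds_rna)

    def _rep_fraction(p: float) -> float:
        if overdispersion <= 0:
            return p
        v = overdispersion**2
        cap = p * (1 - p)
        v = min(v, cap * 0.99)
        conc = cap / v - 1.0
        return float(rng.beta(p * conc, (1 - p) * conc))

    rows = []
    for i in range(n_patients):
        for rep in range(1, n_replicates + 1):
            pd_rep = _rep_fraction(p_dna[i])
            pr_rep = _rep_fraction(p_rna[i])
            dna_minor = int(rng.binomial(dna_depth, pd_rep)) if dna_depth else 0
            rna_minor = int(rng.binomial(rna_depth, pr_rep)) if rna_depth else 0
            rows.append(
                {
                    "sample": f"patient{i + 1:02d}",
                    "replicate": f"rep{rep}",
                    "dna_major": dna_depth - dna_minor,
                    "dna_minor": dna_minor,
                    "rna_major": rna_depth - rna_minor,
                    "rna_minor": rna_minor,
                }
            )
    counts = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {
            "sample": [f"patient{i + 1:02d}" for i in range(n_patients)],
            "p_dna": p_dna,
            "p_rna": p_rna,
            "true_fold": true_fold,
        }
    )
    return counts, truth


def random_genome_and_snps(
    n_snps: int,
    seed: int = 0,
    spacing: int = 500,
    chrom: str = "chr1",
) -> tuple[dict[str, str], list[SnpRecord]]:
    """A random reference chromosome with evenly spaced biallelic SNPs.

    The reference carries the major allele at each SNP position; useful for
    end-to-end demos and tests that need a genome consistent with a
    simulated screen.
    """
    rng = np.random.default_rng(seed)
    length = spacing * (n_snps + 1) + INSERT_LEN
    seq = _BASES[rng.integers(0, 4, size=length)].tobytes().decode()
    seq_list = list(seq)
    snps = []
    bases = "ACGT"
    for i in range(n_snps):
        pos = spacing * (i + 1)  # 1-based; windows stay in bounds
        major = seq_list[pos - 1]
        minor = bases[(bases.index(major) + int(rng.integers(1, 4))) % 4]
        snps.append(
            SnpRecord(
                snp_id=f"snp{i:05d}",
                chrom=chrom,
                pos=pos,
                major=major,
                minor=minor,
                lead_group=f"lead{i // 50}",
            )
        )
    return {chrom: "".join(seq_list)}, snps
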