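"""Oligo library design for an allele-resolved STARR-seq screen.

For every candidate SNP the screen synthesizes the 196-nt genomic window
centered on the variant in both allelic states, flanked by the two cloning
adaptors, yielding a 230-nt oligo per allele.  The window is taken off the
plus strand with the variant base at 1-based offset 98 within the insert
(97 nt upstream, 98 nt downstream); genomic coordinates are exported in
0-based half-open BED convention, so an insert spans ``[pos-98, pos+98)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ADAPTOR5 = "TCTAGAGCATGCACCGG"
ADAPTOR3 = "GCCGGTCAGAATGATGG"
INSERT_LEN = 196
OLIGO_LEN = len(ADAPTOR5) + INSERT_LEN + len(ADAPTOR3)  # 230
#: 0-based offset of the variant base within the insert (1-based offset 98).
SNP_OFFSET = 97
_UPSTREAM = SNP_OFFSET          # 97 nt left of the SNP
_DOWNSTREAM = INSERT_LEN - SNP_OFFSET - 1  # 98 nt right of the SNP

_BASES = frozenset("ACGT")


class DesignError(ValueError):
    """Base class for library-design failures."""


class WindowBoundsError(DesignError):
    """The 196-nt window does not fit on the chromosome."""


class AlleleMismatchError(DesignError):
    """The reference base at the SNP position matches neither allele."""


class DuplicateSnpError(DesignError):
    """Two input records share a snp_id."""


@dataclass(frozen=True)
class SnpRecord:
    """A candidate variant: one biallelic SNP tagged with its LD block.

    ``lead_group`` identifies the GWAS lead SNP whose LD block (r^2 > 0.8)
    the variant belongs to; the LD expansion itself happens upstream and is
    not part of this package.
    """

    snp_id: str
    chrom: str
    pos: int  # 1-based genomic coordinate
    major: str
    minor: str
    lead_group: str = ""
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DesignError(f"{self.snp_id}: pos must be >= 1, got {self.pos}")
        for name, base in (("major", self.major), ("minor", self.minor)):
            if base not in _BASES:
                raise DesignError(
                    f"{self.snp_id}: {name} allele must be a single A/C/G/T, got {base!r}"
                )
        if self.major == self.minor:
            raise DesignError(f"{self.snp_id}: major and minor alleles are identical")
        if self.maf is not None and not 0.0 <= self.maf <= 1.0:
            raise DesignError(f"{self.snp_id}: maf must lie in [0, 1]")


@dataclass(frozen=True)
class OligoDesign:
    """One synthesized library member: a 196-nt insert in one allelic state."""

    snp_id: str
    allele_tag: str  # "major" or "minor"
    insert: str
    chrom: str = ""
    start: int = 0  # 0-based half-open genomic span of the insert
    end: int = 0

    @property
    def oligo(self) -> str:
        return ADAPTOR5 + self.insert + ADAPTOR3

    @property
    def name(self) -> str:
        return f"{self.snp_id}_{self.allele_tag}"


def _chrom_seq(genome: Mapping[str, object], chrom: str) -> object:
    try:
        return genome[chrom]
    except KeyError:
        raise DesignError(f"chromosome {chrom!r} not present in the reference") from None


def extract_window(genome: Mapping[str, object], snp: SnpRecord) -> tuple[str, str]:
    """Extract the 196-nt window around ``snp`` in both allelic states.

    ``genome`` is any mapping from chromosome name to a sliceable sequence
    (a plain string, a Bio.Seq, or a pyfaidx record).  Returns the
    ``(major_insert, minor_insert)`` pair; the two strings differ only at
    the SNP offset.
    """
    seq = _chrom_seq(genome, snp.chrom)
    start0 = snp.pos - 1 - _UPSTREAM
    end0 = snp.pos + _DOWNSTREAM
    if start0 < 0 or end0 > len(seq):
        raise WindowBoundsError(
            f"{snp.snp_id}: window [{start0}, {end0}) exceeds {snp.chrom} "
            f"bounds [0, {len(seq)})"
        )
    window = str(seq[start0:end0]).upper()
    ref_base = window[SNP_OFFSET]
    if ref_base not in (snp.major, snp.minor):
        raise AlleleMismatchError(
            f"{snp.snp_id}: reference base {ref_base!r} at {snp.chrom}:{snp.pos} "
            f"matches neither allele ({snp.major}/{snp.minor})"
        )
    major = window[:SNP_OFFSET] + snp.major + window[SNP_OFFSET + 1:]
    minor = window[:SNP_OFFSET] + snp.minor + window[SNP_OFFSET + 1:]
    return major, minor


def build_library(
    snps: Sequence[SnpRecord], genome: Mapping[str, object]
) -> list[OligoDesign]:
    """Design both allelic oligos for every SNP (two designs per variant)."""
    seen: set[str] = set()
    designs: list[OligoDesign] = []
    for snp in snps:
        if snp.snp_id in seen:
            raise DuplicateSnpError(f"duplicate snp_id {snp.snp_id!r}")
        seen.add(snp.snp_id)
        major, minor = extract_window(genome, snp)
        start0 = snp.pos - 1 - _UPSTREAM
        end0 = snp.pos + _DOWNSTREAM
        for tag, insert in (("major", major), ("minor", minor)):
            designs.append(
                OligoDesign(snp.snp_id, tag, insert, snp.chrom, start0, end0)
            )
    return designs


def designs_to_frame(designs: Iterable[OligoDesign]) -> pd.DataFrame:
    rows = [
        {
            "snp_id": d.snp_id,
            "allele": d.allele_tag,
            "chrom": d.chrom,
            "start": d.start,
            "end": d.end,
            "insert": d.insert,
            "oligo": d.oligo,
        }
        for d in designs
    ]
    return pd.DataFrame(rows)


def write_library_fasta(designs: Iterable[OligoDesign], path: str | Path) -> None:
    """Write the insert reference FASTA, one record per (snp_id, allele)."""
    records = [
        SeqRecord(Seq(d.insert), id=d.name, description="") for d in designs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_library_fasta(path: str | Path) -> list[OligoDesign]:
    """Parse an insert reference FASTA written by :func:`write_library_fasta`."""
    designs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        snp_id, _, tag = rec.id.rpartition("_")
        designs.append(OligoDesign(snp_id, tag, str(rec.seq).upper()))
    return designs


def write_design_bed(designs: Iterable[OligoDesign], path: str | Path) -> None:
    """BED file of the major-allele window coordinates (one line per SNP)."""
    with open(path, "w") as fh:
        for d in designs:
            if d.allele_tag != "major":
                continue
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{d.snp_id}\n")


def read_variant_table(path: str | Path) -> list[SnpRecord]:
    """Read a variant TSV (snp_id, chrom, pos, major, minor[, lead_group, maf])."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SnpRecord(
                snp_id=str(row.snp_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                major=str(row.major),
                minor=str(row.minor),
                lead_group=str(getattr(row, "lead_group", "")),
                maf=float(row.maf) if hasattr(row, "maf") else None,
            )
        )
    return records
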