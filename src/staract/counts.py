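"""From raw DNA/RNA reads to a per-replicate barcode count table.

Reads are assigned to library members by exact match of their first 196 nt
against the insert reference — the deterministic equivalent of keeping
only error-free molecules, which is what the activity score needs.  Any
mismatch anywhere in the insert, the downstream adaptor, or the barcode
rejects the read; reject tallies are kept per reason so input reads are
always conserved (assigned + rejected = total).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .design import ADAPTOR3, INSERT_LEN, OligoDesign
from .simlib import BARCODE_LEN

MIN_READ_LEN = INSERT_LEN + len(ADAPTOR3) + BARCODE_LEN  # 218
_BARCODE_START = INSERT_LEN + len(ADAPTOR3)  # 0-based 213
_VALID_BASES = frozenset("ACGT")

#: reject reason codes used in tallies
REJECT_UNASSIGNED = "unassigned_insert"
REJECT_SHORT = "short_read"
REJECT_ADAPTOR = "adaptor_mismatch"
REJECT_BARCODE = "bad_barcode"


class ReferenceError_(ValueError):
    """The insert reference is unusable (e.g. duplicate inserts)."""


class InsertIndex:
    """Exact-match lookup from 196-nt insert sequence to (snp_id, allele)."""

    def __init__(self, designs: Iterable[OligoDesign]):
        self._map: dict[str, tuple[str, str]] = {}
        for d in designs:
            if len(d.insert) != INSERT_LEN:
                raise ReferenceError_(
                    f"{d.name}: insert length {len(d.insert)} != {INSERT_LEN}"
                )
            if d.insert in self._map:
                other = self._map[d.insert]
                raise ReferenceError_(
                    f"duplicate insert shared by {other[0]}_{other[1]} and {d.name}"
                )
            self._map[d.insert] = (d.snp_id, d.allele_tag)

    def __len__(self) -> int:
        return len(self._map)

    def lookup(self, insert: str) -> tuple[str, str] | None:
        return self._map.get(insert)


def assign_read(read: str, index: InsertIndex) -> tuple[str, str] | None:
    """Assign a read by exact match of its first 196 nt; None = reject."""
    if len(read) < INSERT_LEN:
        return None
    return index.lookup(read[:INSERT_LEN])


def extract_barcode(read: str) -> tuple[str | None, str | None]:
    """Pull the 5-nt degenerate barcode off a read.

    Returns ``(barcode, None)`` on success or ``(None, reason)`` on
    rejection.  The 17-nt adaptor directly upstream of the barcode must
    match exactly; any adaptor error implies an error-prone molecule.
    """
    if len(read) < MIN_READ_LEN:
        return None, REJECT_SHORT
    if read[INSERT_LEN:_BARCODE_START] != ADAPTOR3:
        return None, REJECT_ADAPTOR
    barcode = read[_BARCODE_START : _BARCODE_START + BARCODE_LEN]
    if any(b not in _VALID_BASES for b in barcode):
        return None, REJECT_BARCODE
    return barcode, None


@dataclass
class TabulateResult:
    """Count table plus the bookkeeping needed downstream.

    ``totals`` are totals of *assigned* reads per pool (the denominator of
    the activity score); ``rejects`` tallies rejected reads per pool and
    reason; ``input_reads`` is the raw read count per pool.
    """

    counts: pd.DataFrame
    totals: dict[str, int]
    rejects: dict[str, Counter] = field(default_factory=dict)
    input_reads: dict[str, int] = field(default_factory=dict)


def _iter_reads(source: str | Path | Iterable[str]) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            for _title, seq, _qual in FastqGeneralIterator(fh):
                yield seq.upper()
    else:
        for seq in source:
            yield seq.upper()


def tabulate(
    dna_reads: str | Path | Iterable[str],
    rna_reads: str | Path | Iterable[str],
    replicate: str,
    index: InsertIndex,
) -> TabulateResult:
    """Count error-free (variant, allele, barcode) molecules in both pools.

    ``dna_reads`` / ``rna_reads`` are FASTQ paths or iterables of read
    sequences.  Empty inputs give an empty table with zero totals.
    """
    tallies: dict[tuple[str, str, str], list[int]] = {}
    rejects = {"dna": Counter(), "rna": Counter()}
    totals = {"dna": 0, "rna": 0}
    input_reads = {"dna": 0, "rna": 0}

    for pool, col, source in (("dna", 0, dna_reads), ("rna", 1, rna_reads)):
        for seq in _iter_reads(source):
            input_reads[pool] += 1
            hit = assign_read(seq, index)
            if hit is None:
                rejects[pool][REJECT_UNASSIGNED] += 1
                continue
            barcode, reason = extract_barcode(seq)
            if barcode is None:
                rejects[pool][reason] += 1
                continue
            key = (hit[0], hit[1], barcode)
            if key not in tallies:
                tallies[key] = [0, 0]
            tallies[key][col] += 1
            totals[pool] += 1

    rows = [
        {
            "snp_id": snp,
            "allele": allele,
            "barcode": barcode,
            "replicate": replicate,
            "dna_reads": v[0],
            "rna_reads": v[1],
        }
        for (snp, allele, barcode), v in tallies.items()
    ]
    counts = pd.DataFrame(
        rows,
        columns=["snp_id", "allele", "barcode", "replicate", "dna_reads", "rna_reads"],
    )
    if len(counts):
        counts = counts.sort_values(
            ["snp_id", "allele", "barcode"], kind="mergesort"
        ).reset_index(drop=True)
    return TabulateResult(counts, totals, rejects, input_reads)


def tabulate_replicates(
    fastq_by_replicate: Mapping[str, Mapping[str, str | Path]],
    index: InsertIndex,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate several replicates and stack the results.

    ``fastq_by_replicate`` maps replicate id to ``{"dna": path, "rna":
    path}`` (the shape :func:`staract.simlib.simulate_reads` returns).
    Returns ``(counts, totals)`` where totals has one row per replicate
    with assigned-read totals per pool.
    """
    frames = []
    totals_rows = []
    for rep in sorted(fastq_by_replicate):
        paths = fastq_by_replicate[rep]
        res = tabulate(paths["dna"], paths["rna"], rep, index)
        frames.append(res.counts)
        totals_rows.append(
            {
                "replicate": rep,
                "dna_total": res.totals["dna"],
                "rna_total": res.totals["rna"],
            }
        )
    counts = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return counts, pd.DataFrame(totals_rows)
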