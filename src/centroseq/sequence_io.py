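"""Sequence and interval I/O for centromere central-domain analysis.

Reads and writes FASTA (via Biopython) and BED6, extracts sub-regions of
named sequences — including across the origin of circular plasmids such as
centromere-bearing minichromosomes — and locates qPCR/cloning amplicons by
exact in-silico PCR.  Coordinates are 0-based half-open throughout; BED
output follows the same convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Recognition sites of the restriction enzymes used in the study's cloning
#: tails; a 5' tail is trimmed through the last such site found near the 5'
#: end of a primer.
RESTRICTION_SITES = {
    "BamHI": "GGATCC",
    "SalI": "GTCGAC",
    "XhoI": "CTCGAG",
    "BglII": "AGATCT",
    "PstI": "CTGCAG",
}

MIN_PRIMER_LEN = 12


class FastaFormatError(ValueError):
    """Raised when a FASTA file is malformed."""


class EmptyInputError(ValueError):
    """Raised when an input file contains no records."""


class PrimerNotFoundError(ValueError):
    """Raised when a primer has no exact match in the template."""


class OrientationError(ValueError):
    """Raised when primer matches imply a negative-length product."""


class AmpliconMultiplicityWarning(UserWarning):
    """Emitted when several primer-pair placements are possible."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a sequence over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence with explicit topology.

    Topology is a declaration, never inferred from content: a circular
    minichromosome and a linear fragment may carry identical sequence.
    """

    id: str
    sequence: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters: {sorted(bad)}"
            )
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def reverse_complement(self, id: Optional[str] = None) -> "SequenceRecord":
        return SequenceRecord(
            id=id or f"{self.id}_rc",
            sequence=reverse_complement(self.sequence),
            topology=self.topology,
        )


@dataclass(frozen=True)
class Region:
    """A strand-aware interval on a named sequence (0-based, half-open).

    On circular sequences ``start > end`` denotes an origin-spanning
    interval of length ``(end - start) mod L``.
    """

    seq_id: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.start < 0 or self.end < 0:
            raise ValueError("coordinates must be non-negative")

    def length(self, seq_len: Optional[int] = None) -> int:
        if self.start < self.end:
            return self.end - self.start
        if seq_len is None:
            raise ValueError(
                "origin-spanning region needs the sequence length to compute size"
            )
        return (self.end - self.start) % seq_len


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair, optionally carrying 5' cloning tails.

    The study's cloning primers are prefixed with tails ending in a
    restriction site (e.g. ``TACTACGGATCC``); these must be removed before
    genomic matching.  ``tail_policy='trim_5prime_tail'`` with
    ``tail_len=None`` auto-detects the tail as everything through the last
    restriction-site match in the 5' half of the primer; an explicit
    ``tail_len`` trims that many bases.
    """

    forward: str
    reverse: str
    tail_policy: str = "none"
    tail_len: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "forward", self.forward.replace(" ", "").upper())
        object.__setattr__(self, "reverse", self.reverse.replace(" ", "").upper())
        if self.tail_policy not in ("none", "trim_5prime_tail"):
            raise ValueError(f"unknown tail policy {self.tail_policy!r}")
        fw, rv = self.trimmed()
        for name, p in (("forward", fw), ("reverse", rv)):
            if len(p) < MIN_PRIMER_LEN:
                raise ValueError(
                    f"{name} primer shorter than {MIN_PRIMER_LEN} bp after tail trimming"
                )

    @staticmethod
    def _auto_trim(primer: str) -> str:
        # Tails sit at the 5' end and terminate in one (or a stack) of
        # restriction sites; scan the 5' half and cut after the last site.
        half = len(primer) // 2 + 3
        cut = 0
        for site in RESTRICTION_SITES.values():
            pos = 0
            while True:
                idx = primer.find(site, pos, half + len(site))
                if idx < 0:
                    break
                cut = max(cut, idx + len(site))
                pos = idx + 1
        return primer[cut:]

    def trimmed(self) -> tuple[str, str]:
        """Return (forward, reverse) with 5' tails removed per policy."""
        if self.tail_policy == "none":
            return self.forward, self.reverse
        if self.tail_len is not None:
            return self.forward[self.tail_len:], self.reverse[self.tail_len:]
        return self._auto_trim(self.forward), self._auto_trim(self.reverse)


def read_fasta(path: str | Path) -> List[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    Sequences are uppercased.  Topology defaults to linear unless the header
    line contains the token ``circular`` (case-insensitive).
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaFormatError(
                        f"{path}: line {lineno}: expected '>' header, got {line.strip()[:30]!r}"
                    )
                break
        else:
            raise EmptyInputError(f"{path}: no FASTA records found")

    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        desc = entry.description.lower()
        topology = "circular" if "circular" in desc.split() else "linear"
        seq = str(entry.seq).upper()
        if not seq:
            raise FastaFormatError(f"{path}: record {entry.id!r} has empty sequence")
        records.append(SequenceRecord(id=entry.id, sequence=seq, topology=topology))
    if not records:
        raise EmptyInputError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapped at ``width`` columns.

    Circular topology is recorded as a ``circular`` token in the header so
    that a round-trip through read_fasta preserves it.
    """
    bio = []
    for rec in records:
        descr = "circular" if rec.is_circular else ""
        bio.append(_BioSeqRecord(Seq(rec.sequence), id=rec.id, description=descr))
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(bio)


def extract_region(rec: SequenceRecord, region: Region) -> SequenceRecord:
    """Extract a Region from a record; minus strand returns the reverse
    complement, and circular records wrap through the origin."""
    if region.seq_id != rec.id:
        raise ValueError(f"region refers to {region.seq_id!r}, record is {rec.id!r}")
    L = len(rec)
    if rec.is_circular:
        if not (0 <= region.start < L and 0 < region.end <= L):
            raise IndexError(
                f"region [{region.start},{region.end}) outside circular sequence of length {L}"
            )
        if region.start < region.end:
            sub = rec.sequence[region.start:region.end]
        else:
            sub = rec.sequence[region.start:] + rec.sequence[:region.end]
    else:
        if not (0 <= region.start < region.end <= L):
            raise IndexError(
                f"region [{region.start},{region.end}) out of bounds for linear "
                f"sequence {rec.id!r} of length {L}"
            )
        sub = rec.sequence[region.start:region.end]
    if region.strand == "-":
        sub = reverse_complement(sub)
    return SequenceRecord(id=region.label or f"{rec.id}:{region.start}-{region.end}",
                          sequence=sub, topology="linear")


def _find_exact(template: str, query: str, circular: bool, L: int) -> List[int]:
    """All exact-match start positions; alignments touching N never match."""
    if "N" in query:
        return []
    hay = template + (template[: len(query) - 1] if circular else "")
    hits = []
    pos = hay.find(query)
    while pos >= 0:
        if pos < L and "N" not in hay[pos:pos + len(query)]:
            hits.append(pos)
        pos = hay.find(query, pos + 1)
    return hits


def locate_amplicon(rec: SequenceRecord, pair: PrimerPair, label: str = "") -> Region:
    """In-silico PCR: the Region spanned by an exactly matching primer pair.

    The forward primer is matched on the top strand, the reverse primer on
    the bottom strand; the product runs from the forward primer's 5' match
    to the reverse primer's 5' match (PCR-product convention).  With
    multiple placements the shortest product wins and a multiplicity
    warning is emitted.
    """
    fw, rv = pair.trimmed()
    L = len(rec)
    fw_hits = _find_exact(rec.sequence, fw, rec.is_circular, L)
    rv_hits = _find_exact(rec.sequence, reverse_complement(rv), rec.is_circular, L)
    if not fw_hits:
        raise PrimerNotFoundError(f"forward primer {fw!r} not found in {rec.id!r}")
    if not rv_hits:
        raise PrimerNotFoundError(f"reverse primer {rv!r} not found in {rec.id!r}")

    candidates = []
    for f in fw_hits:
        for r in rv_hits:
            end = r + len(rv)
            if rec.is_circular:
                length = (end - f) % L
                if length >= len(fw) + len(rv) or (f == r and len(fw) == len(rv)):
                    candidates.append((length, f, end % L if end > L else end))
            else:
                if end - f >= max(len(fw), len(rv)):
                    candidates.append((end - f, f, end))
    if not candidates:
        raise OrientationError(
            f"primers match {rec.id!r} but imply a negative-length product"
        )
    candidates.sort()
    if len(candidates) > 1:
        warnings.warn(
            f"{len(candidates)} possible amplicons in {rec.id!r}; returning shortest",
            AmpliconMultiplicityWarning,
        )
    _, start, end = candidates[0]
    return Region(seq_id=rec.id, start=start, end=end, strand="+", label=label)


def read_bed(path: str | Path) -> List[Region]:
    """Read BED6 (or BED3/4) intervals as Regions."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            regions.append(Region(
                seq_id=f[0], start=int(f[1]), end=int(f[2]),
                label=f[3] if len(f) > 3 else "",
                strand=f[5] if len(f) > 5 else ".",
            ))
    return regions


def write_bed(regions: Sequence[Region], path: str | Path) -> None:
    """Write Regions as BED6."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.seq_id}\t{r.start}\t{r.end}\t{r.label or '.'}\t0\t{r.strand}\n")


def write_bedgraph(values, path: str | Path, chrom: str, start: int = 0, span: int = 1) -> None:
    """Write a per-base track as bedGraph, merging equal-value runs."""
    with open(path, "w") as fh:
        i = 0
        n = len(values)
        while i < n:
            j = i
            while j + 1 < n and values[j + 1] == values[i]:
                j += 1
            a = start + i * span
            b = start + (j + 1) * span
            fh.write(f"{chrom}\t{a}\t{b}\t{float(values[i]):.6g}\n")
            i = j + 1


def read_bedgraph(path: str | Path, chrom: Optional[str] = None):
    """Read a bedGraph into a per-base numpy array (single chromosome)."""
    import numpy as np

    spans = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            c, a, b, v = line.split("\t")[:4]
            if chrom is not None and c != chrom:
                continue
            spans.append((int(a), int(b), float(v)))
    if not spans:
        raise EmptyInputError(f"{path}: no intervals" + (f" for {chrom}" if chrom else ""))
    length = max(b for _, b, _ in spans)
    track = np.zeros(length)
    for a, b, v in spans:
        track[a:b] = v
    return track
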