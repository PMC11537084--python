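"""Marker extraction: operon/16S/23S/5S sub-regions and in-silico V3-V4 PCR.

Regions are looked up from the generator's annotation sidecar; the V3-V4
amplicon is found by a degenerate-primer search on the extracted 16S
(forward primer on the given strand, reverse primer as its reverse
complement downstream), allowing a Hamming mismatch budget of
``floor(max_mismatch_fraction * primer_length)`` per site.  Length filters:
operons are kept only within 4,000-6,000 bp and amplicons within
430-550 bp; 16S/23S/5S records are kept as annotated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .synthgen import SyntheticGenome

__all__ = [
    "MarkerRecord",
    "PrimerPair",
    "Amplicon",
    "ExtractionLog",
    "DEFAULT_PRIMERS",
    "REGIONS",
    "extract_regions",
    "primer_search",
    "iupac_match_count",
    "write_marker_fasta",
    "read_marker_fasta",
]

REGIONS = ("operon", "16S", "23S", "5S", "V3V4")

OPERON_MIN, OPERON_MAX = 4000, 6000
AMPLICON_MIN, AMPLICON_MAX = 430, 550

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MarkerRecord:
    """One extracted marker sequence."""

    marker_id: str
    genome_id: str
    genus: str
    species: str
    region: str
    copy_index: int
    sequence: str

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if not self.sequence:
            raise ValueError("empty sequence")


@dataclass(frozen=True)
class PrimerPair:
    """A degenerate primer pair with a per-primer mismatch budget."""

    forward: str
    reverse: str
    max_mismatch_fraction: float = 0.10

    def __post_init__(self) -> None:
        for p in (self.forward, self.reverse):
            bad = set(p) - set(IUPAC)
            if bad:
                raise ValueError(f"non-IUPAC codes in primer: {bad}")
        if not 0 <= self.max_mismatch_fraction < 0.5:
            raise ValueError("max_mismatch_fraction outside [0, 0.5)")

    def budget(self, primer: str) -> int:
        return int(self.max_mismatch_fraction * len(primer))


# Standard V3-V4 pair (341F / 805R).
DEFAULT_PRIMERS = PrimerPair("CCTACGGGNGGCWGCAG", "GACTACHVGGGTATCTAATCC")


@dataclass
class Amplicon:
    sequence: str
    start: int  # 0-based, includes the forward primer footprint
    end: int    # half-open, includes the reverse footprint


@dataclass
class ExtractionLog:
    """Counts of records kept/dropped by each filter."""

    region: str
    n_input: int = 0
    n_kept: int = 0
    n_length_filtered: int = 0
    n_no_amplicon: int = 0
    dropped: list[str] = field(default_factory=list)


def _pattern_masks(pattern: str) -> np.ndarray:
    """4-bit encode an IUPAC pattern (bit order A,C,G,T)."""
    bits = {"A": 1, "C": 2, "G": 4, "T": 8}
    return np.array([sum(bits[b] for b in IUPAC[c]) for c in pattern],
                    dtype=np.uint8)


_SEQ_BITS = np.zeros(256, dtype=np.uint8)
for _b, _v in zip(b"ACGT", (1, 2, 4, 8)):
    _SEQ_BITS[_b] = _v


def iupac_match_count(window: str, pattern: str) -> int:
    """Number of positions of ``window`` not matched by the IUPAC pattern."""
    if len(window) != len(pattern):
        raise ValueError("length mismatch")
    w = _SEQ_BITS[np.frombuffer(window.encode(), dtype=np.uint8)]
    return int(((w & _pattern_masks(pattern)) == 0).sum())


def _scan(seq_bits: np.ndarray, masks: np.ndarray, budget: int) -> np.ndarray:
    """All start positions where the pattern matches within ``budget``."""
    L, m = seq_bits.size, masks.size
    if L < m:
        return np.empty(0, dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(seq_bits, m)
    mism = ((windows & masks) == 0).sum(axis=1)
    return np.flatnonzero(mism <= budget)


def primer_search(seq_16s: str, primers: PrimerPair = DEFAULT_PRIMERS,
                  trim_primers: bool = False) -> Amplicon | None:
    """Locate the V3-V4 amplicon in a 16S sequence.

    The forward primer is matched on the given strand; the reverse primer
    is matched as its reverse complement downstream of the forward hit.
    Among candidates the leftmost forward site wins, then the nearest
    reverse site.  The amplicon includes both primer footprints (unless
    ``trim_primers``) and must pass the 430-550 bp filter; ``None`` is
    returned when no passing amplicon exists.
    """
    bits = _SEQ_BITS[np.frombuffer(seq_16s.encode(), dtype=np.uint8)]
    fwd_masks = _pattern_masks(primers.forward)
    rev_site = reverse_complement(primers.reverse)
    rev_masks = _pattern_masks(rev_site)
    fwd_hits = _scan(bits, fwd_masks, primers.budget(primers.forward))
    if fwd_hits.size == 0:
        return None
    rev_hits = _scan(bits, rev_masks, primers.budget(primers.reverse))
    f = int(fwd_hits[0])
    downstream = rev_hits[rev_hits >= f + fwd_masks.size]
    if downstream.size == 0:
        return None
    r = int(downstream[0])
    start, end = f, r + rev_masks.size
    if not AMPLICON_MIN <= end - start <= AMPLICON_MAX:
        return None
    if trim_primers:
        start, end = f + fwd_masks.size, r
    return Amplicon(seq_16s[start:end], start, end)


def extract_regions(
    genomes: Sequence[SyntheticGenome],
    region: str,
    primers: PrimerPair = DEFAULT_PRIMERS,
    trim_primers: bool = False,
) -> tuple[list[MarkerRecord], ExtractionLog]:
    """Extract one MarkerRecord per (genome, copy) that passes the filters.

    ``operon`` records span the 16S start through the 5S end (ITS
    included); ``V3V4`` records come from primer search on each extracted
    16S copy.  Dropped copies are counted in the returned log.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    log = ExtractionLog(region=region)
    records: list[MarkerRecord] = []
    lookup = "16S" if region == "V3V4" else region
    for g in genomes:
        for ann in g.annotations:
            if ann.region != lookup:
                continue
            if ann.start < 0 or ann.end > len(g.sequence):
                raise ValueError(
                    f"annotation out of bounds for {g.genome_id}")
            log.n_input += 1
            seq = g.sequence[ann.start:ann.end]
            if region == "operon":
                if not OPERON_MIN <= len(seq) <= OPERON_MAX:
                    log.n_length_filtered += 1
                    log.dropped.append(f"{g.genome_id}/copy{ann.copy_index}")
                    continue
            elif region == "V3V4":
                amp = primer_search(seq, primers, trim_primers)
                if amp is None:
                    log.n_no_amplicon += 1
                    log.dropped.append(f"{g.genome_id}/copy{ann.copy_index}")
                    continue
                seq = amp.sequence
            records.append(MarkerRecord(
                marker_id=f"{g.genome_id}:{region}:{ann.copy_index}",
                genome_id=g.genome_id, genus=g.genus, species=g.species,
                region=region, copy_index=ann.copy_index, sequence=seq))
            log.n_kept += 1
    return records, log


# ---------------------------------------------------------------------------
# FASTA I/O; headers carry marker metadata as `marker_id|genome|genus|species|copy`


def write_marker_fasta(records: Iterable[MarkerRecord],
                       path: str | Path) -> Path:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = [SeqRecord(Seq(r.sequence),
                     id="|".join([r.marker_id, r.genome_id, r.genus,
                                  r.species, str(r.copy_index)]),
                     description=r.region)
           for r in records]
    SeqIO.write(out, path, "fasta")
    return path


def read_marker_fasta(path: str | Path, region: str) -> list[MarkerRecord]:
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        marker_id, genome_id, genus, species, copy_index = rec.id.split("|")[:5]
        records.append(MarkerRecord(marker_id, genome_id, genus, species,
                                    region, int(copy_index), str(rec.seq)))
    return records
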