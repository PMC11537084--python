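"""Per-position sequencing-error injection.

Built-in profiles mirror published platform error rates: nanopore-class
long reads for the operon (and its 23S/5S sub-regions, which ride on the
same long-read run) and Illumina-class short reads for the 16S and its
V3-V4 amplicon.

Scanning original positions left to right, three independent uniform draws
per position decide deletion, insertion (a uniform random base inserted
before the position), and mismatch, in that order; a deleted base is never
also substituted.  A mismatch replaces the base with one of the three
*other* bases so the realized per-base mismatch rate equals the nominal
rate (``mismatch_includes_self=True`` restores the 4-way draw).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["ErrorProfile", "EditCounts", "builtin_profile", "inject_errors",
           "NANOPORE_PROFILE", "ILLUMINA_PROFILE"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ErrorProfile:
    mismatch_rate: float
    insertion_rate: float
    deletion_rate: float
    label: str = ""

    def __post_init__(self) -> None:
        rates = (self.mismatch_rate, self.insertion_rate, self.deletion_rate)
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("rates must be in [0, 1]")
        if self.mismatch_rate + self.deletion_rate > 1:
            raise ValueError("mismatch + deletion rates exceed 1")


NANOPORE_PROFILE = ErrorProfile(0.0116, 0.0081, 0.0144, "nanopore-1D")
ILLUMINA_PROFILE = ErrorProfile(0.0089, 0.00045, 0.00045, "illumina-paired")

_REGION_PROFILES = {
    "operon": NANOPORE_PROFILE,
    "23S": NANOPORE_PROFILE,
    "5S": NANOPORE_PROFILE,
    "16S": ILLUMINA_PROFILE,
    "V3V4": ILLUMINA_PROFILE,
}


def builtin_profile(region: str) -> ErrorProfile:
    """Error profile for a marker region's sequencing platform."""
    try:
        return _REGION_PROFILES[region]
    except KeyError:
        raise ValueError(f"unknown region {region!r}") from None


@dataclass(frozen=True)
class EditCounts:
    """Realized edit operations, for calibration bookkeeping.

    Mismatch frequency is naturally measured per *surviving* base
    (``n_mismatch / (n_sites - n_deletion)``); insertion and deletion
    frequencies per original position.
    """

    n_sites: int
    n_mismatch: int
    n_insertion: int
    n_deletion: int

    @property
    def mismatch_freq(self) -> float:
        surviving = self.n_sites - self.n_deletion
        return self.n_mismatch / surviving if surviving else 0.0

    @property
    def insertion_freq(self) -> float:
        return self.n_insertion / self.n_sites if self.n_sites else 0.0

    @property
    def deletion_freq(self) -> float:
        return self.n_deletion / self.n_sites if self.n_sites else 0.0


def inject_errors(
    seq: str,
    profile: ErrorProfile,
    seed: int | np.random.Generator = 0,
    mismatch_includes_self: bool = False,
) -> tuple[str, EditCounts]:
    """Inject errors into one sequence; returns (mutated, edit counts)."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    L = arr.size
    if L == 0:
        return "", EditCounts(0, 0, 0, 0)
    u = rng.random((3, L))
    del_mask = u[0] < profile.deletion_rate
    ins_mask = u[1] < profile.insertion_rate
    mm_mask = (u[2] < profile.mismatch_rate) & ~del_mask

    n_mm = int(mm_mask.sum())
    if n_mm:
        idx = np.searchsorted(_BASES, arr[mm_mask])
        shift = rng.integers(0, 4, n_mm) if mismatch_includes_self \
            else rng.integers(1, 4, n_mm)
        arr[mm_mask] = _BASES[(idx + shift) % 4]
    n_ins = int(ins_mask.sum())
    ins_bases = _BASES[rng.integers(0, 4, n_ins)] if n_ins else None

    keep = ~del_mask
    # each original position contributes (optional inserted base) + (kept base)
    chunk = ins_mask.astype(np.int64) + keep.astype(np.int64)
    ends = np.cumsum(chunk)
    total = int(ends[-1])
    out = np.empty(total, dtype=np.uint8)
    if n_ins:
        out[(ends - chunk)[ins_mask]] = ins_bases
    out[ends[keep] - 1] = arr[keep]
    counts = EditCounts(L, n_mm, n_ins, int(del_mask.sum()))
    return out.tobytes().decode("ascii"), counts


def inject_errors_many(
    seqs: Sequence[str],
    profile: ErrorProfile,
    rng: np.random.Generator,
    mismatch_includes_self: bool = False,
) -> tuple[list[str], list[EditCounts]]:
    """Inject errors into each sequence, consuming one shared RNG stream."""
    out_seqs, out_counts = [], []
    for s in seqs:
        m, c = inject_errors(s, profile, rng, mismatch_includes_self)
        out_seqs.append(m)
        out_counts.append(c)
    return out_seqs, out_counts
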