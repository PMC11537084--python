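"""Within-genus species classification of marker sequences.

Two classifiers, mirroring common practice in amplicon taxonomy:

* **k-mer matching** (Kraken-style): count, over all query windows, how
  many 31-mers occur in each species' reference set; the species with the
  most matching windows wins.
* **best local alignment** (BLAST-style): Smith-Waterman score of the
  query against every reference (match +2, mismatch -3, gap open -5, gap
  extend -2, i.e. a gap of length g scores -5 - 2*(g-1)); the species of
  the best-scoring reference wins.

Ties are broken uniformly at random with a seeded draw.  A genome with
multiple marker copies is classified by its best-scoring copy.  References
are the original error-free extracted markers; queries are error-injected
copies of the same markers (no leave-one-out), so the benchmark measures
error tolerance plus species separability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .extract import MarkerRecord

__all__ = [
    "KmerIndex",
    "ClassificationResult",
    "AlignScoring",
    "build_index",
    "kmer_classify",
    "align_classify",
    "classify_genome",
    "sw_score",
]


@dataclass(frozen=True)
class ClassificationResult:
    query_id: str
    true_species: str
    predicted_species: str | None  # None = unclassified (scored incorrect)
    method: str  # "kmer" or "align"
    score: float
    tie_broken: bool = False

    @property
    def correct(self) -> bool:
        return self.predicted_species == self.true_species

    @property
    def genus(self) -> str:
        return self.true_species.rsplit("_", 1)[0]


@dataclass
class KmerIndex:
    """Exact k-mer index over one genus' references for one region."""

    k: int
    genus: str
    region: str
    kmer_to_species: dict[str, frozenset]
    n_references: int
    n_skipped_short: int = 0


def build_index(references: Sequence[MarkerRecord], k: int = 31) -> KmerIndex:
    """Index every length-k window of every reference.

    References shorter than k contribute nothing (counted in the index).
    All references must share one genus and one region.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not references:
        raise ValueError("no references")
    genera = {r.genus for r in references}
    regions = {r.region for r in references}
    if len(genera) > 1:
        raise ValueError(f"mixed genera in index: {sorted(genera)}")
    if len(regions) > 1:
        raise ValueError(f"mixed regions in index: {sorted(regions)}")
    tmp: dict[str, set] = {}
    n_short = 0
    for rec in references:
        if len(rec.sequence) < k:
            n_short += 1
            continue
        seq = rec.sequence
        for i in range(len(seq) - k + 1):
            tmp.setdefault(seq[i:i + k], set()).add(rec.species)
    return KmerIndex(k, genera.pop(), regions.pop(),
                     {km: frozenset(sp) for km, sp in tmp.items()},
                     n_references=len(references), n_skipped_short=n_short)


def _break_ties(candidates: list[str], rng: np.random.Generator
                ) -> tuple[str, bool]:
    if len(candidates) == 1:
        return candidates[0], False
    return candidates[int(rng.integers(len(candidates)))], True


def kmer_classify(
    query: str | MarkerRecord,
    index: KmerIndex,
    seed: int | np.random.Generator = 0,
    query_id: str = "",
    true_species: str = "",
) -> ClassificationResult:
    """Classify one query by 31-mer match counting.

    Each query window contributes at most one match per species (window
    multiplicity over query positions, not distinct shared k-mers).  A
    query with zero matches anywhere is returned unclassified.
    """
    if isinstance(query, MarkerRecord):
        query_id = query_id or query.marker_id
        true_species = true_species or query.species
        query = query.sequence
    if not query:
        raise ValueError("empty query")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    k = index.k
    scores: dict[str, int] = {}
    lookup = index.kmer_to_species
    for i in range(len(query) - k + 1):
        hit = lookup.get(query[i:i + k])
        if hit:
            for sp in hit:
                scores[sp] = scores.get(sp, 0) + 1
    if not scores:
        return ClassificationResult(query_id, true_species, None,
                                    "kmer", 0.0)
    best = max(scores.values())
    winners = sorted(sp for sp, sc in scores.items() if sc == best)
    winner, tied = _break_ties(winners, rng)
    return ClassificationResult(query_id, true_species, winner, "kmer",
                                float(best), tied)


# ---------------------------------------------------------------------------
# local alignment


@dataclass(frozen=True)
class AlignScoring:
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0    # score of the first base of a gap
    gap_extend: float = -2.0  # each additional gap base


_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return arr


def _sw_kernel(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n, m = a.size, b.size
    H = np.zeros(m + 1, np.float64)
    E = np.full(m + 1, -1e18)
    best = 0.0
    for i in range(1, n + 1):
        F = -1e18
        diag = 0.0
        ai = a[i - 1]
        for j in range(1, m + 1):
            E[j] = max(E[j] + gap_extend, H[j] + gap_open)
            F = max(F + gap_extend, H[j - 1] + gap_open)
            s = match if ai == b[j - 1] else mismatch
            h = diag + s
            if E[j] > h:
                h = E[j]
            if F > h:
                h = F
            if h < 0.0:
                h = 0.0
            diag = H[j]
            H[j] = h
            if h > best:
                best = h
    return best


try:  # jit-compile when numba is available; the pure kernel stays the oracle
    from numba import njit

    _sw_jit = njit(cache=True)(_sw_kernel)
except ImportError:  # pragma: no cover
    _sw_jit = _sw_kernel


def sw_score(query: str, reference: str,
             scoring: AlignScoring = AlignScoring()) -> float:
    """Smith-Waterman local alignment score (affine gaps, score only)."""
    if not query or not reference:
        return 0.0
    return float(_sw_jit(_encode(query), _encode(reference),
                         scoring.match, scoring.mismatch,
                         scoring.gap_open, scoring.gap_extend))


def align_classify(
    query: str | MarkerRecord,
    references: Sequence[MarkerRecord],
    seed: int | np.random.Generator = 0,
    scoring: AlignScoring = AlignScoring(),
    query_id: str = "",
    true_species: str = "",
) -> ClassificationResult:
    """Classify one query by best local-alignment score across references."""
    if isinstance(query, MarkerRecord):
        query_id = query_id or query.marker_id
        true_species = true_species or query.species
        query = query.sequence
    species = {r.species for r in references}
    if len(species) < 2:
        raise ValueError("need references from >= 2 species")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    best_by_species: dict[str, float] = {}
    for ref in references:
        sc = sw_score(query, ref.sequence, scoring)
        if sc > best_by_species.get(ref.species, -np.inf):
            best_by_species[ref.species] = sc
    best = max(best_by_species.values())
    winners = sorted(sp for sp, sc in best_by_species.items() if sc == best)
    winner, tied = _break_ties(winners, rng)
    return ClassificationResult(query_id, true_species, winner, "align",
                                best, tied)


def classify_genome(
    copy_results: Sequence[ClassificationResult],
    seed: int | np.random.Generator = 0,
    genome_id: str = "",
) -> ClassificationResult:
    """Reduce per-copy results to one genome call: the best-scoring copy.

    Score ties across copies are resolved by a seeded random choice among
    the tied copies.
    """
    if not copy_results:
        raise ValueError("empty copy list")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    best = max(r.score for r in copy_results)
    tied = [r for r in copy_results if r.score == best]
    chosen = tied[int(rng.integers(len(tied)))] if len(tied) > 1 else tied[0]
    return ClassificationResult(
        genome_id or chosen.query_id.split(":")[0],
        chosen.true_species, chosen.predicted_species, chosen.method,
        chosen.score, tie_broken=chosen.tie_broken or len(tied) > 1)
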