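"""Synthetic reference genomes, rRNA operons, and community profiles.

This module builds everything the benchmark consumes without touching real
databases: a multi-genus, multi-species collection of genomes whose rRNA
operons (16S–ITS1–23S–ITS2–5S) have controlled within/between-species
divergence and conserved V3–V4 primer footprints, plus Dirichlet community
profiles and two-group (control vs case) study tables with planted
differentially abundant species.

Sequence evolution is a star phylogeny: a random genus ancestor operon is
mutated independently into species consensus sequences, each species into
genome sequences, and each genome into operon copies.  Mutations are i.i.d.
per site (uniform substitutions plus a small indel fraction); the planted
primer footprints inside the 16S are exempt so that in-silico PCR stays
well defined.  All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaxonomyConfig",
    "OperonTemplate",
    "DivergenceModel",
    "StudyDesignConfig",
    "RegionAnnotation",
    "SyntheticGenome",
    "CommunityProfile",
    "generate_reference_set",
    "generate_true_profile",
    "generate_study_profiles",
    "write_reference_set",
    "read_reference_set",
    "FWD_PRIMER_SITE",
    "REV_PRIMER_SITE_RC",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Concrete instances planted at the conserved primer footprints.  They are
# legal expansions of the standard V3-V4 primer pair 341F/805R
# (CCTACGGGNGGCWGCAG / GACTACHVGGGTATCTAATCC).
FWD_PRIMER_SITE = "CCTACGGGAGGCTGCAG"
_REV_PRIMER_INSTANCE = "GACTACCAGGGTATCTAATCC"
_COMP = str.maketrans("ACGT", "TGCA")
REV_PRIMER_SITE_RC = _REV_PRIMER_INSTANCE.translate(_COMP)[::-1]

REGION_NAMES = ("16S", "ITS1", "23S", "ITS2", "5S")


def _as_range(value, name: str) -> tuple[int, int]:
    """Normalize an int or (min, max) pair to an inclusive integer range."""
    if isinstance(value, (int, np.integer)):
        return int(value), int(value)
    lo, hi = (int(v) for v in value)
    if lo > hi:
        raise ValueError(f"{name}: min > max ({lo} > {hi})")
    if lo < 1:
        raise ValueError(f"{name}: counts must be >= 1")
    return lo, hi


@dataclass(frozen=True)
class TaxonomyConfig:
    """Shape of the synthetic taxonomy.

    ``species_per_genus`` and ``genomes_per_species`` accept either a fixed
    count or an inclusive ``(min, max)`` range sampled per genus/species.
    ``copies_per_genome`` defaults to 1–7, the typical bacterial rRNA
    operon copy-number range.
    """

    n_genera: int = 5
    species_per_genus: int | tuple[int, int] = 5
    genomes_per_species: int | tuple[int, int] = 4
    copies_per_genome: tuple[int, int] = (1, 7)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genera < 1:
            raise ValueError("n_genera must be >= 1")
        lo, _ = _as_range(self.species_per_genus, "species_per_genus")
        if lo < 2:
            raise ValueError("species_per_genus must be >= 2 "
                             "(within-genus classification needs >= 2 classes)")
        _as_range(self.genomes_per_species, "genomes_per_species")
        _as_range(self.copies_per_genome, "copies_per_genome")


@dataclass(frozen=True)
class OperonTemplate:
    """Region lengths and primer placement for the ancestor operon.

    Defaults give a 5,127 bp operon with a 1,536 bp 16S, 2,914 bp 23S and
    108 bp 5S.  The forward primer footprint starts at ``fwd_primer_start``
    (relative to the 16S 5' end) and the amplicon, primers included, spans
    ``amplicon_len`` bases.
    """

    len_16s: int = 1536
    len_its1: int = 400
    len_23s: int = 2914
    len_its2: int = 169
    len_5s: int = 108
    fwd_primer_start: int = 340
    amplicon_len: int = 465

    OPERON_MIN = 4000
    OPERON_MAX = 6000
    AMPLICON_MIN = 430
    AMPLICON_MAX = 550

    @property
    def total_len(self) -> int:
        return (self.len_16s + self.len_its1 + self.len_23s
                + self.len_its2 + self.len_5s)

    def __post_init__(self) -> None:
        if not self.OPERON_MIN <= self.total_len <= self.OPERON_MAX:
            raise ValueError(
                f"operon template length {self.total_len} outside "
                f"[{self.OPERON_MIN}, {self.OPERON_MAX}]")
        if not self.AMPLICON_MIN <= self.amplicon_len <= self.AMPLICON_MAX:
            raise ValueError(
                f"amplicon length {self.amplicon_len} outside "
                f"[{self.AMPLICON_MIN}, {self.AMPLICON_MAX}]")
        n_fwd = len(FWD_PRIMER_SITE)
        n_rev = len(REV_PRIMER_SITE_RC)
        if self.amplicon_len < n_fwd + n_rev:
            raise ValueError("amplicon too short to contain both primers")
        if self.fwd_primer_start + self.amplicon_len > self.len_16s:
            raise ValueError("amplicon extends past the 16S 3' end")


@dataclass(frozen=True)
class DivergenceModel:
    """Per-site divergence targets between taxonomic levels.

    Rates are expected *pairwise* substitution densities: two species of a
    genus differ at about ``d_between_species`` sites per site, two genomes
    of a species at about ``d_within_species``, and two operon copies of a
    genome at about ``d_between_copies``.  ``indel_fraction`` is the share
    of mutation events realized as 1 bp indels instead of substitutions.
    """

    d_between_species: float = 0.02
    d_within_species: float = 0.002
    d_between_copies: float = 0.001
    indel_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.d_within_species < self.d_between_species <= 0.3:
            raise ValueError("require 0 <= d_within < d_between <= 0.3")
        if not 0 <= self.d_between_copies <= 0.3:
            raise ValueError("d_between_copies outside [0, 0.3]")
        if not 0 <= self.indel_fraction <= 1:
            raise ValueError("indel_fraction outside [0, 1]")


@dataclass(frozen=True)
class StudyDesignConfig:
    """Two-group study layout with planted differential species."""

    n_control: int = 39
    n_case: int = 47
    n_species: int = 188
    n_differential: int = 20
    effect_size: float = 1.0
    alpha_p: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_differential > self.n_species:
            raise ValueError("n_differential > n_species")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 < self.alpha_p < 1:
            raise ValueError("alpha_p must be in (0, 1)")


@dataclass(frozen=True)
class RegionAnnotation:
    """One annotated region of one operon copy, in genome coordinates."""

    copy_index: int
    region: str  # one of REGION_NAMES or "operon"
    start: int   # 0-based, half-open
    end: int
    strand: str = "+"


@dataclass
class SyntheticGenome:
    genome_id: str
    genus: str
    species: str
    sequence: str
    annotations: list[RegionAnnotation] = field(default_factory=list)

    def region_sequences(self, region: str) -> list[tuple[int, str]]:
        """Return (copy_index, subsequence) for every copy of ``region``."""
        return [(a.copy_index, self.sequence[a.start:a.end])
                for a in self.annotations if a.region == region]


@dataclass
class CommunityProfile:
    """A composition over an ordered species list.

    ``concentrations`` keeps the Dirichlet parameters the proportions were
    drawn from, when known, so that downstream study simulation can perturb
    them for case samples.
    """

    species: list[str]
    proportions: np.ndarray
    concentrations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if len(self.species) != self.proportions.size:
            raise ValueError("species/proportions length mismatch")
        if np.any(self.proportions < 0):
            raise ValueError("negative proportion")
        if abs(self.proportions.sum() - 1.0) > 1e-9:
            raise ValueError("proportions do not sum to 1")


# ---------------------------------------------------------------------------
# sequence-level machinery


def _random_dna(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(arr: np.ndarray, rate: float, indel_fraction: float,
            rng: np.random.Generator) -> np.ndarray:
    """Mutate a uint8 DNA array i.i.d. per site.

    Each site is hit with probability ``rate``; a hit is a 1 bp indel with
    probability ``indel_fraction`` (insertion or deletion, 50/50) and a
    substitution to one of the three other bases otherwise.
    """
    if rate <= 0 or arr.size == 0:
        return arr.copy()
    hit = rng.random(arr.size) < rate
    kind = rng.random(arr.size)  # consumed per site for determinism
    is_indel = hit & (kind < indel_fraction)
    is_sub = hit & ~is_indel
    out = arr.copy()
    n_sub = int(is_sub.sum())
    if n_sub:
        # shift by 1..3 in base space => never the original base
        idx = np.searchsorted(_BASES, out[is_sub])
        out[is_sub] = _BASES[(idx + rng.integers(1, 4, size=n_sub)) % 4]
    if is_indel.any():
        ins_flag = rng.random(int(is_indel.sum())) < 0.5
        pieces: list[np.ndarray] = []
        prev = 0
        for pos, ins in zip(np.flatnonzero(is_indel), ins_flag):
            pieces.append(out[prev:pos])
            if ins:
                pieces.append(_BASES[rng.integers(0, 4, size=1)])
                pieces.append(out[pos:pos + 1])
            prev = pos + 1  # deletion: skip the site
        pieces.append(out[prev:])
        out = np.concatenate(pieces)
    return out


def _seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


class _Operon:
    """An operon held as mutable segments so primer footprints stay fixed.

    Segments, in order: 16S-pre, fwd-primer, 16S-mid, rev-site, 16S-post,
    ITS1, 23S, ITS2, 5S.  The two primer segments are never mutated.
    """

    _MUTABLE = (0, 2, 4, 5, 6, 7, 8)

    def __init__(self, segments: list[np.ndarray]):
        self.segments = segments

    @classmethod
    def ancestor(cls, template: OperonTemplate,
                 rng: np.random.Generator) -> "_Operon":
        fwd = np.frombuffer(FWD_PRIMER_SITE.encode(), dtype=np.uint8)
        rev = np.frombuffer(REV_PRIMER_SITE_RC.encode(), dtype=np.uint8)
        mid_len = template.amplicon_len - fwd.size - rev.size
        post_len = (template.len_16s - template.fwd_primer_start
                    - template.amplicon_len)
        if post_len < 0:
            raise ValueError("amplicon extends past the 16S 3' end")
        segs = [
            _random_dna(rng, template.fwd_primer_start),
            fwd.copy(),
            _random_dna(rng, mid_len),
            rev.copy(),
            _random_dna(rng, post_len),
            _random_dna(rng, template.len_its1),
            _random_dna(rng, template.len_23s),
            _random_dna(rng, template.len_its2),
            _random_dna(rng, template.len_5s),
        ]
        return cls(segs)

    def mutated(self, rate: float, indel_fraction: float,
                rng: np.random.Generator) -> "_Operon":
        segs = [
            _mutate(s, rate, indel_fraction, rng) if i in self._MUTABLE
            else s.copy()
            for i, s in enumerate(self.segments)
        ]
        return _Operon(segs)

    def region_arrays(self) -> dict[str, np.ndarray]:
        s = self.segments
        return {
            "16S": np.concatenate(s[0:5]),
            "ITS1": s[5],
            "23S": s[6],
            "ITS2": s[7],
            "5S": s[8],
        }


def generate_reference_set(
    taxonomy: TaxonomyConfig,
    template: OperonTemplate | None = None,
    divergence: DivergenceModel | None = None,
) -> list[SyntheticGenome]:
    """Generate the annotated genome collection.

    Every genome carries >= 1 operon copy, each annotated with 16S/ITS1/
    23S/ITS2/5S coordinates plus the enclosing ``operon`` span.  The same
    configuration (including seed) reproduces byte-identical output.
    """
    template = template or OperonTemplate()
    divergence = divergence or DivergenceModel()
    rng = np.random.default_rng(taxonomy.seed)

    sp_lo, sp_hi = _as_range(taxonomy.species_per_genus, "species_per_genus")
    gn_lo, gn_hi = _as_range(taxonomy.genomes_per_species,
                             "genomes_per_species")
    cp_lo, cp_hi = _as_range(taxonomy.copies_per_genome, "copies_per_genome")

    # Pairwise divergence d between two leaves of a star phylogeny is about
    # twice the per-branch rate, so branches mutate at d/2.
    r_species = divergence.d_between_species / 2.0
    r_genome = divergence.d_within_species / 2.0
    r_copy = divergence.d_between_copies / 2.0
    indels = divergence.indel_fraction

    genomes: list[SyntheticGenome] = []
    for gi in range(taxonomy.n_genera):
        genus = f"genus{gi + 1:02d}"
        ancestor = _Operon.ancestor(template, rng)
        n_species = int(rng.integers(sp_lo, sp_hi + 1))
        for si in range(n_species):
            species = f"{genus}_sp{si + 1:02d}"
            sp_operon = ancestor.mutated(r_species, indels, rng)
            n_genomes = int(rng.integers(gn_lo, gn_hi + 1))
            for ki in range(n_genomes):
                genome_id = f"{species}_gen{ki + 1:02d}"
                gen_operon = sp_operon.mutated(r_genome, indels, rng)
                n_copies = int(rng.integers(cp_lo, cp_hi + 1))
                chunks: list[np.ndarray] = []
                annots: list[RegionAnnotation] = []
                offset = 0
                for ci in range(n_copies):
                    spacer = _random_dna(rng, int(rng.integers(200, 501)))
                    chunks.append(spacer)
                    offset += spacer.size
                    copy = gen_operon.mutated(r_copy, indels, rng)
                    operon_start = offset
                    for region, arr in copy.region_arrays().items():
                        annots.append(RegionAnnotation(
                            ci, region, offset, offset + arr.size))
                        chunks.append(arr)
                        offset += arr.size
                    annots.append(RegionAnnotation(
                        ci, "operon", operon_start, offset))
                chunks.append(_random_dna(rng, int(rng.integers(200, 501))))
                genomes.append(SyntheticGenome(
                    genome_id, genus, species,
                    _seq(np.concatenate(chunks)), annots))
    return genomes


# ---------------------------------------------------------------------------
# community / study profiles


def generate_true_profile(
    species_list: Sequence[str],
    alpha_p: float = 0.01,
    seed: int | np.random.Generator = 0,
) -> CommunityProfile:
    """Draw a true community composition.

    Per-species Dirichlet concentrations are i.i.d. Geometric(``alpha_p``)
    on {1, 2, ...} (mean 1/alpha_p), then proportions are a single draw
    from Dirichlet(alpha).
    """
    if len(species_list) < 2:
        raise ValueError("need >= 2 species")
    if not 0 < alpha_p < 1:
        raise ValueError("alpha_p must be in (0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    alpha = rng.geometric(alpha_p, size=len(species_list)).astype(float)
    props = rng.dirichlet(alpha)
    return CommunityProfile(list(species_list), props, concentrations=alpha)


def generate_study_profiles(
    design: StudyDesignConfig,
    base_profile: CommunityProfile | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a species x sample proportion table for a two-group study.

    Control samples are independent Dirichlet draws at the base
    concentrations; case samples use the same concentrations except that
    ``n_differential`` randomly chosen species have theirs multiplied by
    exp(+-effect_size), the sign drawn per species and recorded.  The
    perturbed concentrations are then rescaled (within the differential
    set only) so the total concentration is unchanged: compositions are
    closed, so without this the planted effects would leak a systematic
    group shift into every null species; with it, null species keep
    identical marginals in both groups and planted effects are read as
    changes relative to the community background.

    Returns ``(table, truth)`` where ``table`` is species x samples
    (columns ``control01.. caseNN``, each summing to 1) and ``truth`` has
    columns ``species`` and ``sign`` (+1/-1) for the planted set.
    """
    rng = np.random.default_rng(design.seed)
    if base_profile is None:
        species = [f"species{i + 1:03d}" for i in range(design.n_species)]
        base_profile = generate_true_profile(species, design.alpha_p, rng)
    if len(base_profile.species) < design.n_species:
        raise ValueError("base_profile covers fewer species than the design")
    if base_profile.concentrations is None:
        raise ValueError("base_profile must carry Dirichlet concentrations")

    species = list(base_profile.species)
    alpha_control = np.asarray(base_profile.concentrations, dtype=float)
    diff_idx = rng.choice(len(species), size=design.n_differential,
                          replace=False)
    # Signs are assigned by greedily balancing the summed concentration of
    # the up- and down-regulated halves (largest alpha first), then flipping
    # the whole assignment with probability 1/2.  Balance keeps the closure
    # correction below the effect size, so every planted sign survives in
    # the realized group means.
    signs = np.ones(design.n_differential, dtype=int)
    alpha_diff = alpha_control[diff_idx]
    sum_pos = sum_neg = 0.0
    for j in np.argsort(-alpha_diff):
        if sum_pos <= sum_neg:
            sum_pos += alpha_diff[j]
        else:
            signs[j] = -1
            sum_neg += alpha_diff[j]
    if rng.random() < 0.5:
        signs = -signs
    alpha_case = alpha_control.copy()
    if design.n_differential:
        multipliers = np.exp(signs * design.effect_size)
        # closure correction: keep the summed concentration of the
        # differential set (hence the total) unchanged
        scale = (alpha_diff.sum() / (alpha_diff * multipliers).sum())
        alpha_case[diff_idx] *= multipliers * scale

    cols, names = [], []
    for j in range(design.n_control):
        cols.append(rng.dirichlet(alpha_control))
        names.append(f"control{j + 1:02d}")
    for j in range(design.n_case):
        cols.append(rng.dirichlet(alpha_case))
        names.append(f"case{j + 1:02d}")
    table = pd.DataFrame(np.column_stack(cols), index=species, columns=names)
    table.index.name = "species"
    order = np.argsort(diff_idx)
    truth = pd.DataFrame({
        "species": [species[i] for i in diff_idx[order]],
        "sign": signs[order].astype(int),
    })
    return table, truth


# ---------------------------------------------------------------------------
# I/O


def write_reference_set(genomes: Iterable[SyntheticGenome],
                        outdir: str | Path) -> tuple[Path, Path]:
    """Write genomes as FASTA plus a TSV annotation sidecar."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "genomes.fasta"
    tsv = outdir / "annotations.tsv"
    records, rows = [], []
    for g in genomes:
        records.append(SeqRecord(Seq(g.sequence), id=g.genome_id,
                                 description=f"{g.genus} {g.species}"))
        for a in g.annotations:
            rows.append((g.genome_id, g.genus, g.species, a.copy_index,
                         a.region, a.start, a.end, a.strand))
    SeqIO.write(records, fasta, "fasta")
    pd.DataFrame(rows, columns=["genome_id", "genus", "species", "copy_index",
                                "region", "start", "end", "strand"]
                 ).to_csv(tsv, sep="\t", index=False)
    return fasta, tsv


def read_reference_set(fasta: str | Path,
                       annotations: str | Path) -> list[SyntheticGenome]:
    from Bio import SeqIO

    ann = pd.read_csv(annotations, sep="\t")
    by_genome: dict[str, list[RegionAnnotation]] = {}
    meta: dict[str, tuple[str, str]] = {}
    for row in ann.itertuples(index=False):
        by_genome.setdefault(row.genome_id, []).append(RegionAnnotation(
            int(row.copy_index), str(row.region),
            int(row.start), int(row.end), str(row.strand)))
        meta[row.genome_id] = (str(row.genus), str(row.species))
    genomes = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        if rec.id not in by_genome:
            raise ValueError(f"genome {rec.id} missing from annotations")
        genus, species = meta[rec.id]
        genomes.append(SyntheticGenome(rec.id, genus, species,
                                       str(rec.seq), by_genome[rec.id]))
    return genomes


def write_profile_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t")
    return path


def taxonomy_from_json(path: str | Path) -> TaxonomyConfig:
    cfg = json.loads(Path(path).read_text())
    for key in ("species_per_genus", "genomes_per_species",
                "copies_per_genome"):
        if isinstance(cfg.get(key), list):
            cfg[key] = tuple(cfg[key])
    return TaxonomyConfig(**cfg)


def design_from_json(path: str | Path) -> StudyDesignConfig:
    return StudyDesignConfig(**json.loads(Path(path).read_text()))
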