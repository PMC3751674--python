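"""Dinucleotide-preserving random-seed null model.

The null is a first-order Markov chain over the RNA alphabet fitted to the
pooled real seeds (empirical position-1 distribution plus dinucleotide
transition frequencies, both with add-one smoothing). Random 7-nt seeds are
sampled from the chain, rejecting any draw identical to a real seed, and each
random set is pushed through the identical scan + conservation path as the
real seeds to produce expected per-stratum counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .conservation import (
    CladeTable,
    ConservationConfig,
    MafIndex,
    call_site_conservation,
    stratify_sites,
)
from .models import TranscriptModel
from .seeds import (
    SITE_TYPES,
    SeedFamily,
    TargetSite,
    dedupe_gene_level,
    scan_transcript,
    seed_to_patterns,
)

RNA_BASES = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(RNA_BASES)}

#: number of random seed sets used for the empirical null
DEFAULT_N_SETS = 20

_MAX_REJECTION_DRAWS = 10**6


@dataclass
class DinucModel:
    """First-order Markov model over ACGU: initial distribution and 4x4
    transition matrix (rows sum to 1)."""

    initial: np.ndarray
    transition: np.ndarray

    def __post_init__(self) -> None:
        if not np.isclose(self.initial.sum(), 1.0):
            raise ValueError("initial distribution must sum to 1")
        if not np.allclose(self.transition.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")


@dataclass
class RandomSeedSet:
    set_index: int
    seeds: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.seeds)


def fit_dinuc_model(seeds: list[str]) -> DinucModel:
    """Fit the Markov null to a pool of 7-nt seeds with add-one smoothing."""
    if not seeds:
        raise ValueError("cannot fit dinucleotide model to an empty seed pool")
    init = np.ones(4)
    trans = np.ones((4, 4))
    for s in seeds:
        if len(s) != 7 or not set(s) <= set(RNA_BASES):
            raise ValueError(f"invalid seed {s!r}")
        init[_BASE_INDEX[s[0]]] += 1
        for a, b in zip(s, s[1:]):
            trans[_BASE_INDEX[a], _BASE_INDEX[b]] += 1
    return DinucModel(
        initial=init / init.sum(),
        transition=trans / trans.sum(axis=1, keepdims=True),
    )


def sample_seed(model: DinucModel, rng: np.random.Generator) -> str:
    states = [int(rng.choice(4, p=model.initial))]
    for _ in range(6):
        states.append(int(rng.choice(4, p=model.transition[states[-1]])))
    return "".join(RNA_BASES[i] for i in states)


def sample_seed_sets(
    model: DinucModel,
    set_size: int,
    real_seeds: set[str],
    rng_seed: int,
    n_sets: int = DEFAULT_N_SETS,
    reject_real: bool = True,
) -> list[RandomSeedSet]:
    """Draw ``n_sets`` sets of ``set_size`` random seeds from the model.

    Draws identical to a real seed are rejected and redrawn (configurable);
    duplicates within a set are allowed — distinct families can share
    composition. Deterministic given ``rng_seed``.
    """
    if set_size < 1:
        raise ValueError("set_size must be >= 1")
    rng = np.random.default_rng(rng_seed)
    sets = []
    draws = 0
    for k in range(1, n_sets + 1):
        seeds = []
        while len(seeds) < set_size:
            draws += 1
            if draws > _MAX_REJECTION_DRAWS:
                raise RuntimeError(
                    "rejection sampling exceeded 1e6 draws; model degenerate"
                )
            s = sample_seed(model, rng)
            if reject_real and s in real_seeds:
                continue
            seeds.append(s)
        sets.append(RandomSeedSet(set_index=k, seeds=seeds))
    return sets


def count_sites_by_stratum(
    families: list[SeedFamily],
    transcripts: list[TranscriptModel],
    index: MafIndex | None,
    clades: CladeTable | None,
    cfg: ConservationConfig | None = None,
    tiers: tuple[str, ...] = ("primate", "mammal", "vertebrate"),
    site_types: tuple[str, ...] = SITE_TYPES,
) -> tuple[dict[tuple[str, str], int], list[TargetSite]]:
    """Scan + conservation-call + gene-level dedupe + stratify, one code path
    shared by the real seeds and every random set (pipeline identity).

    Returns the cumulative (tier, site_type) count map and the deduplicated,
    conservation-annotated site list. With ``index`` None, conservation is
    skipped and only the "none"-tier scan is meaningful.
    """
    patterns = []
    for fam in families:
        patterns.extend(
            p for p in seed_to_patterns(fam) if p.site_type in site_types
        )
    sites: list[TargetSite] = []
    for t in transcripts:
        sites.extend(scan_transcript(t, patterns))
    sites = dedupe_gene_level(sites)
    if index is not None:
        if clades is None:
            raise ValueError("clade table required for conservation calls")
        cache: dict[tuple, object] = {}
        for s in sites:
            key = (s.genome_chrom, tuple(s.genome_intervals), s.strand, s.match_dna)
            if key not in cache:
                cache[key] = call_site_conservation(s, index, clades, cfg)
            s.conservation = cache[key]
    return stratify_sites(sites, tiers, site_types), sites


def expected_counts(
    seed_sets: list[RandomSeedSet],
    transcripts: list[TranscriptModel],
    index: MafIndex | None,
    clades: CladeTable | None,
    cfg: ConservationConfig | None = None,
    tiers: tuple[str, ...] = ("primate", "mammal", "vertebrate"),
    site_types: tuple[str, ...] = SITE_TYPES,
) -> dict[int, dict[tuple[str, str], int]]:
    """Per-set stratum counts for the random seed sets, produced by the same
    pipeline as the observed counts."""
    out: dict[int, dict[tuple[str, str], int]] = {}
    for seed_set in seed_sets:
        families = [
            SeedFamily(f"set{seed_set.set_index}_seed{i:03d}", s, "random")
            for i, s in enumerate(seed_set.seeds, start=1)
        ]
        counts, _ = count_sites_by_stratum(
            families, transcripts, index, clades, cfg, tiers, site_types
        )
        out[seed_set.set_index] = counts
    return out


def write_seed_sets(sets: list[RandomSeedSet], path: str | Path) -> None:
    """Audit TSV of the sampled null seeds (set_index, seed)."""
    with open(path, "w") as fh:
        fh.write("set_index\tseed\n")
        for s in sets:
            for seed in s.seeds:
                fh.write(f"{s.set_index}\t{seed}\n")
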