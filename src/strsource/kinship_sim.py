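"""Hardy-Weinberg genotype simulation and first-degree-relative generation.

Unrelated individuals (UI) are independent two-allele draws per locus from
a population allele-frequency table.  Parent-offspring (PO) and full-sibling
(FS) profiles are simulated conditional on an anchor individual's germline
profile: the offspring inherits one uniformly chosen anchor allele plus one
population draw; for a sibling, two parents are reconstructed (each holding
one anchor allele plus one population draw) and the sibling receives one
uniformly chosen allele from each.  Loci are independent and meiosis is
mutation-free, so every simulated pedigree is exactly Mendel-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .profiles_io import (
    AlleleFrequencyTable,
    Genotype,
    STRProfile,
    allele_sort_key,
)

__all__ = [
    "SimulatedRelative",
    "sample_genotype",
    "sample_profile",
    "simulate_ui_cohort",
    "simulate_po",
    "simulate_fs",
]

RELATIONS = ("UI", "FS", "PO")


@dataclass(frozen=True)
class SimulatedRelative:
    """A simulated profile plus its relation to the anchoring patient."""

    profile: STRProfile
    relation: str
    anchor_id: str | None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")


def _draw_allele(freqs: Mapping[str, float], rng: np.random.Generator) -> str:
    alleles = sorted(freqs, key=allele_sort_key)
    p = np.asarray([freqs[a] for a in alleles], dtype=float)
    p = p / p.sum()
    return alleles[int(rng.choice(len(alleles), p=p))]


def sample_genotype(
    freqs: Mapping[str, float], rng: np.random.Generator, locus: str
) -> Genotype:
    """Two independent allele draws from the locus frequency distribution."""
    if not freqs:
        raise ValueError(f"empty frequency map for locus {locus!r}")
    return Genotype(locus, (_draw_allele(freqs, rng), _draw_allele(freqs, rng)))


def sample_profile(
    table: AlleleFrequencyTable,
    rng: np.random.Generator,
    sample_id: str,
    loci: Iterable[str] | None = None,
    source: str = "germline",
) -> STRProfile:
    """An independent HWE profile over the table's (or the given) loci."""
    loci = tuple(loci) if loci is not None else table.loci
    genotypes = {}
    for locus in loci:
        if locus not in table:
            raise ValueError(f"locus {locus!r} missing from frequency table")
        genotypes[locus] = sample_genotype(table[locus], rng, locus)
    return STRProfile(sample_id=sample_id, source=source, platform="NGS",
                      regime="truth", genotypes=genotypes)


def simulate_ui_cohort(
    table: AlleleFrequencyTable,
    n: int,
    rng: np.random.Generator,
    loci: Iterable[str] | None = None,
) -> list[STRProfile]:
    """``n`` independent HWE profiles (the unrelated-individual cohort)."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    width = len(str(n))
    return [
        sample_profile(table, rng, f"UI{i + 1:0{width}d}", loci)
        for i in range(n)
    ]


def simulate_po(
    anchor: STRProfile,
    table: AlleleFrequencyTable,
    rng: np.random.Generator,
    sample_id: str | None = None,
    seed: int | None = None,
) -> SimulatedRelative:
    """Simulate an offspring (or parent) of the anchor's germline profile.

    Per locus the relative carries one uniformly chosen anchor allele and
    one population draw, so a PO pair shares at least one allele at every
    locus by construction.
    """
    genotypes = {}
    for locus, g in anchor.genotypes.items():
        if locus not in table:
            raise ValueError(f"locus {locus!r} missing from frequency table")
        pair = g.as_diploid()
        transmitted = pair[int(rng.integers(2))]
        genotypes[locus] = Genotype(
            locus, (transmitted, _draw_allele(table[locus], rng))
        )
    profile = STRProfile(
        sample_id=sample_id or f"{anchor.sample_id}_PO",
        source="simulated", platform="NGS", regime="truth",
        genotypes=genotypes,
    )
    return SimulatedRelative(profile, "PO", anchor.sample_id, seed)


def simulate_fs(
    anchor: STRProfile,
    table: AlleleFrequencyTable,
    rng: np.random.Generator,
    sample_id: str | None = None,
    seed: int | None = None,
) -> SimulatedRelative:
    """Simulate a full sibling of the anchor's germline profile.

    Per locus: each reconstructed parent holds one anchor allele (randomly
    assigned between the parents when the anchor is heterozygous) plus one
    population draw; the sibling inherits one uniformly chosen allele from
    each parent.
    """
    genotypes = {}
    for locus, g in anchor.genotypes.items():
        if locus not in table:
            raise ValueError(f"locus {locus!r} missing from frequency table")
        a1, a2 = g.as_diploid()
        if a1 != a2 and rng.integers(2):
            a1, a2 = a2, a1
        parent1 = (a1, _draw_allele(table[locus], rng))
        parent2 = (a2, _draw_allele(table[locus], rng))
        sib = (parent1[int(rng.integers(2))], parent2[int(rng.integers(2))])
        genotypes[locus] = Genotype(locus, sib)
    profile = STRProfile(
        sample_id=sample_id or f"{anchor.sample_id}_FS",
        source="simulated", platform="NGS", regime="truth",
        genotypes=genotypes,
    )
    return SimulatedRelative(profile, "FS", anchor.sample_id, seed)
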