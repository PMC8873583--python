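"""Pairwise allele-sharing statistics: A0/A1/A2 counts and the IBS score.

For a pair of profiles, each co-typed panel locus contributes the size of
the multiset intersection of the two genotypes (capped at 2): A0, A1 and A2
count loci sharing 0, 1 and 2 alleles, and the IBS score is A1 + 2*A2.
Pairs are collected in four comparison groups: PC (tumor vs the patient's
own germline), UI (tumor vs each unrelated individual), FS and PO (tumor vs
the patient's simulated full siblings / parent-offspring relatives).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .allele_calling import NGS_AT, CallingRegime, call_profile
from .kinship_sim import SimulatedRelative
from .profiles_io import Genotype, LocusPanel, PairedCase, STRProfile

__all__ = [
    "GROUPS",
    "IBSResult",
    "shared_allele_count",
    "score_pair",
    "score_groups",
    "results_to_frame",
]

GROUPS = ("PC", "UI", "FS", "PO")


def shared_allele_count(g1: Genotype, g2: Genotype) -> int:
    """Number of alleles shared by two genotypes: 0, 1 or 2.

    The size of the multiset intersection, capped at 2; single-allele calls
    are treated as homozygous duplicates, and a tumor genotype carrying
    more than two distinct alleles can still share at most 2.
    """
    inter = g1.as_multiset() & g2.as_multiset()
    return min(2, sum(inter.values()))


@dataclass(frozen=True)
class IBSResult:
    """Allele-sharing counts for one pair over the co-typed panel loci."""

    id_a: str
    id_b: str
    group: str
    n_loci: int
    a0: int
    a1: int
    a2: int
    ibs: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.a0 + self.a1 + self.a2 != self.n_loci:
            raise ValueError("A-counts do not sum to the locus count")
        if self.ibs != self.a1 + 2 * self.a2:
            raise ValueError("IBS score inconsistent with A-counts")


def score_pair(
    p1: STRProfile, p2: STRProfile, panel: LocusPanel, group: str = "UI"
) -> IBSResult:
    """Score one pair over the panel's non-excluded, co-typed loci.

    Loci that are no-calls (absent) in either profile are dropped from the
    denominator (pairwise-complete scoring); zero scorable loci is an error.
    """
    counts = [0, 0, 0]
    n = 0
    for locus in panel.scoring_loci:
        g1 = p1.genotypes.get(locus)
        g2 = p2.genotypes.get(locus)
        if g1 is None or g2 is None:
            continue
        counts[shared_allele_count(g1, g2)] += 1
        n += 1
    if n == 0:
        raise ValueError(
            f"no co-typed scorable loci for pair ({p1.sample_id!r}, "
            f"{p2.sample_id!r})"
        )
    a0, a1, a2 = counts
    return IBSResult(p1.sample_id, p2.sample_id, group, n, a0, a1, a2,
                     a1 + 2 * a2)


def _tumor_profile(case: PairedCase, regime: CallingRegime) -> STRProfile:
    if case.tumor.raw:
        return call_profile(case.tumor, regime)
    return case.tumor


def score_groups(
    cases: Sequence[PairedCase],
    ui_cohort: Sequence[STRProfile],
    fs_relatives: Sequence[SimulatedRelative],
    po_relatives: Sequence[SimulatedRelative],
    panel: LocusPanel,
    regime: CallingRegime = NGS_AT,
) -> dict[str, list[IBSResult]]:
    """Collect IBS results for the PC, UI, FS and PO comparison groups.

    Tumor profiles are called under ``regime`` (analytical threshold by
    default — the regime that restores low-share germline alleles) before
    scoring.  FS/PO relatives are matched to cases by their ``anchor_id``;
    a relative anchored to an unknown case is an error.
    """
    if not cases:
        raise ValueError("no cases to score")
    by_case = {c.case_id: c for c in cases}
    tumors = {c.case_id: _tumor_profile(c, regime) for c in cases}
    for rel in list(fs_relatives) + list(po_relatives):
        if rel.anchor_id not in by_case:
            raise ValueError(
                f"relative {rel.profile.sample_id!r} anchored to unknown "
                f"case {rel.anchor_id!r}"
            )
    results: dict[str, list[IBSResult]] = {g: [] for g in GROUPS}
    for c in cases:
        results["PC"].append(
            score_pair(tumors[c.case_id], c.germline, panel, "PC")
        )
        for ui in ui_cohort:
            results["UI"].append(
                score_pair(tumors[c.case_id], ui, panel, "UI")
            )
    for group, relatives in (("FS", fs_relatives), ("PO", po_relatives)):
        for rel in relatives:
            results[group].append(
                score_pair(tumors[rel.anchor_id], rel.profile, panel, group)
            )
    return results


def results_to_frame(
    results: Mapping[str, Sequence[IBSResult]] | Sequence[IBSResult],
) -> pd.DataFrame:
    """Flatten IBS results to one row per pair (the TSV interchange form)."""
    if isinstance(results, Mapping):
        flat = [r for group in results.values() for r in group]
    else:
        flat = list(results)
    return pd.DataFrame(
        [
            {
                "id_a": r.id_a, "id_b": r.id_b, "group": r.group,
                "n_loci": r.n_loci, "a0": r.a0, "a1": r.a1, "a2": r.a2,
                "ibs": r.ibs,
            }
            for r in flat
        ],
        columns=["id_a", "id_b", "group", "n_loci", "a0", "a1", "a2", "ibs"],
    )
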