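"""Somatic STR status classification and cross-platform comparison reports.

A tumor genotype is compared against the patient's germline (control)
genotype locus by locus and assigned one of five statuses — stable (S),
partial loss of heterozygosity (pLOH), complete loss of heterozygosity (L),
additional allele (Aadd), new allele (Anew) — or Failed when the locus did
not type.  Because tumor tissue is a mixture of tumor and stromal cells, L
and Anew are detection artifacts whenever the stromal (germline) allele
falls below the caller's threshold; re-calling under a lower threshold
reclassifies them to pLOH and Aadd.  This module also provides the
cross-platform accounting built on that fact: genotype concordance, status
cross-tabulation, and germline-allele recovery per regime.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._common import percent, round_half_up
from .allele_calling import CallingRegime, call_locus, call_profile
from .profiles_io import Genotype, PairedCase, RawLocusSignal, STRProfile

__all__ = [
    "MutationStatus",
    "MERGED_CATEGORIES",
    "DEFAULT_H_MIN",
    "heterozygote_balance",
    "classify_locus",
    "classify_case",
    "StatusReport",
    "cohort_distribution",
    "genotype_concordance",
    "ConcordanceResult",
    "status_crosstab",
    "CrossTab",
    "germline_recovery",
    "RecoveryReport",
]


class MutationStatus(str, Enum):
    S = "S"
    PLOH = "pLOH"
    L = "L"
    AADD = "Aadd"
    ANEW = "Anew"
    FAILED = "Failed"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


STATUS_ORDER: tuple[MutationStatus, ...] = (
    MutationStatus.S, MutationStatus.PLOH, MutationStatus.L,
    MutationStatus.AADD, MutationStatus.ANEW, MutationStatus.FAILED,
)

#: Reporting categories with S and pLOH merged — the unit in which status
#: distributions are compared across platforms (the numeric S/pLOH split
#: depends on the heterozygote-balance floor, which is a local convention).
MERGED_CATEGORIES: tuple[str, ...] = ("S/pLOH", "L", "Aadd", "Anew", "Failed")

#: Heterozygote-balance floor (minor/major signal) below which a locus with
#: both germline alleles present is called pLOH rather than S.
DEFAULT_H_MIN = 0.6


def merged_category(status: MutationStatus) -> str:
    if status in (MutationStatus.S, MutationStatus.PLOH):
        return "S/pLOH"
    return status.value


def heterozygote_balance(
    germline: Genotype, signal: RawLocusSignal | None
) -> float | None:
    """Minor/major signal ratio over the two germline alleles in the tumor.

    ``None`` when the germline is homozygous or no signal is available.
    """
    if signal is None or not germline.is_heterozygous:
        return None
    a, b = germline.as_diploid()
    va, vb = signal.get(a), signal.get(b)
    hi, lo = max(va, vb), min(va, vb)
    if hi <= 0:
        return None
    return lo / hi


def classify_locus(
    germline: Genotype,
    tumor: Genotype | None,
    balance: float | None = None,
    h_min: float = DEFAULT_H_MIN,
) -> MutationStatus:
    """Classify one locus's somatic STR status against the germline call.

    Decision rules, in order:

    1. tumor no-call -> Failed;
    2. tumor gains a non-germline allele while keeping every germline
       allele -> Aadd;
    3. tumor gains a non-germline allele and lacks a germline allele
       -> Anew;
    4. no new allele, heterozygous germline, only one germline allele
       retained -> L;
    5. both germline alleles retained but imbalanced
       (``balance < h_min``) -> pLOH;
    6. otherwise -> S.

    A germline single-allele call is treated as homozygous; complete
    allelic loss at such loci is undetectable and classifies as S.
    """
    G = germline.distinct
    if len(G) > 2:
        raise ValueError(
            f"germline at {germline.locus!r} has {len(G)} distinct alleles; "
            "tri-allelic patterns unsupported"
        )
    if tumor is None:
        return MutationStatus.FAILED
    T = tumor.distinct
    new = T - G
    if new and G <= T:
        return MutationStatus.AADD
    if new:
        return MutationStatus.ANEW
    if len(G) == 2 and len(T & G) == 1:
        return MutationStatus.L
    if T == G and len(G) == 2 and balance is not None and balance < h_min:
        return MutationStatus.PLOH
    return MutationStatus.S


@dataclass
class StatusReport:
    """Per-locus somatic status for one case under one calling regime."""

    case_id: str
    regime: str
    statuses: dict[str, MutationStatus]

    def distribution(self) -> dict[str, tuple[int, float]]:
        """Counts and fractions per merged category (fractions sum to 1)."""
        n = len(self.statuses)
        if n == 0:
            raise ValueError("empty status report")
        counts = Counter(merged_category(s) for s in self.statuses.values())
        return {c: (counts.get(c, 0), counts.get(c, 0) / n)
                for c in MERGED_CATEGORIES}


def classify_case(
    case: PairedCase,
    regime: CallingRegime,
    h_min: float = DEFAULT_H_MIN,
) -> StatusReport:
    """Classify every shared typed locus of a paired case under a regime.

    If the tumor profile carries raw signal it is (re-)called under the
    regime; a raw locus where nothing passes the threshold is Failed.
    Without raw signal the tumor's existing genotype calls are used as-is.
    """
    germ = case.germline.genotypes
    if case.tumor.raw:
        called = call_profile(case.tumor, regime)
        attempted = set(case.tumor.raw)
        shared = sorted(set(germ) & attempted)
        statuses = {}
        for locus in shared:
            tumor_g = called.genotypes.get(locus)
            bal = heterozygote_balance(germ[locus], case.tumor.raw.get(locus))
            statuses[locus] = classify_locus(germ[locus], tumor_g, bal, h_min)
    else:
        shared = sorted(set(germ) & set(case.tumor.genotypes))
        statuses = {
            locus: classify_locus(germ[locus], case.tumor.genotypes[locus],
                                  None, h_min)
            for locus in shared
        }
    if not statuses:
        raise ValueError(f"case {case.case_id!r}: no shared typed loci")
    return StatusReport(case.case_id, regime.name, statuses)


def cohort_distribution(
    reports: Sequence[StatusReport],
) -> dict[str, tuple[int, float]]:
    """Pooled merged-category counts and fractions across cases."""
    counts: Counter = Counter()
    for r in reports:
        counts.update(merged_category(s) for s in r.statuses.values())
    n = sum(counts.values())
    if n == 0:
        raise ValueError("no classified loci")
    return {c: (counts.get(c, 0), counts.get(c, 0) / n)
            for c in MERGED_CATEGORIES}


@dataclass(frozen=True)
class ConcordanceResult:
    concordant: int
    total: int
    percent: float


def genotype_concordance(
    profiles_a: Sequence[STRProfile], profiles_b: Sequence[STRProfile]
) -> ConcordanceResult:
    """Fraction of loci with identical called allele multisets.

    Profiles are paired by ``sample_id``.  The denominator is every locus
    typed on at least one side of a pair; a locus typed on exactly one side
    counts as discordant.  Percent is reported half-up to 2 decimals.
    """
    by_id_b = {p.sample_id: p for p in profiles_b}
    concordant = total = 0
    matched = False
    for pa in profiles_a:
        pb = by_id_b.get(pa.sample_id)
        if pb is None:
            continue
        matched = True
        for locus in pa.typed_loci | pb.typed_loci:
            total += 1
            ga, gb = pa.genotypes.get(locus), pb.genotypes.get(locus)
            if ga is not None and gb is not None and ga.same_call(gb):
                concordant += 1
    if not matched or total == 0:
        raise ValueError("no shared typed loci between the profile sets")
    return ConcordanceResult(concordant, total, percent(concordant, total))


@dataclass
class CrossTab:
    """Status-vs-status contingency table between two calling regimes."""

    counts: pd.DataFrame  # 6x6, rows = regime A status, cols = regime B
    concordant_loci: int  # merged-view (S/pLOH pooled) diagonal total
    total_loci: int

    @property
    def merged_counts(self) -> pd.DataFrame:
        """5x5 view with S and pLOH pooled on both axes."""
        mapping = {s.value: merged_category(s) for s in STATUS_ORDER}
        df = self.counts.rename(index=mapping, columns=mapping)
        df = df.groupby(level=0, sort=False).sum().T
        df = df.groupby(level=0, sort=False).sum().T
        order = [c for c in MERGED_CATEGORIES]
        return df.reindex(index=order, columns=order, fill_value=0)


def status_crosstab(
    reports_a: Sequence[StatusReport], reports_b: Sequence[StatusReport]
) -> CrossTab:
    """Cross-tabulate per-locus statuses between two regimes, case-matched."""
    by_id_b = {r.case_id: r for r in reports_b}
    labels = [s.value for s in STATUS_ORDER]
    counts = pd.DataFrame(0, index=labels, columns=labels)
    total = 0
    for ra in reports_a:
        rb = by_id_b.get(ra.case_id)
        if rb is None:
            raise ValueError(f"case {ra.case_id!r} missing from second report set")
        if set(ra.statuses) != set(rb.statuses):
            raise ValueError(
                f"case {ra.case_id!r}: locus sets differ between regimes"
            )
        for locus, sa in ra.statuses.items():
            sb = rb.statuses[locus]
            counts.loc[sa.value, sb.value] += 1
            total += 1
    merged_diag = sum(
        counts.loc[a.value, b.value]
        for a in STATUS_ORDER for b in STATUS_ORDER
        if merged_category(a) == merged_category(b)
    )
    return CrossTab(counts=counts, concordant_loci=int(merged_diag),
                    total_loci=total)


@dataclass
class RecoveryReport:
    """Germline-allele recovery at mutated loci, per query regime.

    ``per_regime`` maps regime name to ``(recovered, mutated_total,
    percent)``; ``failures`` maps regime name to a per-locus count of
    unrecovered germline alleles (the locus-specific failure breakdown).
    """

    baseline: str
    per_regime: dict[str, tuple[int, int, float]]
    failures: dict[str, Counter]


def germline_recovery(
    cases: Sequence[PairedCase],
    baseline: CallingRegime,
    queries: Sequence[CallingRegime],
    h_min: float = DEFAULT_H_MIN,
) -> RecoveryReport:
    """Count mutated loci whose full germline genotype reappears per regime.

    A locus is "mutated" when its baseline-regime status is neither S nor
    Failed.  It is recovered under a query regime iff every germline allele
    appears among the tumor alleles called under that regime.
    """
    mutated: list[tuple[PairedCase, str]] = []
    for case in cases:
        report = classify_case(case, baseline, h_min)
        for locus, status in report.statuses.items():
            if status not in (MutationStatus.S, MutationStatus.FAILED):
                mutated.append((case, locus))
    per_regime: dict[str, tuple[int, int, float]] = {}
    failures: dict[str, Counter] = {}
    for regime in queries:
        recovered = 0
        fail: Counter = Counter()
        for case, locus in mutated:
            sig = (case.tumor.raw or {}).get(locus)
            if sig is not None:
                tumor_g = call_locus(sig, regime)
            else:
                tumor_g = case.tumor.genotypes.get(locus)
            germ = case.germline.genotypes[locus].distinct
            if tumor_g is not None and germ <= tumor_g.distinct:
                recovered += 1
            else:
                fail[locus] += 1
        n = len(mutated)
        pct = percent(recovered, n) if n else 0.0
        per_regime[regime.name] = (recovered, n, pct)
        failures[regime.name] = fail
    return RecoveryReport(baseline=baseline.name, per_regime=per_regime,
                          failures=failures)
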