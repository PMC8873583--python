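"""Somatic status rules, concordance accounting, and truth-record agreement."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from strsource import (
    CE_DEFAULT,
    NGS_AT,
    NGS_IT,
    TRUTH,
    Genotype,
    MutationStatus,
    STRProfile,
    call_profile,
    classify_case,
    classify_locus,
    cohort_distribution,
    genotype_concordance,
    germline_recovery,
    status_crosstab,
)
from strsource._common import percent
from strsource.somatic_status import StatusReport, heterozygote_balance

G = lambda *alleles: Genotype("FGA", tuple(alleles))  # noqa: E731


@pytest.mark.parametrize(
    "germline, tumor, balance, expected",
    [
        # complete loss of heterozygosity: one germline allele vanishes
        (G("12", "15"), G("12"), None, MutationStatus.L),
        # additional allele: germline retained plus a non-germline allele
        (G("12", "15"), G("12", "15", "17"), None, MutationStatus.AADD),
        # new allele: non-germline allele with a germline allele missing
        (G("12", "15"), G("12", "17"), None, MutationStatus.ANEW),
        # both germline alleles present but imbalanced -> partial LOH
        (G("12", "15"), G("12", "15"), 0.3, MutationStatus.PLOH),
        (G("12", "15"), G("12", "15"), 0.9, MutationStatus.S),
        (G("12", "15"), G("12", "15"), None, MutationStatus.S),
        (G("12", "15"), None, None, MutationStatus.FAILED),
        # homozygous germline: loss is invisible, classified stable
        (G("12"), G("12"), None, MutationStatus.S),
        (G("12", "12"), G("12"), 0.2, MutationStatus.S),
        # new allele beats loss in rule order at a homozygous locus
        (G("12"), G("12", "13"), None, MutationStatus.AADD),
        (G("12"), G("13"), None, MutationStatus.ANEW),
        # a locus with both a gained and a lost allele is Anew, not L
        (G("12", "15"), G("15", "17"), None, MutationStatus.ANEW),
    ],
)
def test_classify_locus_rule_table(germline, tumor, balance, expected):
    assert classify_locus(germline, tumor, balance) == expected


def test_classify_locus_rejects_triallelic_germline():
    with pytest.raises(ValueError, match="tri-allelic"):
        classify_locus(G("12", "13", "14"), G("12"))


alleles = st.sampled_from(["10", "11", "12", "13"])
genotypes = st.builds(
    lambda a: Genotype("FGA", tuple(a)),
    st.lists(alleles, min_size=1, max_size=3, unique=True),
)


@given(
    st.builds(lambda a: Genotype("FGA", tuple(a)),
              st.lists(alleles, min_size=1, max_size=2, unique=True)),
    st.one_of(st.none(), genotypes),
    st.one_of(st.none(), st.floats(0, 1)),
)
def test_classification_is_total(germ, tumor, balance):
    """Every called (germline, tumor) pair maps to exactly one status."""
    status = classify_locus(germ, tumor, balance)
    assert isinstance(status, MutationStatus)


def test_heterozygote_balance(small_cohort):
    from strsource.profiles_io import RawLocusSignal

    sig = RawLocusSignal("FGA", {"12": 900, "15": 300})
    assert heterozygote_balance(G("12", "15"), sig) == pytest.approx(1 / 3)
    assert heterozygote_balance(G("12"), sig) is None
    assert heterozygote_balance(G("12", "15"), None) is None


def _profile(sample_id, calls, regime="NGS-IT"):
    genotypes = {
        locus: Genotype(locus, alleles) for locus, alleles in calls.items()
    }
    return STRProfile(sample_id, "tumor", "NGS", regime, genotypes)


def test_genotype_concordance_counts_and_rounding():
    # 1014 matching loci of 1109 -> 91.43%; 246 of 262 -> 93.89%
    assert percent(1014, 1109) == 91.43
    assert percent(246, 262) == 93.89
    a = _profile("S1", {f"L{i}": ("12", "15") for i in range(6)})
    b_calls = {f"L{i}": ("12", "15") for i in range(5)}
    b_calls["L5"] = ("12",)
    b = _profile("S1", b_calls)
    res = genotype_concordance([a], [b])
    assert (res.concordant, res.total) == (5, 6)
    assert res.percent == 83.33
    assert genotype_concordance([a], [a]).percent == 100.0


def test_concordance_counts_one_sided_loci_as_discordant():
    a = _profile("S1", {"L1": ("12",), "L2": ("9", "10")})
    b = _profile("S1", {"L1": ("12", "12")})  # L2 failed on this platform
    res = genotype_concordance([a], [b])
    assert (res.concordant, res.total) == (1, 2)


def test_concordance_requires_shared_loci():
    a = _profile("S1", {"L1": ("12",)})
    b = _profile("S2", {"L1": ("12",)})
    with pytest.raises(ValueError):
        genotype_concordance([a], [b])


def test_classify_case_matches_truth_record(noisefree_cohort):
    """Without sampling noise the pipeline must reproduce the analytic
    expected status at every locus under every regime."""
    for regime in (CE_DEFAULT, NGS_IT, NGS_AT):
        for case in noisefree_cohort.cases:
            report = classify_case(case, regime,
                                   noisefree_cohort.config.h_min)
            expected = noisefree_cohort.truths[case.case_id].expected[
                regime.name]
            got = {l: s.value for l, s in report.statuses.items()}
            assert got == expected


def test_regime_refinement_transitions(noisefree_cohort):
    """Lowering thresholds only moves L -> {pLOH, S}, Anew -> {Aadd},
    Failed -> anything; never the reverse."""
    allowed = {
        MutationStatus.L: {MutationStatus.L, MutationStatus.PLOH,
                           MutationStatus.S},
        MutationStatus.ANEW: {MutationStatus.ANEW, MutationStatus.AADD},
        MutationStatus.FAILED: set(MutationStatus),
    }
    for case in noisefree_cohort.cases:
        hi = classify_case(case, NGS_IT).statuses
        lo = classify_case(case, NGS_AT).statuses
        for locus, s_hi in hi.items():
            s_lo = lo[locus]
            if s_hi in allowed:
                assert s_lo in allowed[s_hi], (locus, s_hi, s_lo)
            else:
                assert s_lo == s_hi, (locus, s_hi, s_lo)


def test_distribution_sums(noisefree_cohort):
    reports = [classify_case(c, NGS_IT) for c in noisefree_cohort.cases]
    dist = cohort_distribution(reports)
    total = sum(c for c, _ in dist.values())
    assert total == sum(len(r.statuses) for r in reports)
    assert sum(f for _, f in dist.values()) == pytest.approx(1.0)


def test_status_crosstab_conservation(noisefree_cohort):
    ce = [classify_case(c, CE_DEFAULT) for c in noisefree_cohort.cases]
    it = [classify_case(c, NGS_IT) for c in noisefree_cohort.cases]
    tab = status_crosstab(ce, it)
    n_loci = sum(len(r.statuses) for r in ce)
    assert int(tab.counts.to_numpy().sum()) == tab.total_loci == n_loci
    assert int(tab.merged_counts.to_numpy().sum()) == n_loci
    same = status_crosstab(ce, ce)
    off_diag = same.counts.to_numpy().sum() - same.counts.to_numpy().trace()
    assert off_diag == 0
    assert same.concordant_loci == same.total_loci


def test_status_crosstab_requires_matching_loci():
    r1 = StatusReport("c1", "CE", {"L1": MutationStatus.S})
    r2 = StatusReport("c1", "NGS-IT", {"L2": MutationStatus.S})
    with pytest.raises(ValueError):
        status_crosstab([r1], [r2])


def test_germline_recovery_truth_regime_is_total(small_cohort):
    """With tumor content < 1 every germline allele keeps positive signal
    share, so the zero-threshold regime recovers 100% of mutated loci."""
    rec = germline_recovery(small_cohort.cases, CE_DEFAULT,
                            [CE_DEFAULT, NGS_AT, TRUTH])
    recovered, total, pct = rec.per_regime["truth"]
    assert total > 0 and recovered == total and pct == 100.0
    # recovery is monotone in threshold looseness
    assert rec.per_regime["CE"][0] <= rec.per_regime["NGS-AT"][0] <= recovered


def test_crosstab_localizes_threshold_driven_loh(noisefree_cohort):
    """Events whose lost-allele share sits between the CE and IT thresholds
    appear as (CE: L, NGS-IT: S/pLOH) cells, matching the truth record."""
    ce = [classify_case(c, CE_DEFAULT) for c in noisefree_cohort.cases]
    it = [classify_case(c, NGS_IT) for c in noisefree_cohort.cases]
    tab = status_crosstab(ce, it)
    expected = 0
    for case in noisefree_cohort.cases:
        truth = noisefree_cohort.truths[case.case_id]
        for locus in case.germline.genotypes:
            if (truth.expected["CE"][locus] == "L"
                    and truth.expected["NGS-IT"][locus] in ("S", "pLOH")):
                expected += 1
    got = int(tab.counts.loc["L", "S"] + tab.counts.loc["L", "pLOH"])
    assert got == expected
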