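"""The cell-mixture signal model, its analytic status oracle, and cohort
generation."""

from fractions import Fraction

import numpy as np
import pytest

from strsource import (
    CE_DEFAULT,
    NGS_AT,
    NGS_IT,
    Genotype,
    MutationStatus,
    SomaticEvent,
    TumorSimConfig,
    classify_locus,
    call_locus,
    expected_shares,
    expected_status,
    simulate_cohort,
    simulate_tumor_signal,
    synthetic_frequency_table,
    tumor_copy_numbers,
    write_profiles,
)
from strsource.allele_calling import CallingRegime

G = lambda *a: Genotype("FGA", tuple(a))  # noqa: E731


def cell_count_oracle(germ_copies, tumor_copies, n_stromal, n_tumor):
    """Brute-force expected shares by counting allele copies over an explicit
    cell population: ``n_stromal`` stromal cells with the germline copy
    numbers plus ``n_tumor`` tumor cells with the post-event copy numbers."""
    counts = {}
    for a in set(germ_copies) | set(tumor_copies):
        counts[a] = (n_stromal * germ_copies.get(a, 0)
                     + n_tumor * tumor_copies.get(a, 0))
    total = sum(counts.values())
    return {a: Fraction(c, total) for a, c in counts.items()}


def test_event_validation():
    with pytest.raises(ValueError):
        SomaticEvent("FGA", "loh", gained="13")
    with pytest.raises(ValueError):
        SomaticEvent("FGA", "aadd", lost="12")
    with pytest.raises(ValueError):
        SomaticEvent("FGA", "anew_slip", lost="12")
    with pytest.raises(ValueError):
        SomaticEvent("FGA", "gain_of_function")
    with pytest.raises(ValueError):
        tumor_copy_numbers(G("12", "15"), [SomaticEvent("FGA", "loh",
                                                        lost="9")])
    with pytest.raises(ValueError):
        tumor_copy_numbers(G("12", "15"), [SomaticEvent("FGA", "aadd",
                                                        gained="12")])


@pytest.mark.parametrize("f", [0.3, 0.5, 0.75, 0.9])
def test_no_events_gives_germline_shares(f):
    assert expected_shares(G("12", "15"), [], f) == {"12": 0.5, "15": 0.5}
    assert expected_shares(G("12"), [], f) == {"12": 1.0}


def test_loh_share_formula_against_cell_enumeration():
    """LOH of allele 15 from {12,15} at f=0.5: the stromal-only allele keeps
    share (1-f)/(2-f) = 1/3, exactly matching a cell-population count."""
    ev = SomaticEvent("FGA", "loh", lost="15")
    shares = expected_shares(G("12", "15"), [ev], 0.5)
    assert shares["15"] == pytest.approx(1 / 3)
    oracle = cell_count_oracle({"12": 1, "15": 1}, {"12": 1},
                               n_stromal=50, n_tumor=50)
    assert shares["15"] == pytest.approx(float(oracle["15"]))
    assert shares["12"] == pytest.approx(float(oracle["12"]))


@pytest.mark.parametrize(
    "event, ct_total, f, n_stromal, n_tumor",
    [
        (SomaticEvent("FGA", "aadd", gained="17"), 3, 0.6, 40, 60),
        (SomaticEvent("FGA", "anew_slip", lost="15", gained="16"), 2,
         0.8, 20, 80),
        (SomaticEvent("FGA", "loh", lost="12"), 1, 0.9, 10, 90),
    ],
)
def test_share_formula_matches_cell_counts(event, ct_total, f, n_stromal,
                                           n_tumor):
    germ = G("12", "15")
    ct = tumor_copy_numbers(germ, [event])
    assert sum(ct.values()) == ct_total
    shares = expected_shares(germ, [event], f)
    oracle = cell_count_oracle({"12": 1, "15": 1}, dict(ct),
                               n_stromal, n_tumor)
    for a, s in shares.items():
        assert s == pytest.approx(float(oracle[a])), a
    assert sum(shares.values()) == pytest.approx(1.0)


def test_lost_allele_share_vanishes_as_content_grows():
    ev = SomaticEvent("FGA", "loh", lost="15")
    shares = [expected_shares(G("12", "15"), [ev], f)["15"]
              for f in (0.3, 0.6, 0.9, 0.99)]
    assert shares == sorted(shares, reverse=True)
    assert shares[-1] < 0.01


def test_invalid_tumor_content_errors():
    with pytest.raises(ValueError):
        expected_shares(G("12", "15"), [], 1.0)
    with pytest.raises(ValueError):
        expected_shares(G("12", "15"), [], -0.1)


def test_expected_status_threshold_mechanism():
    """A lost-allele share of exactly 2% is below the 4.5% interpretation
    threshold (seen as L) but above the 1.5% analytical threshold (seen as
    pLOH) — the reclassification mechanism."""
    f = 48 / 49  # lost share (1-f)/(2-f) = 1/50
    ev = SomaticEvent("FGA", "loh", lost="15")
    assert expected_shares(G("12", "15"), [ev], f)["15"] == pytest.approx(0.02)
    it = CallingRegime("NGS-IT", 0.045, 0.0)
    at = CallingRegime("NGS-AT", 0.015, 0.0)
    assert expected_status(G("12", "15"), [ev], f, it) == MutationStatus.L
    assert expected_status(G("12", "15"), [ev], f, at) == MutationStatus.PLOH
    assert expected_status(G("12", "15"), [], f, it) == MutationStatus.S


@pytest.mark.parametrize("f", [0.35, 0.5, 0.65, 0.8, 0.9, 0.96])
@pytest.mark.parametrize(
    "events",
    [
        [],
        [SomaticEvent("FGA", "loh", lost="15")],
        [SomaticEvent("FGA", "aadd", gained="17")],
        [SomaticEvent("FGA", "anew_slip", lost="15", gained="16")],
    ],
)
@pytest.mark.parametrize("regime", [CE_DEFAULT, NGS_IT, NGS_AT])
def test_classifier_agrees_with_oracle_on_exact_shares(f, events, regime):
    """On noise-free signals, call + classify equals the analytic oracle for
    every event kind, regime and mixture fraction on the grid."""
    germ = G("12", "15")
    cfg = TumorSimConfig(depth_noise=False, tumor_content=0.9)
    sig = simulate_tumor_signal(germ, events, cfg, np.random.default_rng(0),
                                f=f)
    tumor = call_locus(sig, regime)
    shares = expected_shares(germ, events, f)
    bal = min(shares.get("12", 0), shares.get("15", 0)) / max(
        shares.get("12", 0), shares.get("15", 0))
    got = classify_locus(germ, tumor, bal)
    assert got == expected_status(germ, events, f, regime,
                                  mean_depth=cfg.mean_depth)


def test_signal_depth_moments(rng):
    """Negative-binomial locus depth: mean and variance m + m^2/k (3 sigma)."""
    cfg = TumorSimConfig(mean_depth=500, dispersion=5, tumor_content=0.8)
    totals = np.array([
        simulate_tumor_signal(G("12", "15"), [], cfg, rng, f=0.8).total
        for _ in range(4000)
    ])
    m, k = 500.0, 5.0
    var = m + m * m / k
    assert abs(totals.mean() - m) < 3 * (var / len(totals)) ** 0.5
    assert abs(totals.var() - var) < 0.2 * var


def test_cohort_structure_and_truth(small_cohort):
    cfg = small_cohort.config
    assert len(small_cohort.cases) == cfg.n_cases
    assert len(small_cohort.ui) == cfg.n_ui
    for case in small_cohort.cases:
        truth = small_cohort.truths[case.case_id]
        assert truth.events, "every study-mimicking case harbours >=1 event"
        assert 0.30 <= case.tumor_content < 1.0
        # germline persistence: all germline alleles keep positive share
        for locus, g in case.germline.genotypes.items():
            tumor_truth = case.tumor.genotypes[locus]
            assert g.distinct <= tumor_truth.distinct
        # truth record consistent with the emitted raw signal support
        for locus, ev in truth.events.items():
            if ev.gained:
                assert ev.gained in case.tumor.raw[locus].signal


def test_cohort_seed_determinism(tmp_path):
    cfg = TumorSimConfig(n_cases=3, n_ui=2, seed=9)
    a, b = simulate_cohort(cfg), simulate_cohort(cfg)
    pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_profiles([c.tumor for c in a.cases], pa, "raw")
    write_profiles([c.tumor for c in b.cases], pb, "raw")
    assert pa.read_bytes() == pb.read_bytes()
    assert a.frequencies.freqs == b.frequencies.freqs


def test_event_rate_matches_configuration():
    """With only gain events (which apply at every locus) the number of
    mutated loci is Binomial(n_loci_total, p) — checked at 3 sigma."""
    p = 0.1
    cfg = TumorSimConfig(n_cases=40, n_ui=1, p_loh=0.0, p_aadd=p, p_anew=0.0,
                         ensure_mutated=False, seed=13)
    cohort = simulate_cohort(cfg)
    n_total = cfg.n_cases * len(cfg.panel)
    n_events = sum(len(t.events) for t in cohort.truths.values())
    sigma = (n_total * p * (1 - p)) ** 0.5
    assert abs(n_events - n_total * p) < 3 * sigma


def test_default_config_reproduces_ce_status_proportions():
    """Calibration check: under the default configuration the cohort-level
    CE status distribution lands within +-5 percentage points of the
    reference proportions (S/pLOH 88.10, L 6.49, Aadd 3.79, Anew 0.99)."""
    from strsource import classify_case, cohort_distribution

    cohort = simulate_cohort(TumorSimConfig(seed=2026))
    reports = [classify_case(c, CE_DEFAULT) for c in cohort.cases]
    dist = {k: 100 * f for k, (_, f) in cohort_distribution(reports).items()}
    reference = {"S/pLOH": 88.10, "L": 6.49, "Aadd": 3.79, "Anew": 0.99}
    for cat, ref in reference.items():
        assert abs(dist[cat] - ref) <= 5.0, (cat, dist[cat], ref)


def test_synthetic_frequency_table_is_valid(rng):
    table = synthetic_frequency_table(("FGA", "vWA"), rng)
    for locus in ("FGA", "vWA"):
        f = table[locus]
        assert len(f) == 8
        assert sum(f.values()) == pytest.approx(1.0)
        assert all(6 <= float(a) <= 24 for a in f)


def test_config_validation():
    with pytest.raises(ValueError):
        TumorSimConfig(tumor_content=0.2)
    with pytest.raises(ValueError):
        TumorSimConfig(tumor_content=(0.5, 1.0))
    with pytest.raises(ValueError):
        TumorSimConfig(p_loh=0.9, p_aadd=0.2, p_anew=0.0)
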