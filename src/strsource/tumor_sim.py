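"""Synthetic tumor-cohort generator with an analytic truth record.

Tumor tissue is modelled as a clonal mixture: a fraction ``f`` of tumor
cells carrying per-locus somatic STR events on top of the germline
genotype, diluted by ``1 - f`` stromal (germline) cells.  The expected
signal share of allele ``a`` at a locus is

    share(a) = [(1 - f) * c_g(a) + f * c_t(a)] / [(1 - f) * 2 + f * C_t]

where ``c_g`` is the germline copy number (0, 1 or 2), ``c_t`` the
post-event tumor copy number and ``C_t`` the tumor total copy number.
Event kinds:

* ``loh`` — the tumor clone loses one germline allele (C_t = 1); the lost
  allele survives only in the stromal fraction, with share (1-f)/(2-f).
* ``aadd`` — the clone gains one non-germline allele (C_t = 3).
* ``anew_slip`` — a germline allele is replaced by a +-1-repeat slippage
  neighbour (C_t = 2); the lost allele's stromal share is (1-f)/2.

Observed read counts are a negative-binomial locus depth distributed
multinomially over the expected shares (or the exact shares when depth
noise is disabled).  Because ``f < 1``, every germline allele retains a
positive expected share — the mixture guarantee that a sufficiently low
detection threshold recovers the full germline genotype.  The truth record
stores, per case, the injected events and the analytically expected status
under each regime, serving as the oracle for the classification pipeline.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .allele_calling import (
    CE_DEFAULT,
    NGS_AT,
    NGS_IT,
    TRUTH,
    CallingRegime,
    call_locus,
)
from .kinship_sim import sample_profile, simulate_ui_cohort
from .profiles_io import (
    DEFAULT_PANEL,
    AlleleFrequencyTable,
    Genotype,
    LocusPanel,
    PairedCase,
    RawLocusSignal,
    STRProfile,
    allele_sort_key,
    normalize_allele,
)
from .somatic_status import DEFAULT_H_MIN, MutationStatus, classify_locus

__all__ = [
    "EVENT_KINDS",
    "SomaticEvent",
    "TumorSimConfig",
    "CaseTruth",
    "SyntheticCohort",
    "tumor_copy_numbers",
    "expected_shares",
    "simulate_tumor_signal",
    "expected_status",
    "synthetic_frequency_table",
    "simulate_cohort",
]

EVENT_KINDS = ("loh", "aadd", "anew_slip")


@dataclass(frozen=True)
class SomaticEvent:
    """A clonal somatic STR event at one locus."""

    locus: str
    kind: str
    lost: str | None = None
    gained: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "loh" and (self.lost is None or self.gained is not None):
            raise ValueError("loh events lose exactly one allele")
        if self.kind == "aadd" and (self.gained is None or self.lost is not None):
            raise ValueError("aadd events gain exactly one allele")
        if self.kind == "anew_slip" and (self.lost is None or self.gained is None):
            raise ValueError("anew_slip events lose and gain one allele")


@dataclass
class TumorSimConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults emulate the reference study design: 55 paired carcinoma cases
    (each harbouring at least one somatic STR event), 75 unrelated
    individuals, tumor-cell content uniform on (0.75, 0.95) — pathology
    floors content at 30%, and the predominance of complete-L calls under
    CE places most specimens above its ~20% minor-share detection limit —
    and per-locus clonal event probabilities calibrated analytically to the
    CE status proportions of such cohorts.
    """

    n_cases: int = 55
    n_ui: int = 75
    tumor_content: float | tuple[float, float] = (0.75, 0.95)
    p_loh: float = 0.08
    p_aadd: float = 0.038
    p_anew: float = 0.012
    mean_depth: float = 1000.0
    dispersion: float = 10.0
    slip_steps: tuple[int, ...] = (-1, 1)
    depth_noise: bool = True
    ensure_mutated: bool = True
    h_min: float = DEFAULT_H_MIN
    n_freq_alleles: int = 8
    freq_concentration: float = 1.5
    panel: LocusPanel = field(default_factory=lambda: DEFAULT_PANEL)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_loh + self.p_aadd + self.p_anew > 1:
            raise ValueError("event probabilities sum beyond 1")
        for p in (self.p_loh, self.p_aadd, self.p_anew):
            if p < 0:
                raise ValueError("negative event probability")
        lo, hi = self.content_range
        if not (0.30 <= lo <= hi < 1.0):
            raise ValueError(
                f"tumor content range ({lo}, {hi}) outside [0.30, 1)"
            )
        if self.mean_depth <= 0 or self.dispersion <= 0:
            raise ValueError("depth mean and dispersion must be positive")

    @property
    def content_range(self) -> tuple[float, float]:
        if isinstance(self.tumor_content, (tuple, list)):
            lo, hi = self.tumor_content
            return float(lo), float(hi)
        f = float(self.tumor_content)
        return f, f

    def draw_content(self, rng: np.random.Generator) -> float:
        lo, hi = self.content_range
        return lo if lo == hi else float(rng.uniform(lo, hi))


def tumor_copy_numbers(
    germline: Genotype, events: Sequence[SomaticEvent]
) -> Counter:
    """Per-allele copy number of the tumor clone after applying events."""
    ct: Counter = Counter(germline.as_diploid())
    germ = germline.distinct
    for ev in events:
        if ev.locus != germline.locus:
            raise ValueError(
                f"event at {ev.locus!r} applied to germline locus "
                f"{germline.locus!r}"
            )
        if ev.lost is not None:
            lost = normalize_allele(ev.lost)
            if lost not in germ:
                raise ValueError(f"lost allele {lost!r} not in germline")
            if ev.kind == "loh":
                ct[lost] = 0
            else:  # anew_slip removes a single copy
                ct[lost] -= 1
                if ct[lost] < 0:
                    raise ValueError("allele copy lost twice")
        if ev.gained is not None:
            gained = normalize_allele(ev.gained)
            if gained in germ:
                raise ValueError(f"gained allele {gained!r} already germline")
            ct[gained] += 1
    return +ct


def expected_shares(
    germline: Genotype, events: Sequence[SomaticEvent], f: float
) -> dict[str, float]:
    """Expected signal share per allele under the cell-mixture model."""
    if not 0.0 <= f < 1.0:
        raise ValueError(f"tumor content {f} outside [0, 1)")
    cg = Counter(germline.as_diploid())
    ct = tumor_copy_numbers(germline, events)
    total_t = sum(ct.values())
    denom = (1.0 - f) * 2.0 + f * total_t
    alleles = sorted(set(cg) | set(ct), key=allele_sort_key)
    return {
        a: ((1.0 - f) * cg.get(a, 0) + f * ct.get(a, 0)) / denom
        for a in alleles
    }


def simulate_tumor_signal(
    germline: Genotype,
    events: Sequence[SomaticEvent],
    config: TumorSimConfig,
    rng: np.random.Generator,
    f: float | None = None,
) -> RawLocusSignal:
    """Draw an observed per-allele read-count signal for one tumor locus."""
    if f is None:
        f = config.draw_content(rng)
    shares = expected_shares(germline, events, f)
    alleles = list(shares)
    p = np.asarray([shares[a] for a in alleles], dtype=float)
    if config.depth_noise:
        # NB(mean m, dispersion k): variance m + m^2/k.
        k, m = config.dispersion, config.mean_depth
        total = int(rng.negative_binomial(k, k / (k + m)))
        reads = rng.multinomial(total, p / p.sum()) if total > 0 else np.zeros(len(p))
        signal = {a: float(r) for a, r in zip(alleles, reads)}
    else:
        signal = {a: float(s * config.mean_depth) for a, s in shares.items()}
    return RawLocusSignal(germline.locus, signal)


def expected_status(
    germline: Genotype,
    events: Sequence[SomaticEvent],
    f: float,
    regime: CallingRegime,
    h_min: float = DEFAULT_H_MIN,
    mean_depth: float = 1000.0,
) -> MutationStatus:
    """Status the classifier should emit if observed shares were exact.

    The analytic oracle for threshold-driven transitions: an allele is
    deemed called iff its expected share reaches
    ``max(relative_threshold, absolute_threshold / mean_depth)``.
    """
    shares = expected_shares(germline, events, f)
    rel, abs_ = regime.thresholds_for(germline.locus)
    cut = max(rel, abs_ / mean_depth)
    called = sorted(
        (a for a, s in shares.items() if s > 0 and s >= cut),
        key=allele_sort_key,
    )
    tumor = Genotype(germline.locus, tuple(called)) if called else None
    balance = None
    if germline.is_heterozygous:
        a, b = germline.as_diploid()
        va, vb = shares.get(a, 0.0), shares.get(b, 0.0)
        hi, lo = max(va, vb), min(va, vb)
        balance = (lo / hi) if hi > 0 else None
    return classify_locus(germline, tumor, balance, h_min)


def synthetic_frequency_table(
    loci: Iterable[str],
    rng: np.random.Generator,
    n_alleles: int = 8,
    concentration: float = 1.5,
) -> AlleleFrequencyTable:
    """Dirichlet allele frequencies over a realistic repeat-number range.

    Each locus gets ``n_alleles`` consecutive integer-repeat alleles
    anchored at a random offset in the forensic 6-24 repeat range, with
    Dirichlet(concentration) frequencies (expected heterozygosity ~0.8 at
    the defaults, typical of forensic STR panels).
    """
    freqs: dict[str, dict[str, float]] = {}
    for locus in loci:
        start = int(rng.integers(6, 25 - n_alleles))
        labels = [str(start + i) for i in range(n_alleles)]
        p = rng.dirichlet(np.full(n_alleles, concentration))
        freqs[locus] = {a: float(v) for a, v in zip(labels, p)}
    return AlleleFrequencyTable(freqs)


def _shift_allele(label: str, step: int) -> str:
    whole, _, frac = label.partition(".")
    shifted = int(whole) + step
    if shifted < 1:
        raise ValueError(f"allele shift below 1 repeat from {label!r}")
    return f"{shifted}.{frac}" if frac else str(shifted)


def _pick_gained(
    germline: Genotype, config: TumorSimConfig, rng: np.random.Generator
) -> str:
    """A non-germline allele one slip step away from a germline allele."""
    germ = germline.distinct
    bases = sorted(germ, key=allele_sort_key)
    steps = list(config.slip_steps)
    order = rng.permutation(len(bases) * len(steps))
    combos = [(b, s) for b in bases for s in steps]
    for i in order:
        base, step = combos[int(i)]
        try:
            cand = _shift_allele(base, int(step))
        except ValueError:
            continue
        if cand not in germ:
            return cand
    # widen the step until a free neighbour exists
    step = 2
    while True:
        for s in (step, -step):
            try:
                cand = _shift_allele(bases[0], s)
            except ValueError:
                continue
            if cand not in germ:
                return cand
        step += 1


def _sample_events(
    germline: Genotype, config: TumorSimConfig, rng: np.random.Generator
) -> list[SomaticEvent]:
    """At most one clonal event per locus, by the configured probabilities.

    A loh draw at a homozygous locus yields no event (complete loss is only
    defined against a heterozygous germline), slightly deflating the
    realized loh rate by the homozygosity fraction.
    """
    u = float(rng.random())
    locus = germline.locus
    if u < config.p_loh:
        if not germline.is_heterozygous:
            return []
        pair = germline.as_diploid()
        lost = pair[int(rng.integers(2))]
        return [SomaticEvent(locus, "loh", lost=lost)]
    if u < config.p_loh + config.p_aadd:
        return [SomaticEvent(locus, "aadd",
                             gained=_pick_gained(germline, config, rng))]
    if u < config.p_loh + config.p_aadd + config.p_anew:
        pair = germline.as_diploid()
        lost = pair[int(rng.integers(2))]
        gained = _pick_gained(germline, config, rng)
        return [SomaticEvent(locus, "anew_slip", lost=lost, gained=gained)]
    return []


@dataclass
class CaseTruth:
    """Ground truth for one simulated case: events and expected statuses."""

    case_id: str
    tumor_content: float
    events: dict[str, SomaticEvent]
    expected: dict[str, dict[str, str]]  # regime -> locus -> status value

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "tumor_content": self.tumor_content,
            "events": {l: asdict(e) for l, e in self.events.items()},
            "expected": self.expected,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CaseTruth":
        return cls(
            case_id=d["case_id"],
            tumor_content=float(d["tumor_content"]),
            events={l: SomaticEvent(**e) for l, e in d["events"].items()},
            expected={r: dict(m) for r, m in d["expected"].items()},
        )


@dataclass
class SyntheticCohort:
    """A simulated study: paired cases with truth, UI cohort, frequencies."""

    cases: list[PairedCase]
    truths: dict[str, CaseTruth]
    ui: list[STRProfile]
    frequencies: AlleleFrequencyTable
    config: TumorSimConfig

    def write_truth(self, path, meta: Mapping | None = None) -> None:
        payload = {
            "meta": dict(meta or {}),
            "cases": [self.truths[c.case_id].to_dict() for c in self.cases],
        }
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


_TRUTH_REGIMES = (CE_DEFAULT, NGS_IT, NGS_AT, TRUTH)


def _simulate_case(
    case_id: str,
    config: TumorSimConfig,
    table: AlleleFrequencyTable,
    rng: np.random.Generator,
) -> tuple[PairedCase, CaseTruth]:
    loci = config.panel.loci
    germline = sample_profile(table, rng, f"{case_id}_N", loci)
    f = config.draw_content(rng)
    events: dict[str, SomaticEvent] = {}
    for _ in range(1000):
        events = {}
        for locus in loci:
            evs = _sample_events(germline.genotypes[locus], config, rng)
            if evs:
                events[locus] = evs[0]
        if events or not config.ensure_mutated:
            break
    else:  # pragma: no cover - p(no event)^1000 is negligible
        raise RuntimeError("could not draw a mutated case")
    raw = {}
    genotypes = {}
    for locus in loci:
        g = germline.genotypes[locus]
        evs = [events[locus]] if locus in events else []
        raw[locus] = simulate_tumor_signal(g, evs, config, rng, f=f)
        truth_alleles = [
            a for a, s in expected_shares(g, evs, f).items() if s > 0
        ]
        genotypes[locus] = Genotype(locus, tuple(truth_alleles))
    tumor = STRProfile(
        sample_id=f"{case_id}_T", source="tumor", platform="NGS",
        regime="truth", genotypes=genotypes, raw=raw,
    )
    expected = {
        regime.name: {
            locus: expected_status(
                germline.genotypes[locus],
                [events[locus]] if locus in events else [],
                f, regime, config.h_min, config.mean_depth,
            ).value
            for locus in loci
        }
        for regime in _TRUTH_REGIMES
    }
    case = PairedCase(case_id, germline, tumor, f)
    truth = CaseTruth(case_id, f, events, expected)
    return case, truth


def simulate_cohort(
    config: TumorSimConfig,
    freq_table: AlleleFrequencyTable | None = None,
) -> SyntheticCohort:
    """Generate the full synthetic study, reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    table = freq_table or synthetic_frequency_table(
        config.panel.loci, rng, config.n_freq_alleles,
        config.freq_concentration,
    )
    ui = simulate_ui_cohort(table, config.n_ui, rng, config.panel.loci)
    cases, truths = [], {}
    width = len(str(config.n_cases))
    for i in range(config.n_cases):
        case_id = f"case{i + 1:0{width}d}"
        case, truth = _simulate_case(case_id, config, table, rng)
        cases.append(case)
        truths[case_id] = truth
    return SyntheticCohort(cases=cases, truths=truths, ui=ui,
                           frequencies=table, config=config)
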