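"""Genotype calling from raw per-allele signal under a detection regime.

A regime combines an absolute floor (RFU or reads) with a relative
threshold expressed as a fraction of the locus total signal.  An allele is
called iff its signal reaches ``max(absolute, relative * total)``;
thresholds are inclusive, so lowering either threshold can only add called
alleles, never remove one (the sensitivity-monotonicity that drives the
analytical-threshold reclassification of somatic status).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .profiles_io import Genotype, RawLocusSignal, STRProfile, allele_sort_key

__all__ = [
    "CallingRegime",
    "CE_DEFAULT",
    "NGS_IT",
    "NGS_AT",
    "TRUTH",
    "DEFAULT_REGIMES",
    "call_locus",
    "call_profile",
]


@dataclass(frozen=True)
class CallingRegime:
    """Detection thresholds for allele calling, with per-locus overrides.

    ``relative_threshold`` is a fraction of the locus total signal in
    [0, 1]; ``absolute_threshold`` a minimum raw signal.  ``overrides``
    maps locus name to a ``(relative, absolute)`` pair.
    """

    name: str
    relative_threshold: float
    absolute_threshold: float
    overrides: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rel, abs_ in [(self.relative_threshold, self.absolute_threshold),
                          *self.overrides.values()]:
            if not 0.0 <= rel <= 1.0:
                raise ValueError(f"relative threshold {rel} outside [0, 1]")
            if abs_ < 0:
                raise ValueError(f"negative absolute threshold {abs_}")

    def thresholds_for(self, locus: str) -> tuple[float, float]:
        return self.overrides.get(
            locus, (self.relative_threshold, self.absolute_threshold)
        )


# Default regimes.  CE: the ~20% minor-contributor detection limit of
# capillary electrophoresis plus a 50-RFU analytic floor.  NGS-IT / NGS-AT:
# interpretation and analytical thresholds typical of the UAS ForenSeq
# defaults (4.5% / 1.5% of locus reads, 10-read floor).  "truth" calls every
# allele with positive signal, exposing the exact content of simulated data.
CE_DEFAULT = CallingRegime("CE", relative_threshold=0.20, absolute_threshold=50.0)
NGS_IT = CallingRegime("NGS-IT", relative_threshold=0.045, absolute_threshold=10.0)
NGS_AT = CallingRegime("NGS-AT", relative_threshold=0.015, absolute_threshold=10.0)
TRUTH = CallingRegime("truth", relative_threshold=0.0, absolute_threshold=0.0)

DEFAULT_REGIMES: dict[str, CallingRegime] = {
    r.name: r for r in (CE_DEFAULT, NGS_IT, NGS_AT, TRUTH)
}


def call_locus(signal: RawLocusSignal, regime: CallingRegime) -> Genotype | None:
    """Call a genotype from per-allele signal; ``None`` means no-call.

    An allele passes iff its signal is positive and at least
    ``max(absolute_threshold, relative_threshold * total)``.  A locus where
    no allele passes fails to be typed; a single passing allele is reported
    as a single-allele (homozygous-appearing) genotype.
    """
    rel, abs_ = regime.thresholds_for(signal.locus)
    cut = max(abs_, rel * signal.total)
    called = [
        a for a, v in signal.signal.items() if v > 0 and v >= cut
    ]
    if not called:
        return None
    return Genotype(signal.locus, tuple(sorted(called, key=allele_sort_key)))


def call_profile(profile: STRProfile, regime: CallingRegime) -> STRProfile:
    """Apply :func:`call_locus` to every raw locus of a profile.

    The returned profile records the regime; no-call loci are absent from
    its genotype map.  Raw signal is carried along for balance assessment.
    """
    if not profile.raw:
        raise ValueError(f"profile {profile.sample_id!r} carries no raw signal")
    genotypes = {}
    for locus, sig in profile.raw.items():
        g = call_locus(sig, regime)
        if g is not None:
            genotypes[locus] = g
    platform = "CE" if regime.name == "CE" else profile.platform
    regime_name = regime.name if regime.name in ("CE", "NGS-IT", "NGS-AT", "truth") else None
    return STRProfile(
        sample_id=profile.sample_id, source=profile.source, platform=platform,
        regime=regime_name, genotypes=genotypes, raw=dict(profile.raw),
    )
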