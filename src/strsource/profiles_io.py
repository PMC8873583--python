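"""Domain types and tab-separated I/O for STR genotype data.

Alleles are identified by length-based (repeat-number) nomenclature —
``"12"`` or the microvariant ``"9.3"`` — the only identity under which
capillary-electrophoresis (CE) and sequencing (NGS) genotypes are directly
comparable.  Sequence-string annotations (e.g. ``"13 [TCTA]13"``) are
collapsed to their repeat-number prefix.

File dialect: UTF-8, tab-separated, ``#``-prefixed header comments, ``"."``
for missing values (the layout of a GeneMapper-style genotype export).
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "AlleleParseError",
    "ProfileTableError",
    "FrequencyTableError",
    "normalize_allele",
    "allele_sort_key",
    "Genotype",
    "RawLocusSignal",
    "STRProfile",
    "LocusPanel",
    "AlleleFrequencyTable",
    "PairedCase",
    "FORENSEQ_AUTOSOMAL_LOCI",
    "DEFAULT_PANEL",
    "UNSTABLE_LOCI",
    "read_profiles",
    "write_profiles",
    "read_frequency_table",
    "write_frequency_table",
    "write_table",
]

MISSING = "."

SOURCES = ("germline", "tumor", "simulated")
PLATFORMS = ("CE", "NGS")
REGIMES = ("CE", "NGS-IT", "NGS-AT", "truth")


class AlleleParseError(ValueError):
    """An allele label that cannot be reduced to repeat-number form."""


class ProfileTableError(ValueError):
    """A malformed genotype / raw-signal table."""


class FrequencyTableError(ValueError):
    """A malformed or non-normalizable allele-frequency table."""


# A repeat-number label: integer repeats, optional decimal microvariant,
# optionally followed by whitespace or a bracketed sequence annotation.
_ALLELE_RE = re.compile(r"^\s*(\d+)(?:\.(\d+))?(?:[\s\[].*)?$")


def normalize_allele(label: str) -> str:
    """Return the canonical repeat-number name for an allele label.

    ``"12.0" -> "12"``, ``"9.3" -> "9.3"``, ``"13 [TCTA]13" -> "13"``.
    Idempotent; raises :class:`AlleleParseError` for non-parsable input.
    """
    m = _ALLELE_RE.match(str(label))
    if not m:
        raise AlleleParseError(f"cannot parse allele label {label!r}")
    whole = str(int(m.group(1)))
    frac = (m.group(2) or "").rstrip("0")
    return f"{whole}.{frac}" if frac else whole


def allele_sort_key(label: str) -> float:
    return float(label)


@dataclass(frozen=True)
class Genotype:
    """A called genotype at one locus: a multiset of allele labels.

    A germline genotype holds one distinct allele (homozygote, which may be
    stored as a single label or as a duplicated pair) or two distinct
    alleles.  Tumor genotypes may carry more than two distinct labels.
    """

    locus: str
    alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValueError(f"empty genotype at locus {self.locus!r}")
        norm = tuple(sorted((normalize_allele(a) for a in self.alleles),
                            key=allele_sort_key))
        object.__setattr__(self, "alleles", norm)

    @property
    def distinct(self) -> frozenset[str]:
        return frozenset(self.alleles)

    @property
    def n_distinct(self) -> int:
        return len(self.distinct)

    @property
    def is_heterozygous(self) -> bool:
        return self.n_distinct >= 2

    def as_diploid(self) -> tuple[str, str]:
        """The genotype as an ordered diploid pair (homozygote duplicated)."""
        d = sorted(self.distinct, key=allele_sort_key)
        if len(d) == 1:
            return (d[0], d[0])
        if len(d) == 2:
            return (d[0], d[1])
        raise ValueError(
            f"genotype at {self.locus!r} has {len(d)} distinct alleles; "
            "not a diploid call"
        )

    def as_multiset(self) -> Counter:
        """Multiset of alleles with a single distinct allele expanded to x2.

        This is the canonical form used for genotype equality and for
        identity-by-state counting: a homozygous call contributes two
        copies whether it was recorded as ``("12",)`` or ``("12", "12")``.
        """
        c = Counter(self.alleles)
        if len(c) == 1:
            (a,) = c
            c[a] = 2
        return c

    def same_call(self, other: "Genotype") -> bool:
        return self.as_multiset() == other.as_multiset()


@dataclass(frozen=True)
class RawLocusSignal:
    """Per-allele quantitative signal (read counts or peak heights, RFU)."""

    locus: str
    signal: Mapping[str, float]

    def __post_init__(self) -> None:
        norm = {}
        for a, v in self.signal.items():
            v = float(v)
            if v < 0:
                raise ValueError(
                    f"negative signal {v} for allele {a!r} at {self.locus!r}"
                )
            norm[normalize_allele(a)] = norm.get(normalize_allele(a), 0.0) + v
        object.__setattr__(self, "signal", norm)

    @property
    def total(self) -> float:
        return float(sum(self.signal.values()))

    def get(self, allele: str, default: float = 0.0) -> float:
        return self.signal.get(allele, default)


@dataclass
class STRProfile:
    """One sample's called genotypes (and optionally raw signal) per locus.

    ``regime`` records the detection regime the genotypes were called under:
    CE (50-RFU floor, ~20% minor-share limit), NGS-IT (interpretation
    threshold), NGS-AT (analytical threshold), or ``truth`` for the exact
    allele content of a simulated profile.
    """

    sample_id: str
    source: str = "germline"
    platform: str = "NGS"
    regime: str | None = None
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    raw: dict[str, RawLocusSignal] | None = None

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.regime is not None and self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        for locus, g in self.genotypes.items():
            if g.locus != locus:
                raise ValueError(
                    f"genotype locus {g.locus!r} filed under key {locus!r}"
                )
        if self.raw is not None:
            for locus, s in self.raw.items():
                if s.locus != locus:
                    raise ValueError(
                        f"signal locus {s.locus!r} filed under key {locus!r}"
                    )

    @property
    def typed_loci(self) -> frozenset[str]:
        return frozenset(self.genotypes)


@dataclass(frozen=True)
class LocusPanel:
    """An ordered STR locus panel with an optional unreliable-locus subset."""

    name: str
    loci: tuple[str, ...]
    excluded: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError("panel must contain at least one locus")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("panel locus names must be unique")
        object.__setattr__(self, "loci", tuple(self.loci))
        object.__setattr__(self, "excluded", frozenset(self.excluded))
        extra = self.excluded - set(self.loci)
        if extra:
            raise ValueError(f"excluded loci not in panel: {sorted(extra)}")

    @property
    def scoring_loci(self) -> tuple[str, ...]:
        return tuple(l for l in self.loci if l not in self.excluded)

    def __len__(self) -> int:
        return len(self.loci)


#: The 27 autosomal STR loci of the ForenSeq signature panel — the default
#: scoring panel (pairwise statistics range over 0..27 loci).
FORENSEQ_AUTOSOMAL_LOCI: tuple[str, ...] = (
    "D1S1656", "TPOX", "D2S441", "D2S1338", "D3S1358", "D4S2408", "FGA",
    "D5S818", "CSF1PO", "D6S1043", "D7S820", "D8S1179", "D9S1122",
    "D10S1248", "TH01", "vWA", "D12S391", "D13S317", "Penta E", "D16S539",
    "D17S1301", "D18S51", "D19S433", "D20S482", "D21S11", "Penta D",
    "D22S1045",
)

DEFAULT_PANEL = LocusPanel("forenseq-autosomal-27", FORENSEQ_AUTOSOMAL_LOCI)

#: Loci with a documented tendency to drop germline alleles in tumor tissue
#: even at the analytical threshold; available as an exclusion preset.
UNSTABLE_LOCI: tuple[str, ...] = ("Penta E", "Penta D", "D18S51", "D6S1043")


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele frequency maps, each summing to 1."""

    freqs: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        self.freqs = {
            locus: _validate_locus_freqs(locus, f)
            for locus, f in self.freqs.items()
        }

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(self.freqs)

    def __getitem__(self, locus: str) -> dict[str, float]:
        return self.freqs[locus]

    def __contains__(self, locus: str) -> bool:
        return locus in self.freqs

    @classmethod
    def from_profiles(
        cls, profiles: Sequence[STRProfile], loci: Iterable[str] | None = None
    ) -> "AlleleFrequencyTable":
        """Plug-in allele frequency estimates from called diploid genotypes."""
        counts: dict[str, Counter] = {}
        for p in profiles:
            for locus, g in p.genotypes.items():
                if loci is not None and locus not in set(loci):
                    continue
                counts.setdefault(locus, Counter()).update(g.as_diploid())
        if not counts:
            raise ValueError("no genotypes to estimate frequencies from")
        freqs = {
            locus: {a: n / sum(c.values()) for a, n in c.items()}
            for locus, c in counts.items()
        }
        return cls(freqs)


def _validate_locus_freqs(locus: str, f: Mapping[str, float]) -> dict[str, float]:
    if not f:
        raise FrequencyTableError(f"empty frequency map at locus {locus!r}")
    out = {}
    for a, v in f.items():
        v = float(v)
        if v < 0:
            raise FrequencyTableError(
                f"negative frequency {v} for allele {a!r} at locus {locus!r}"
            )
        out[normalize_allele(a)] = out.get(normalize_allele(a), 0.0) + v
    s = sum(out.values())
    if abs(s - 1.0) <= 1e-9:
        return out
    if abs(s - 1.0) <= 1e-3:
        warnings.warn(
            f"frequencies at locus {locus!r} sum to {s:.6f}; renormalizing",
            stacklevel=3,
        )
        return {a: v / s for a, v in out.items()}
    raise FrequencyTableError(
        f"frequencies at locus {locus!r} sum to {s:.6f}, beyond tolerance"
    )


@dataclass
class PairedCase:
    """A patient's germline profile paired with the tumor profile."""

    case_id: str
    germline: STRProfile
    tumor: STRProfile
    tumor_content: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_content < 1.0:
            raise ValueError(
                f"tumor_content {self.tumor_content} outside [0, 1)"
            )
        if self.germline.source != "germline":
            raise ValueError("germline profile must have source='germline'")
        if self.tumor.source != "tumor":
            raise ValueError("tumor profile must have source='tumor'")


# ---------------------------------------------------------------------------
# Readers / writers

GENOTYPE_COLUMNS = ["sample_id", "source", "platform", "regime", "locus", "alleles"]
RAW_COLUMNS = ["sample_id", "locus", "allele", "signal"]
FREQ_COLUMNS = ["locus", "allele", "freq"]


def _read_tsv(path, expected: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = list(df.columns)
    unknown = [c for c in cols if c not in expected]
    missing = [c for c in expected if c not in cols]
    if unknown:
        raise ProfileTableError(f"unknown column(s) {unknown} in {path}")
    if missing:
        raise ProfileTableError(f"missing column(s) {missing} in {path}")
    return df


def _write_tsv(df: pd.DataFrame, path, header: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_profiles(path, kind: str = "genotypes") -> list[STRProfile]:
    """Read STR profiles from a genotype or raw-signal TSV.

    Genotype tables have one row per sample x locus with ``";"``-joined
    allele labels; raw tables have one row per sample x locus x allele with
    a numeric ``signal`` column.  Missing loci are absent rows (or ``"."``
    alleles), never empty genotypes.
    """
    if kind == "genotypes":
        return _read_genotype_profiles(path)
    if kind == "raw":
        return _read_raw_profiles(path)
    raise ValueError(f"unknown kind {kind!r}")


def _read_genotype_profiles(path) -> list[STRProfile]:
    df = _read_tsv(path, GENOTYPE_COLUMNS)
    seen: set[tuple[str, str]] = set()
    profiles: dict[str, STRProfile] = {}
    for row in df.itertuples(index=False):
        key = (row.sample_id, row.locus)
        if key in seen:
            raise ProfileTableError(f"duplicate row for sample/locus {key}")
        seen.add(key)
        regime = None if row.regime in (MISSING, None) else row.regime
        if row.sample_id not in profiles:
            profiles[row.sample_id] = STRProfile(
                sample_id=row.sample_id, source=row.source,
                platform=row.platform, regime=regime,
            )
        p = profiles[row.sample_id]
        if (p.source, p.platform, p.regime) != (row.source, row.platform, regime):
            raise ProfileTableError(
                f"inconsistent metadata for sample {row.sample_id!r}"
            )
        if row.alleles in (MISSING, None) or pd.isna(row.alleles):
            continue
        alleles = tuple(a for a in str(row.alleles).split(";") if a)
        p.genotypes[row.locus] = Genotype(row.locus, alleles)
    return list(profiles.values())


def _read_raw_profiles(path) -> list[STRProfile]:
    df = _read_tsv(path, RAW_COLUMNS)
    seen: set[tuple[str, str, str]] = set()
    signals: dict[str, dict[str, dict[str, float]]] = {}
    for row in df.itertuples(index=False):
        key = (row.sample_id, row.locus, row.allele)
        if key in seen:
            raise ProfileTableError(f"duplicate raw row {key}")
        seen.add(key)
        signals.setdefault(row.sample_id, {}).setdefault(row.locus, {})[
            row.allele
        ] = float(row.signal)
    out = []
    for sample_id, loci in signals.items():
        raw = {
            locus: RawLocusSignal(locus, sig) for locus, sig in loci.items()
        }
        out.append(
            STRProfile(sample_id=sample_id, source="tumor", platform="NGS",
                       regime=None, genotypes={}, raw=raw)
        )
    return out


def write_profiles(
    profiles: Sequence[STRProfile], path, kind: str = "genotypes",
    header: str | None = None,
) -> None:
    """Write profiles to TSV (inverse of :func:`read_profiles`)."""
    rows = []
    if kind == "genotypes":
        for p in profiles:
            for locus, g in p.genotypes.items():
                rows.append({
                    "sample_id": p.sample_id, "source": p.source,
                    "platform": p.platform,
                    "regime": p.regime if p.regime is not None else MISSING,
                    "locus": locus, "alleles": ";".join(g.alleles),
                })
        df = pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)
    elif kind == "raw":
        for p in profiles:
            for locus, sig in (p.raw or {}).items():
                for a in sorted(sig.signal, key=allele_sort_key):
                    rows.append({
                        "sample_id": p.sample_id, "locus": locus,
                        "allele": a, "signal": sig.signal[a],
                    })
        df = pd.DataFrame(rows, columns=RAW_COLUMNS)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    _write_tsv(df, path, header)


def read_frequency_table(path) -> AlleleFrequencyTable:
    df = _read_tsv(path, FREQ_COLUMNS)
    freqs: dict[str, dict[str, float]] = {}
    for row in df.itertuples(index=False):
        freqs.setdefault(row.locus, {})[row.allele] = float(row.freq)
    return AlleleFrequencyTable(freqs)


def write_frequency_table(
    table: AlleleFrequencyTable, path, header: str | None = None
) -> None:
    rows = [
        {"locus": locus, "allele": a, "freq": f[a]}
        for locus, f in table.freqs.items()
        for a in sorted(f, key=allele_sort_key)
    ]
    _write_tsv(pd.DataFrame(rows, columns=FREQ_COLUMNS), path, header)


def write_table(rows, path, header: str | None = None) -> None:
    """Write an iterable of mappings (or a DataFrame) as a TSV report."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    _write_tsv(df, path, header)
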