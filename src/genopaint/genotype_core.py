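"""Domain model for markers, samples and diploid genotype calls.

A genotype table is a markers x samples matrix of diploid calls, written in
one of three cell-encoding dialects:

* ``SIMPLE``   -- ``A`` / ``B`` / ``H`` / ``N`` (two parental homozygotes,
  heterozygote, missing); carries no phase.
* ``PHASED``   -- VCF-style ``0|0`` / ``1|1`` / ``1|0`` / ``0|1`` / ``.|.``;
  allele order is haplotype order and is preserved.
* ``UNPHASED`` -- ``0/0`` / ``1/1`` / ``1/0`` / ``0/1`` / ``./.``; allele
  order carries no information and heterozygotes are canonicalised to (A, B).

Allele ``A`` is the reference / parent-1 allele (token ``0`` or letter ``A``),
``B`` the alternate / parent-2 allele (token ``1`` or ``B``).  Polyploid calls
(three or more allele fields) and multi-allelic calls (any allele index >= 2)
are unsupported and rejected.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger("genopaint")


class GenotypeError(ValueError):
    """A data-level error in genotype input (bad token, bad table, ...)."""


class AlleleState(enum.Enum):
    A = "A"
    B = "B"
    MISSING = "N"


@dataclass(frozen=True)
class Call:
    """One diploid genotype call: an ordered pair of allele states.

    ``phased`` is True only for calls parsed from the PHASED dialect, where
    hap1/hap2 order is the haplotype order from the caller.  A missing call
    has both haplotypes MISSING; partial missingness is not representable.
    """

    hap1: AlleleState
    hap2: AlleleState
    phased: bool = False

    def __post_init__(self) -> None:
        if (self.hap1 is AlleleState.MISSING) != (self.hap2 is AlleleState.MISSING):
            raise GenotypeError(
                "half-missing calls are not representable: both haplotypes "
                "must be MISSING together"
            )

    @property
    def is_missing(self) -> bool:
        return self.hap1 is AlleleState.MISSING

    @property
    def is_het(self) -> bool:
        return not self.is_missing and self.hap1 is not self.hap2


class EncodingDialect(enum.Enum):
    SIMPLE = "simple"
    PHASED = "phased"
    UNPHASED = "unphased"


# Token tables.  Exactly 4 non-missing tokens + 1 missing token per dialect.
_A, _B, _N = AlleleState.A, AlleleState.B, AlleleState.MISSING

_TOKEN_MAP: dict[EncodingDialect, dict[str, Call]] = {
    EncodingDialect.SIMPLE: {
        "A": Call(_A, _A, phased=False),
        "B": Call(_B, _B, phased=False),
        "H": Call(_A, _B, phased=False),
        "N": Call(_N, _N, phased=False),
    },
    EncodingDialect.PHASED: {
        "0|0": Call(_A, _A, phased=True),
        "1|1": Call(_B, _B, phased=True),
        "1|0": Call(_B, _A, phased=True),
        "0|1": Call(_A, _B, phased=True),
        ".|.": Call(_N, _N, phased=False),
    },
    EncodingDialect.UNPHASED: {
        "0/0": Call(_A, _A, phased=False),
        "1/1": Call(_B, _B, phased=False),
        # unphased heterozygote order is arbitrary: canonicalised to (A, B)
        "1/0": Call(_A, _B, phased=False),
        "0/1": Call(_A, _B, phased=False),
        "./.": Call(_N, _N, phased=False),
    },
}

MISSING_TOKENS: dict[EncodingDialect, str] = {
    EncodingDialect.SIMPLE: "N",
    EncodingDialect.PHASED: ".|.",
    EncodingDialect.UNPHASED: "./.",
}


def dialect_tokens(dialect: EncodingDialect) -> frozenset[str]:
    """The complete token set of a dialect (4 non-missing + 1 missing)."""
    return frozenset(_TOKEN_MAP[dialect])


def _diagnose_token(token: str) -> Optional[str]:
    """Return a specific reason a token is unsupported, or None."""
    for sep in ("|", "/"):
        if sep in token:
            fields = token.split(sep)
            if len(fields) > 2:
                return f"polyploid genotype {token!r} is not supported"
            if any(f.isdigit() and int(f) >= 2 for f in fields):
                return f"multi-allelic genotype {token!r} is not supported"
    return None


def parse_call(token: str, dialect: EncodingDialect, *, context: str = "") -> Call:
    """Parse one genotype cell ``token`` under ``dialect``.

    Raises :class:`GenotypeError` for tokens outside the dialect's set; the
    message names the token, the dialect and ``context`` (e.g. row/column
    coordinates supplied by the CSV reader).
    """
    try:
        return _TOKEN_MAP[dialect][token]
    except KeyError:
        pass
    where = f" at {context}" if context else ""
    reason = _diagnose_token(token)
    if reason is not None:
        raise GenotypeError(f"{reason}{where}")
    raise GenotypeError(
        f"genotype token {token!r}{where} is not valid for the "
        f"{dialect.value} dialect (expected one of "
        f"{sorted(_TOKEN_MAP[dialect])})"
    )


def serialize_call(call: Call, dialect: EncodingDialect) -> str:
    """Inverse of :func:`parse_call` up to unphased-heterozygote order.

    PHASED heterozygotes keep their haplotype order; UNPHASED heterozygotes
    always serialise to the canonical ``0/1``.
    """
    if call.is_missing:
        return MISSING_TOKENS[dialect]
    if dialect is EncodingDialect.SIMPLE:
        return "H" if call.is_het else call.hap1.value
    sep = "|" if dialect is EncodingDialect.PHASED else "/"
    if dialect is EncodingDialect.UNPHASED and call.is_het:
        return "0/1"
    code = {AlleleState.A: "0", AlleleState.B: "1"}
    return f"{code[call.hap1]}{sep}{code[call.hap2]}"


def detect_dialect(tokens: Iterable[str]) -> EncodingDialect:
    """Infer the single dialect whose token set covers all given tokens.

    Detection is order-independent.  Ambiguity (only possible when every
    token is a missing token) and mixed/unknown token sets are errors that
    instruct the user to pass an explicit dialect override.
    """
    seen = set(tokens)
    if not seen:
        raise GenotypeError(
            "no genotype tokens found; pass an explicit dialect override"
        )
    matches = [d for d in EncodingDialect if seen <= dialect_tokens(d)]
    if len(matches) == 1:
        return matches[0]
    if not matches:
        raise GenotypeError(
            f"genotype tokens {sorted(seen)[:8]} match no single encoding "
            "dialect (simple/phased/unphased); tables must use one dialect "
            "throughout -- fix the data or pass an explicit dialect override"
        )
    raise GenotypeError(
        "all genotype calls are missing; the dialect cannot be inferred -- "
        "pass an explicit dialect override"
    )


@dataclass(frozen=True)
class Marker:
    """A genotyped site: chromosome, name, 1-based physical position (bp).

    ``genetic_position`` (cM) is carried when the input CSV provides a
    4-column metadata block but is never used for layout.
    """

    chrom: str
    name: str
    position: int
    genetic_position: Optional[float] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise GenotypeError(
                f"marker {self.name!r}: position must be >= 1 (1-based bp), "
                f"got {self.position}"
            )


@dataclass
class GenotypeTable:
    """Markers x samples matrix of diploid calls plus dialect metadata.

    ``calls[i][j]`` is the call of sample ``samples[j]`` at ``markers[i]``.
    After :func:`normalize_table`, markers are grouped by chromosome with
    non-decreasing positions inside each chromosome, and a validation report
    (marker counts per chromosome) is attached.
    """

    markers: list[Marker]
    samples: list[str]
    calls: list[list[Call]]
    dialect: EncodingDialect
    validation_report: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.calls) != len(self.markers):
            raise GenotypeError(
                f"call matrix has {len(self.calls)} rows for "
                f"{len(self.markers)} markers"
            )
        for i, row in enumerate(self.calls):
            if len(row) != len(self.samples):
                raise GenotypeError(
                    f"call matrix row {i} has {len(row)} entries for "
                    f"{len(self.samples)} samples"
                )

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def chromosomes(self) -> list[str]:
        """Chromosome names in first-appearance order."""
        out: list[str] = []
        for m in self.markers:
            if not out or out[-1] != m.chrom:
                if m.chrom not in out:
                    out.append(m.chrom)
        return out

    def chromosome_calls(self, chrom: str, sample: str) -> list[tuple[Marker, Call]]:
        """(marker, call) pairs for one sample on one chromosome, in order."""
        j = self.samples.index(sample)
        return [
            (m, self.calls[i][j])
            for i, m in enumerate(self.markers)
            if m.chrom == chrom
        ]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.markers == other.markers
            and self.samples == other.samples
            and self.calls == other.calls
            and self.dialect == other.dialect
        )


def _check_unique(names: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for n in names:
        if n in seen and n not in dups:
            dups.append(n)
        seen.add(n)
    if dups:
        raise GenotypeError(f"duplicate {kind} name(s): {dups}")


def normalize_table(raw: GenotypeTable) -> GenotypeTable:
    """Validate and canonically order a parsed table.

    Markers are stably sorted by (chromosome, position) — chromosomes keep
    their first-appearance order, and duplicate (chromosome, position) pairs
    keep their input order.  Duplicate marker or sample names are errors.
    Idempotent.
    """
    _check_unique(raw.samples, "sample")
    _check_unique([m.name for m in raw.markers], "marker")

    chrom_order = {c: k for k, c in enumerate(raw.chromosomes())}
    order = sorted(
        range(len(raw.markers)),
        key=lambda i: (chrom_order[raw.markers[i].chrom], raw.markers[i].position),
    )
    markers = [raw.markers[i] for i in order]
    calls = [list(raw.calls[i]) for i in order]

    report: dict[str, int] = {}
    for m in markers:
        report[m.chrom] = report.get(m.chrom, 0) + 1
    logger.debug("normalized table: %d markers over %d chromosomes",
                 len(markers), len(report))
    return GenotypeTable(
        markers=markers,
        samples=list(raw.samples),
        calls=calls,
        dialect=raw.dialect,
        validation_report=report,
    )
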