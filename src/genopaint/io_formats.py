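"""Readers and writers for the tool's file formats.

Covers the CSV genotype table (the native input), VCF-to-CSV conversion,
FASTA chromosome-length scanning, and the two JSON databases: chromosome
lengths per species and named color sets.

CSV schema
----------
A header row, then 3 or 4 leading metadata columns followed by one column
per sample.  The 3-column form is (chromosome, marker name, physical
position); the 4-column form inserts a genetic position (cM) before the
physical one.  Which form is in use is auto-detected from the header (the
4th header name must look like a physical-position column) and can be
forced with ``meta_columns=``.  Cells are genotype tokens in a single
encoding dialect (see :mod:`genopaint.genotype_core`).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import pandas as pd
from Bio import SeqIO
from cyvcf2 import VCF

from .genotype_core import (
    Call,
    EncodingDialect,
    GenotypeError,
    GenotypeTable,
    Marker,
    detect_dialect,
    normalize_table,
    parse_call,
    serialize_call,
)

logger = logging.getLogger("genopaint")

PathLike = Union[str, Path]

# header names (lower-cased) accepted as a physical-position column
_POSITION_NAMES = {"position", "pos", "physical_position", "physical_pos",
                   "physical position", "bp", "position_bp"}


# ---------------------------------------------------------------------------
# CSV genotype tables


def _detect_meta_columns(header: list[str]) -> int:
    if len(header) >= 4 and header[3].strip().lower() in _POSITION_NAMES:
        return 4
    return 3


def read_genotype_csv(
    path: PathLike,
    dialect_override: Optional[EncodingDialect] = None,
    meta_columns: Optional[int] = None,
) -> GenotypeTable:
    """Read and normalize a genotype table from CSV.

    The encoding dialect is auto-detected from the genotype cells unless
    ``dialect_override`` is given.  Errors carry row/column coordinates
    (1-based, header = row 1).
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False,
                         skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise GenotypeError(f"{path}: empty file (no header row)") from None
    header = [str(c) for c in df.columns]
    if not header or header[0].startswith("Unnamed"):
        raise GenotypeError(f"{path}: missing or malformed header row")
    n_meta = meta_columns if meta_columns is not None else _detect_meta_columns(header)
    if n_meta not in (3, 4):
        raise GenotypeError("meta_columns must be 3 or 4")
    if len(header) <= n_meta:
        raise GenotypeError(f"{path}: no sample columns after the "
                            f"{n_meta} metadata columns")
    samples = header[n_meta:]

    geno = df.iloc[:, n_meta:]
    if dialect_override is not None:
        dialect = dialect_override
    else:
        dialect = detect_dialect(geno.to_numpy().ravel().tolist())

    markers: list[Marker] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        chrom = str(row[0])
        name = str(row[1])
        pos_field = row[n_meta - 1]
        try:
            position = int(str(pos_field))
        except ValueError:
            raise GenotypeError(
                f"{path}: row {i}, column {n_meta}: position {pos_field!r} "
                "is not an integer") from None
        genetic = None
        if n_meta == 4:
            try:
                genetic = float(str(row[2]))
            except ValueError:
                genetic = None
        markers.append(Marker(chrom=chrom, name=name, position=position,
                              genetic_position=genetic))

    calls: list[list[Call]] = []
    for i, row in enumerate(geno.itertuples(index=False), start=2):
        calls.append([
            parse_call(str(tok).strip(), dialect,
                       context=f"{path}: row {i}, column {n_meta + j + 1} "
                               f"(sample {samples[j]!r})")
            for j, tok in enumerate(row)
        ])

    raw = GenotypeTable(markers=markers, samples=samples, calls=calls,
                        dialect=dialect)
    return normalize_table(raw)


def write_genotype_csv(table: GenotypeTable, path: PathLike) -> None:
    """Write a table back to CSV in the schema read_genotype_csv accepts.

    Round-trips exactly, except that unphased heterozygotes serialise to
    the canonical ``0/1``.
    """
    if table.n_markers == 0:
        raise GenotypeError("refusing to write a table with zero markers")
    has_cm = any(m.genetic_position is not None for m in table.markers)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        meta = (["chrom", "marker", "genetic_position", "position"]
                if has_cm else ["chrom", "marker", "position"])
        w.writerow(meta + list(table.samples))
        for i, m in enumerate(table.markers):
            lead = [m.chrom, m.name]
            if has_cm:
                lead.append("" if m.genetic_position is None
                            else repr(m.genetic_position))
            lead.append(m.position)
            w.writerow(lead + [serialize_call(c, table.dialect)
                               for c in table.calls[i]])


# ---------------------------------------------------------------------------
# VCF -> CSV conversion


@dataclass(frozen=True)
class ConversionReport:
    """Bookkeeping for a VCF conversion; categories partition the records."""

    total_records: int
    kept: int
    dropped_multiallelic: int
    dropped_nondiploid: int
    dropped_other: int

    def __post_init__(self) -> None:
        parts = (self.kept + self.dropped_multiallelic
                 + self.dropped_nondiploid + self.dropped_other)
        if parts != self.total_records:
            raise ValueError("conversion report categories do not sum to total")

    def __str__(self) -> str:
        return (f"records: {self.total_records}  kept: {self.kept}  "
                f"dropped multi-allelic: {self.dropped_multiallelic}  "
                f"dropped non-diploid: {self.dropped_nondiploid}  "
                f"dropped other: {self.dropped_other}")


def convert_vcf(vcf_path: PathLike, out_path: PathLike,
                add_marker_names: bool = False) -> ConversionReport:
    """Convert a VCF (GT subfield only) into the CSV genotype-table schema.

    Only biallelic, diploid records are kept: records with more than one ALT
    allele or any allele index >= 2 are counted ``dropped_multiallelic``;
    genotypes with a ploidy other than 2 are counted ``dropped_nondiploid``.
    The output dialect follows the GT separator: ``|`` everywhere -> phased,
    ``/`` everywhere -> unphased; a file mixing the two is an error (phase
    loss must be explicit -- pre-harmonise the VCF, e.g. with bcftools).

    With ``add_marker_names`` marker names are built as ``<chrom>_<pos>``;
    otherwise the VCF ID field is used (or that generated name when ID is
    absent/".").
    """
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    if not samples:
        raise GenotypeError(f"{vcf_path}: VCF has no sample columns")

    total = kept = multi = nondip = other = 0
    phased_seen = unphased_seen = False
    rows: list[tuple[str, str, int, list[str]]] = []

    for var in vcf:
        total += 1
        if len(var.ALT) != 1:
            multi += 1
            continue
        gts = var.genotypes  # per sample: [allele..., phased_flag]
        if gts is None:
            other += 1
            continue
        if any(len(g) != 3 for g in gts):
            nondip += 1
            continue
        if any(a >= 2 for g in gts for a in g[:2]):
            multi += 1
            continue
        tokens: list[str] = []
        row_phased = row_unphased = False
        for a1, a2, ph in gts:
            missing = a1 < 0 or a2 < 0
            sep = "|" if ph else "/"
            if ph:
                row_phased = True
            else:
                row_unphased = True
            if missing:
                tokens.append(f".{sep}.")
            else:
                tokens.append(f"{a1}{sep}{a2}")
        phased_seen |= row_phased
        unphased_seen |= row_unphased
        name = var.ID if (var.ID not in (None, ".")) else f"{var.CHROM}_{var.POS}"
        if add_marker_names:
            name = f"{var.CHROM}_{var.POS}"
        rows.append((var.CHROM, name, var.POS, tokens))
        kept += 1
    vcf.close()

    if phased_seen and unphased_seen:
        raise GenotypeError(
            f"{vcf_path}: mixes phased ('|') and unphased ('/') genotypes; "
            "harmonise the phasing first (e.g. bcftools +fixploidy / "
            "re-phase) rather than silently discarding phase")

    report = ConversionReport(total_records=total, kept=kept,
                              dropped_multiallelic=multi,
                              dropped_nondiploid=nondip, dropped_other=other)
    logger.info("VCF conversion: %s", report)

    with open(out_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["chrom", "marker", "position"] + samples)
        for chrom, name, pos, tokens in rows:
            w.writerow([chrom, name, pos] + tokens)
    return report


# ---------------------------------------------------------------------------
# FASTA chromosome-length scanning


def scan_fasta_lengths(fasta_path: PathLike) -> dict[str, int]:
    """Sequence lengths per record, in file order.

    Record names are the header token up to the first whitespace; lengths
    count sequence characters only (line breaks excluded).
    """
    lengths: dict[str, int] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in lengths:
            raise GenotypeError(
                f"{fasta_path}: duplicate record name {rec.id!r}")
        lengths[rec.id] = len(rec.seq)
    if not lengths:
        raise GenotypeError(f"{fasta_path}: no FASTA records found")
    return lengths


# ---------------------------------------------------------------------------
# chromosome-length database


@dataclass
class ChromLengthDB:
    """species name -> ordered {chromosome -> length (bp)}.

    Chromosome order within a species is insertion order and defines the
    drawing order (so "Chr2" precedes "Chr10" when the source did).
    """

    entries: dict[str, dict[str, int]]

    def __post_init__(self) -> None:
        for sp, chroms in self.entries.items():
            for c, ln in chroms.items():
                if int(ln) < 1:
                    raise GenotypeError(
                        f"species {sp!r}: chromosome {c!r} has non-positive "
                        f"length {ln}")

    @property
    def species(self) -> list[str]:
        return list(self.entries)

    def __contains__(self, species: str) -> bool:
        return species in self.entries

    def __getitem__(self, species: str) -> dict[str, int]:
        try:
            return self.entries[species]
        except KeyError:
            raise GenotypeError(
                f"species {species!r} not in database; available: "
                f"{self.species}") from None

    def save(self, path: PathLike) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.entries, fh, indent=1)
            fh.write("\n")


def load_chrom_length_db(path: Optional[PathLike] = None) -> ChromLengthDB:
    """Load a chromosome-length database; default = the packaged 8-species DB."""
    if path is None:
        src = resources.files("genopaint.data") / "chromosome_length_database.json"
        data = json.loads(src.read_text(encoding="utf-8"))
    else:
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
    return ChromLengthDB(entries={
        sp: {c: int(ln) for c, ln in chroms.items()}
        for sp, chroms in data.items()
    })


def add_species(db: ChromLengthDB, name: str, lengths: dict[str, int],
                *, force: bool = False,
                persist_path: Optional[PathLike] = None) -> ChromLengthDB:
    """Return a new DB with ``name`` added; optionally persist it as JSON.

    Overwriting an existing species requires ``force=True``.
    """
    if not name:
        raise GenotypeError("species name must be non-empty")
    if name in db.entries and not force:
        raise GenotypeError(
            f"species {name!r} already exists in the database; pass force "
            "to overwrite")
    entries = {sp: dict(ch) for sp, ch in db.entries.items()}
    entries[name] = {c: int(ln) for c, ln in lengths.items()}
    new = ChromLengthDB(entries=entries)
    if persist_path is not None:
        new.save(persist_path)
    return new


# ---------------------------------------------------------------------------
# color sets


_ROLE_KEYS = ("A", "B", "het", "missing")


def _parse_hex(color: str, where: str) -> tuple[int, int, int]:
    c = color.strip()
    if c.startswith("#"):
        c = c[1:]
    if len(c) != 6:
        raise GenotypeError(f"{where}: color {color!r} is not #RRGGBB")
    try:
        return tuple(int(c[k:k + 2], 16) for k in (0, 2, 4))  # type: ignore[return-value]
    except ValueError:
        raise GenotypeError(f"{where}: color {color!r} is not #RRGGBB") from None


@dataclass(frozen=True)
class ColorSet:
    """A named set of the four role colors used to paint genotypes."""

    name: str
    colorA: tuple[int, int, int]
    colorB: tuple[int, int, int]
    colorHet: tuple[int, int, int]
    colorMissing: tuple[int, int, int]


def load_color_sets(path: Optional[PathLike] = None) -> dict[str, ColorSet]:
    """Load the color-set registry; default = the packaged file.

    Each set must define all four roles (A, B, het, missing) as #RRGGBB.
    """
    if path is None:
        src = resources.files("genopaint.data") / "color_set.json"
        data = json.loads(src.read_text(encoding="utf-8"))
    else:
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
    registry: dict[str, ColorSet] = {}
    for name, roles in data.items():
        for key in _ROLE_KEYS:
            if key not in roles:
                raise GenotypeError(
                    f"color set {name!r}: missing role {key!r}")
        registry[name] = ColorSet(
            name=name,
            colorA=_parse_hex(roles["A"], f"color set {name!r} role A"),
            colorB=_parse_hex(roles["B"], f"color set {name!r} role B"),
            colorHet=_parse_hex(roles["het"], f"color set {name!r} role het"),
            colorMissing=_parse_hex(roles["missing"],
                                    f"color set {name!r} role missing"),
        )
    return registry
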