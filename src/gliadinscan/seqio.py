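"""Readers and writers for every external artifact of the pipeline.

Sequences travel as FASTA (plain or with ``key=value`` tokens in the
description), epitope catalogs as YAML or TSV, 2-DE spot tables and all
census/summary reports as TSV.  Every reader validates against the domain
invariants and every writer round-trips losslessly through the matching
reader.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ALLOWED_RESIDUES",
    "SPOT_CATEGORIES",
    "ProteinRecord",
    "EpitopeDefinition",
    "SpotRecord",
    "read_fasta",
    "write_fasta",
    "read_epitope_catalog",
    "default_catalog",
    "read_spot_table",
    "write_spot_table",
    "keumkang_spot_listings",
    "write_census_report",
    "read_census_report",
    "write_summary",
    "read_summary",
]

#: 20 canonical amino acids plus X for ambiguous residues.
ALLOWED_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

SPOT_CATEGORIES = ("alpha", "gamma", "omega", "lmw_gs", "non_gluten", "unknown")

MATURITIES = ("precursor", "mature", "unknown")

EPITOPE_DISEASES = ("CD", "WDEIA")

EPITOPE_FAMILIES = ("alpha", "gamma", "omega", "any")


class CatalogError(ValueError):
    """An epitope catalog violated its invariants."""


class FastaError(ValueError):
    """A FASTA file could not be parsed or validated."""


@dataclass(frozen=True)
class ProteinRecord:
    """One input protein sequence with its maturity state.

    ``sequence`` is normalised to uppercase and restricted to the 20
    canonical residues plus X; any other character is a hard error because
    the pipeline operates on clean deduced protein sequences.
    """

    id: str
    sequence: str
    description: str = ""
    maturity: str = "unknown"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.id:
            raise ValueError("protein record requires a non-empty id")
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - ALLOWED_RESIDUES
        if bad:
            raise ValueError(
                f"{self.id}: invalid residue(s) {sorted(bad)}; allowed are the "
                "20 canonical amino acids plus X"
            )
        if self.maturity not in MATURITIES:
            raise ValueError(f"{self.id}: maturity must be one of {MATURITIES}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class EpitopeDefinition:
    """A catalog entry: one immunogenic core sequence.

    ``core_deamidated`` is the tissue-transglutaminase product of the native
    core (glutamine deamidated to glutamate at specific positions); when
    present it must have the same length as the native core and differ only
    at Q->E positions.  ``verified`` marks cores whose sequence is fixed by
    primary data rather than configuration.
    """

    name: str
    core_native: str
    core_deamidated: str | None = None
    disease: str = "CD"
    source_family: str = "any"
    verified: bool = True

    def __post_init__(self) -> None:
        if not self.name:
            raise CatalogError("epitope requires a name")
        if not self.core_native:
            raise CatalogError(f"{self.name}: empty native core")
        for core in (self.core_native, self.core_deamidated or ""):
            bad = set(core) - ALLOWED_RESIDUES
            if bad:
                raise CatalogError(f"{self.name}: invalid residue(s) {sorted(bad)}")
        if self.disease not in EPITOPE_DISEASES:
            raise CatalogError(f"{self.name}: disease must be one of {EPITOPE_DISEASES}")
        if self.source_family not in EPITOPE_FAMILIES:
            raise CatalogError(
                f"{self.name}: source_family must be one of {EPITOPE_FAMILIES}"
            )
        if self.core_deamidated is not None:
            if len(self.core_deamidated) != len(self.core_native):
                raise CatalogError(
                    f"{self.name}: deamidated core length "
                    f"{len(self.core_deamidated)} != native length "
                    f"{len(self.core_native)}"
                )
            for i, (a, b) in enumerate(zip(self.core_native, self.core_deamidated)):
                if a != b and not (a == "Q" and b == "E"):
                    raise CatalogError(
                        f"{self.name}: deamidated core differs from native at "
                        f"position {i} ({a}->{b}); only Q->E substitutions are "
                        "deamidation"
                    )


@dataclass(frozen=True)
class SpotRecord:
    """One 2-DE spot listing.

    ``volume_norm`` is a percentage of total gel volume (0-100 scale).
    ``minor_flag`` marks listings in which the protein is a minor component
    of the spot rather than its predominant protein.
    """

    spot_id: str
    volume_norm: float
    protein_id: str = ""
    category: str = "unknown"
    minor_flag: bool = False

    def __post_init__(self) -> None:
        if not self.spot_id:
            raise ValueError("spot record requires a spot_id")
        if self.volume_norm < 0:
            raise ValueError(f"spot {self.spot_id}: negative volume {self.volume_norm}")
        if self.category not in SPOT_CATEGORIES:
            raise ValueError(
                f"spot {self.spot_id}: unknown category {self.category!r}; "
                f"expected one of {SPOT_CATEGORIES}"
            )


# ---------------------------------------------------------------------------
# FASTA


def _maturity_from_description(description: str) -> str:
    for token in description.split():
        if token.startswith("maturity="):
            value = token.split("=", 1)[1]
            if value not in MATURITIES:
                raise FastaError(f"unknown maturity token {value!r}")
            return value
    return "unknown"


def read_fasta(path: str | Path, strict: bool = True):
    """Read protein records from a FASTA file.

    Sequences are uppercased; maturity is taken from an optional
    ``maturity=`` token in the header, defaulting to ``unknown``.  Malformed
    files and duplicate ids raise :class:`FastaError`.  With
    ``strict=False`` record-level validation failures (e.g. an invalid
    residue) are collected instead of raised and the return value is
    ``(records, [(id, error message), ...])``.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaError(
                        f"{path}: line {lineno}: expected '>' header, got "
                        f"{line.strip()[:30]!r}"
                    )
                break
    records: list[ProteinRecord] = []
    bad: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        try:
            records.append(
                ProteinRecord(
                    id=rec.id,
                    sequence=str(rec.seq),
                    description=rec.description,
                    maturity=_maturity_from_description(rec.description),
                )
            )
        except ValueError as exc:
            if strict:
                raise FastaError(f"{path}: {exc}") from exc
            bad.append((rec.id, str(exc)))
    if strict:
        return records
    return records, bad


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write protein records to FASTA, preserving the maturity token."""
    seq_records = []
    for rec in records:
        desc = rec.description
        if f"maturity={rec.maturity}" not in desc:
            desc = (desc + f" maturity={rec.maturity}").strip()
        seq_records.append(SeqRecord(Seq(rec.sequence), id=rec.id, description=desc))
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Epitope catalogs


def _entry_from_mapping(row: dict) -> EpitopeDefinition:
    deam = row.get("core_deamidated")
    if deam in ("", "-", None) or (isinstance(deam, float) and pd.isna(deam)):
        deam = None
    verified = row.get("verified", True)
    if isinstance(verified, str):
        verified = verified.strip().lower() in ("true", "1", "yes")
    return EpitopeDefinition(
        name=str(row["name"]),
        core_native=str(row["core_native"]).upper(),
        core_deamidated=None if deam is None else str(deam).upper(),
        disease=str(row.get("disease", "CD")),
        source_family=str(row.get("source_family", "any")),
        verified=bool(verified),
    )


def read_epitope_catalog(path: str | Path) -> list[EpitopeDefinition]:
    """Read an epitope catalog from YAML (``.yaml``/``.yml``) or TSV.

    Names must be unique; every entry is validated against the
    :class:`EpitopeDefinition` invariants.
    """
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as handle:
            payload = yaml.safe_load(handle)
        rows = payload["epitopes"] if isinstance(payload, dict) else payload
    else:
        rows = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False).to_dict(
            "records"
        )
    catalog = [_entry_from_mapping(row) for row in rows or []]
    names = [e.name for e in catalog]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise CatalogError(f"{path}: duplicate epitope name(s) {sorted(dupes)}")
    return catalog


def default_catalog() -> list[EpitopeDefinition]:
    """The shipped CD/WDEIA epitope catalog (see ``data/default_epitopes.yaml``)."""
    with resources.files("gliadinscan.data").joinpath("default_epitopes.yaml").open() as fh:
        rows = yaml.safe_load(fh)["epitopes"]
    return [_entry_from_mapping(row) for row in rows]


# ---------------------------------------------------------------------------
# Spot tables

_SPOT_COLUMNS = ["spot_id", "volume_norm", "protein_id", "category", "minor_flag"]


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in ("true", "1", "yes", "*")


def read_spot_table(path: str | Path, unique: bool = True) -> list[SpotRecord]:
    """Read a TSV spot table.

    With ``unique=True`` (the resolved-table contract) a duplicate spot_id is
    an error.  ``unique=False`` admits multiple listings per spot, as in raw
    per-table transcriptions where one spot may carry a predominant and
    several minor-component listings.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    missing = set(_SPOT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    records = [
        SpotRecord(
            spot_id=row["spot_id"],
            volume_norm=float(row["volume_norm"]),
            protein_id=row["protein_id"],
            category=row["category"],
            minor_flag=_parse_bool(row["minor_flag"]),
        )
        for row in df.to_dict("records")
    ]
    if unique:
        ids = [r.spot_id for r in records]
        dupes = {s for s in ids if ids.count(s) > 1}
        if dupes:
            raise ValueError(f"{path}: duplicate spot_id(s) {sorted(dupes)}")
    return records


def write_spot_table(records: Iterable[SpotRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_SPOT_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.spot_id,
                    repr(rec.volume_norm),
                    rec.protein_id,
                    rec.category,
                    str(rec.minor_flag).lower(),
                ]
            )


def keumkang_spot_listings() -> list[SpotRecord]:
    """The shipped transcription of the published 2-DE spot assignments.

    Gliadin listings (spot id, predominant protein, minor-component flags)
    are transcribed from the published identification tables; LMW-GS,
    non-gluten and unidentified spots appear with synthetic placeholder ids
    because only their counts and volume totals are published.  Listings are
    non-unique by design (a spot can carry minor-component listings).
    """
    with resources.as_file(
        resources.files("gliadinscan.data").joinpath("keumkang_spot_listings.tsv")
    ) as path:
        return read_spot_table(path, unique=False)


# ---------------------------------------------------------------------------
# Census and summary reports

_CENSUS_FIXED = [
    "protein_id",
    "family",
    "subtype",
    "genome",
    "cys_count",
    "chain_terminator",
    "has_33mer",
]


def write_census_report(profiles: Sequence, path: str | Path) -> None:
    """Write one TSV row per profile, with one column per catalog epitope.

    Column layout mirrors the published identification tables: structural
    characteristics first, then per-epitope counts.
    """
    epitope_names: list[str] = []
    for prof in profiles:
        for name in prof.epitope_counts:
            if name not in epitope_names:
                epitope_names.append(name)
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_CENSUS_FIXED + epitope_names)
        for prof in profiles:
            genome = prof.genome_call.genome if prof.genome_call else "unknown"
            writer.writerow(
                [
                    prof.protein_id,
                    prof.family,
                    prof.subtype,
                    genome,
                    prof.cys_count,
                    str(prof.chain_terminator).lower(),
                    str(prof.has_33mer).lower(),
                ]
                + [prof.epitope_counts.get(name, 0) for name in epitope_names]
            )


def read_census_report(path: str | Path) -> pd.DataFrame:
    """Read a census TSV back into a DataFrame (epitope columns as ints)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in df.columns:
        if col in ("cys_count",) or col not in _CENSUS_FIXED:
            df[col] = df[col].astype(int)
    for col in ("chain_terminator", "has_33mer"):
        df[col] = df[col].map(_parse_bool)
    return df


def write_summary(summary, path: str | Path) -> None:
    """Write a composition summary TSV (category, n_spots, volume_pct).

    Percentages are printed with 2 decimals, matching the published summary
    table; a total row is appended.
    """
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["category", "n_spots", "volume_pct"])
        for category, n_spots, volume_pct in summary.rows:
            writer.writerow([category, n_spots, f"{volume_pct:.2f}"])
        writer.writerow(["total", summary.total_spots, f"{summary.total_pct:.2f}"])


def read_summary(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"category": str})
    df["n_spots"] = df["n_spots"].astype(int)
    df["volume_pct"] = df["volume_pct"].astype(float)
    return df
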