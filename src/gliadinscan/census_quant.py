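"""Census assembly and 2-DE spot-volume aggregation.

``build_census`` runs the whole per-protein pipeline (mature -> classify ->
segment -> epitope scan -> cysteine census -> 33-mer detection -> genome
call) over a protein collection.  The spot-side operations aggregate
normalized spot volumes (percent of total gel volume) into composition
summaries, predominant-spot counts and per-genome volume shares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from . import classifier as _classifier
from . import motif_engine
from .classifier import (
    ALPHA_REPEAT_MOTIFS,
    OMEGA_MOTIFS,
    ClassifierConfig,
    DEFAULT_CONFIG,
    GliadinProfile,
)
from .genome_assigner import ReferencePanel, assign_genome
from .seqio import SPOT_CATEGORIES, ProteinRecord, SpotRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CompositionSummary",
    "CensusFailure",
    "build_census",
    "resolve_listings",
    "summarize_spots",
    "count_predominant_spots",
    "genome_share",
]

_VOLUME_TOL = 1e-9


@dataclass(frozen=True)
class CompositionSummary:
    """Per-category spot counts and volume percentages, plus totals."""

    rows: tuple[tuple[str, int, float], ...]
    total_spots: int
    total_pct: float

    def __post_init__(self) -> None:
        if any(pct < 0 for _, _, pct in self.rows):
            raise ValueError("volume percentages must be >= 0")
        if sum(n for _, n, _ in self.rows) != self.total_spots:
            raise ValueError("per-category spot counts must sum to total_spots")
        if abs(sum(pct for _, _, pct in self.rows) - self.total_pct) > _VOLUME_TOL:
            raise ValueError("per-category volumes must sum to total_pct")

    def volume_of(self, category: str) -> float:
        for cat, _, pct in self.rows:
            if cat == category:
                return pct
        return 0.0

    def spots_of(self, category: str) -> int:
        for cat, n, _ in self.rows:
            if cat == category:
                return n
        return 0


@dataclass(frozen=True)
class CensusFailure:
    protein_id: str
    error: str


#: Motifs whose counts every census profile carries.
CENSUS_MOTIFS = OMEGA_MOTIFS + ALPHA_REPEAT_MOTIFS


def build_census(
    proteins: Iterable[ProteinRecord],
    catalog: Sequence,
    panel: ReferencePanel | None = None,
    config: ClassifierConfig = DEFAULT_CONFIG,
    deamidation_mode: str = "native_only",
    tie_margin: float = 0.5,
) -> tuple[list[GliadinProfile], list[CensusFailure]]:
    """Profile every protein; failures are logged and collected, not raised."""
    profiles: list[GliadinProfile] = []
    failures: list[CensusFailure] = []
    for protein in proteins:
        try:
            profiles.append(
                profile_protein(
                    protein,
                    catalog,
                    panel=panel,
                    config=config,
                    deamidation_mode=deamidation_mode,
                    tie_margin=tie_margin,
                )
            )
        except Exception as exc:  # keep the batch going, record the failure
            logger.error("census failed for %s: %s", protein.id, exc)
            failures.append(CensusFailure(protein_id=protein.id, error=str(exc)))
    return profiles, failures


def profile_protein(
    protein: ProteinRecord,
    catalog: Sequence,
    panel: ReferencePanel | None = None,
    config: ClassifierConfig = DEFAULT_CONFIG,
    deamidation_mode: str = "native_only",
    tie_margin: float = 0.5,
) -> GliadinProfile:
    """Run the full characterization pipeline on one protein."""
    mature_rec = _classifier.mature(
        protein, config.signature_set, config.signature_search_limit
    )
    seq = mature_rec.sequence
    family, subtype = _classifier.classify(seq, config)
    segmentation = (
        _classifier.segment_domains(seq, family, config)
        if family != "unclassified"
        else None
    )
    hits = motif_engine.scan_epitopes(mature_rec, catalog, deamidation_mode)
    cys = _classifier.count_cysteines(seq)
    motif_counts = {m: motif_engine.count_occurrences(seq, m) for m in CENSUS_MOTIFS}
    motif_counts[motif_engine.GAMMA_REPEAT_LABEL] = motif_engine.count_gamma_repeat(seq)
    profile = GliadinProfile(
        protein_id=protein.id,
        family=family,
        subtype=subtype,
        nterm_signature=seq[:4],
        cys_count=cys,
        chain_terminator=_classifier.flag_chain_terminator(cys),
        has_33mer=bool(motif_engine.detect_33mer(seq)),
        mature_sequence=seq,
        segmentation=segmentation,
        motif_counts=motif_counts,
        epitope_counts=motif_engine.epitope_counts(hits, catalog),
    )
    if family != "unclassified":
        call = assign_genome(profile, panel, tie_margin=tie_margin)
        profile = replace(profile, genome_call=call)
    return profile


# ---------------------------------------------------------------------------
# Spot aggregation


def resolve_listings(listings: Sequence[SpotRecord]) -> list[SpotRecord]:
    """Collapse per-table listings to one record per spot.

    A spot takes the category of its non-minor (predominant) listing; minor
    listings of the same spot are dropped.  A spot with no non-minor
    listing, or with conflicting non-minor listings, is an input error.
    """
    by_spot: dict[str, list[SpotRecord]] = {}
    order: list[str] = []
    for rec in listings:
        if rec.spot_id not in by_spot:
            order.append(rec.spot_id)
        by_spot.setdefault(rec.spot_id, []).append(rec)
    resolved = []
    for spot_id in order:
        predominant = [r for r in by_spot[spot_id] if not r.minor_flag]
        if not predominant:
            raise ValueError(f"spot {spot_id}: no predominant (non-minor) listing")
        if len(predominant) > 1:
            raise ValueError(
                f"spot {spot_id}: conflicting predominant listings "
                f"({[r.category for r in predominant]})"
            )
        resolved.append(predominant[0])
    return resolved


def summarize_spots(spot_table: Sequence[SpotRecord]) -> CompositionSummary:
    """Group spots by category, summing volumes and counting spots.

    Volume is conserved exactly (up to float tolerance): the category sums
    equal the input sum.  Duplicate spot ids are an error — resolve raw
    listings with :func:`resolve_listings` first.
    """
    seen: set[str] = set()
    volumes: dict[str, float] = {}
    counts: dict[str, int] = {}
    for rec in spot_table:
        if rec.spot_id in seen:
            raise ValueError(f"duplicate spot_id {rec.spot_id!r}")
        seen.add(rec.spot_id)
        volumes[rec.category] = volumes.get(rec.category, 0.0) + rec.volume_norm
        counts[rec.category] = counts.get(rec.category, 0) + 1
    categories = [c for c in SPOT_CATEGORIES if c in counts] + [
        c for c in counts if c not in SPOT_CATEGORIES
    ]
    rows = tuple((c, counts[c], volumes[c]) for c in categories)
    return CompositionSummary(
        rows=rows,
        total_spots=sum(counts.values()),
        total_pct=sum(volumes.values()),
    )


def count_predominant_spots(listings: Sequence[SpotRecord], category: str) -> int:
    """Number of distinct spots whose predominant protein is of ``category``.

    Minor-component listings are excluded; conflicting predominant listings
    for one spot are an input error.
    """
    predominant: dict[str, str] = {}
    for rec in listings:
        if rec.minor_flag:
            continue
        prior = predominant.get(rec.spot_id)
        if prior is not None and prior != rec.category:
            raise ValueError(
                f"spot {rec.spot_id}: conflicting predominant categories "
                f"{prior!r} and {rec.category!r}"
            )
        predominant[rec.spot_id] = rec.category
    return sum(1 for cat in predominant.values() if cat == category)


def genome_share(
    spot_table: Sequence[SpotRecord],
    census: Sequence[GliadinProfile],
    family: str,
) -> dict[str, float]:
    """Volume percentage per genome within one gliadin family.

    A spot contributes its volume to the genome of its predominant protein's
    census profile; proteins without a genome call accumulate under
    ``unknown``.  Minor listings are excluded.
    """
    by_id = {p.protein_id: p for p in census}
    shares: dict[str, float] = {}
    for rec in spot_table:
        if rec.minor_flag:
            continue
        prof = by_id.get(rec.protein_id)
        if prof is None or prof.family != family:
            continue
        genome = prof.genome_call.genome if prof.genome_call else "unknown"
        shares[genome] = shares.get(genome, 0.0) + rec.volume_norm
    return shares
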