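"""Genome-of-origin assignment for gliadins of hexaploid bread wheat.

Bread wheat carries three subgenomes (A, B, D); each gliadin is encoded by
one of them.  Two complementary methods are implemented:

* diagnostic motif rules — omega-1,2 gliadins opening with ARE- are
  D-encoded, with ARQ- or KEL- A-encoded; omega-5 gliadins opening with
  SRL-/GRL- are B-encoded; alpha-gliadins containing the CSTT motif are
  B-encoded;
* nearest labelled reference — percent identity under global alignment
  against a genome-labelled reference panel, replacing the usual
  tree-building step with its actual decision content ("which labelled
  cluster is nearest").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from ._align import pairwise_identity
from .classifier import GliadinProfile

__all__ = [
    "GENOMES",
    "PanelEntry",
    "ReferencePanel",
    "GenomeCall",
    "read_reference_panel",
    "write_reference_panel",
    "assign_by_motif",
    "assign_by_reference",
    "nearest_reference",
    "assign_genome",
    "pairwise_identity",
]

GENOMES = ("A", "B", "D")

#: Alpha-gliadin motif diagnostic of the B genome.
CSTT_MOTIF = "CSTT"


@dataclass(frozen=True)
class PanelEntry:
    protein_id: str
    genome: str
    family: str
    sequence: str  # mature sequence

    def __post_init__(self) -> None:
        if self.genome not in GENOMES:
            raise ValueError(f"{self.protein_id}: genome must be one of {GENOMES}")
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty panel sequence")


@dataclass(frozen=True)
class ReferencePanel:
    """Genome-labelled mature reference sequences, grouped by family."""

    entries: tuple[PanelEntry, ...]

    def for_family(self, family: str) -> tuple[PanelEntry, ...]:
        return tuple(e for e in self.entries if e.family == family)

    @property
    def genomes(self) -> set[str]:
        return {e.genome for e in self.entries}


@dataclass(frozen=True)
class GenomeCall:
    """One genome assignment with its method and evidence."""

    protein_id: str
    genome: str  # A, B, D or unknown
    method: str  # "motif" or "reference"
    evidence: str = ""
    identity: float | None = None  # percent, only for method="reference"

    def __post_init__(self) -> None:
        if self.genome not in GENOMES + ("unknown",):
            raise ValueError(f"invalid genome {self.genome!r}")
        if self.method not in ("motif", "reference"):
            raise ValueError(f"invalid method {self.method!r}")
        if self.identity is not None and not 0 <= self.identity <= 100:
            raise ValueError("identity must lie in [0, 100]")


def read_reference_panel(path: str | Path) -> ReferencePanel:
    """Read a reference panel FASTA with ``genome=`` and ``family=`` header keys."""
    from .seqio import read_fasta

    entries = []
    for rec in read_fasta(path):
        keys = dict(
            token.split("=", 1) for token in rec.description.split() if "=" in token
        )
        if "genome" not in keys or "family" not in keys:
            raise ValueError(
                f"panel entry {rec.id}: header must carry genome= and family= keys"
            )
        entries.append(
            PanelEntry(
                protein_id=rec.id,
                genome=keys["genome"],
                family=keys["family"],
                sequence=rec.sequence,
            )
        )
    return ReferencePanel(entries=tuple(entries))


def write_reference_panel(panel: ReferencePanel, path: str | Path) -> None:
    from .seqio import ProteinRecord, write_fasta

    write_fasta(
        [
            ProteinRecord(
                id=e.protein_id,
                sequence=e.sequence,
                description=f"genome={e.genome} family={e.family}",
                maturity="mature",
            )
            for e in panel.entries
        ],
        path,
    )


def assign_by_motif(profile: GliadinProfile) -> GenomeCall:
    """Apply the diagnostic motif rules; returns ``unknown`` when none fire."""
    start = profile.mature_sequence[:3]
    if profile.family == "omega" and profile.subtype == "omega_1_2":
        if start == "ARE":
            return GenomeCall(profile.protein_id, "D", "motif", evidence="ARE- start")
        if start in ("ARQ", "KEL"):
            return GenomeCall(profile.protein_id, "A", "motif", evidence=f"{start}- start")
    if profile.family == "omega" and profile.subtype == "omega_5":
        if start in ("SRL", "GRL"):
            return GenomeCall(profile.protein_id, "B", "motif", evidence=f"{start}- start")
    if profile.family == "alpha" and CSTT_MOTIF in profile.mature_sequence:
        return GenomeCall(profile.protein_id, "B", "motif", evidence="CSTT motif")
    return GenomeCall(profile.protein_id, "unknown", "motif", evidence="no rule fired")


def nearest_reference(
    sequence: str,
    panel: ReferencePanel,
    family: str,
    protein_id: str = "query",
    tie_margin: float = 0.5,
    match: int = 1,
    mismatch: int = 0,
    gap: int = -1,
) -> GenomeCall:
    """Genome of the highest-identity family-matched reference.

    If the top two references from *different* genomes lie within
    ``tie_margin`` identity points of each other, the call is ``unknown``
    (below the resolution at which nearest-reference identity separates the
    subgenomes).  An empty family-matched panel is an error.
    """
    candidates = panel.for_family(family)
    if not candidates:
        raise ValueError(
            f"{protein_id}: reference panel has no entries for family {family!r}"
        )
    scored = sorted(
        ((pairwise_identity(sequence, e.sequence, match, mismatch, gap), e)
         for e in candidates),
        key=lambda t: -t[0],
    )
    best_identity, best = scored[0]
    for identity, other in scored[1:]:
        if other.genome != best.genome:
            if best_identity - identity < tie_margin:
                return GenomeCall(
                    protein_id,
                    "unknown",
                    "reference",
                    evidence=f"tie between {best.protein_id} ({best.genome}) and "
                    f"{other.protein_id} ({other.genome})",
                    identity=best_identity,
                )
            break
    return GenomeCall(
        protein_id, best.genome, "reference", evidence=best.protein_id,
        identity=best_identity,
    )


def assign_by_reference(
    profile: GliadinProfile,
    panel: ReferencePanel,
    tie_margin: float = 0.5,
    match: int = 1,
    mismatch: int = 0,
    gap: int = -1,
) -> GenomeCall:
    """Nearest-reference genome call for a classified profile."""
    return nearest_reference(
        profile.mature_sequence,
        panel,
        profile.family,
        protein_id=profile.protein_id,
        tie_margin=tie_margin,
        match=match,
        mismatch=mismatch,
        gap=gap,
    )


def assign_genome(
    profile: GliadinProfile,
    panel: ReferencePanel | None = None,
    tie_margin: float = 0.5,
) -> GenomeCall:
    """Motif rules first; fall back to nearest-reference when available."""
    call = assign_by_motif(profile)
    if call.genome != "unknown" or panel is None:
        return call
    if not panel.for_family(profile.family):
        return call
    return assign_by_reference(profile, panel, tie_margin=tie_margin)
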