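"""Per-protein structural characterization of gliadins.

Maturation (signal-peptide trimming by mature-start signature), family and
omega-subtype classification, motif-density domain segmentation, cysteine
census and chain-terminator flagging.

The biology behind the rules: alpha-gliadins carry one N-terminal
repetitive domain, two polyglutamine domains and two non-repetitive domains
holding (usually) six cysteines; gamma-gliadins have five domains with a
[PFPQ(1-2)(PQQ)(1-2)] repeat and usually eight cysteines; omega-gliadins
are almost pure repeat (PQQPFP for the omega-1,2 type, FPQQQ/QQIPQQ for
omega-5) and usually cysteine-free.  A gliadin with an odd number of
cysteines has one unpaired thiol, can graft onto the glutenin polymer, and
acts as a chain terminator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from . import motif_engine
from .motif_engine import MotifCount
from .seqio import ProteinRecord

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_SIGNATURES",
    "OMEGA_MOTIFS",
    "ALPHA_REPEAT_MOTIFS",
    "ClassifierConfig",
    "DomainSegmentation",
    "GliadinProfile",
    "mature",
    "count_cysteines",
    "flag_chain_terminator",
    "classify",
    "segment_domains",
]

#: Known mature-start signatures.  ARE/ARQ/KEL open omega-1,2 gliadins,
#: SRL/GRL open omega-5 gliadins, VRV alpha-gliadins, NMQ gamma-gliadins,
#: ISQ/SHI LMW glutenin subunits.  Initiator-Met variants are handled by
#: the earliest-occurrence search.
DEFAULT_SIGNATURES = ("ARE", "ARQ", "KEL", "SRL", "GRL", "VRV", "NMQ", "ISQ", "SHI")

#: Repeat motifs diagnostic of omega-gliadins: PQQPFP for the omega-1,2
#: type, FPQQQ and QQIPQQ for the omega-5 type.
OMEGA_MOTIFS = ("PQQPFP", "FPQQQ", "QQIPQQ")

#: Motifs saturating the alpha-gliadin N-terminal repetitive domain.
ALPHA_REPEAT_MOTIFS = ("PQPQPFP", "PQQPYP", "PQPQLPY")

SEGMENT_LABELS = ("signal", "nterm_signature", "repetitive", "polyglutamine", "nonrepetitive")

FAMILIES = ("alpha", "gamma", "omega", "unclassified")

SUBTYPES = ("omega_1_2", "omega_5", "none")


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable thresholds for maturation, classification and segmentation."""

    signature_set: tuple[str, ...] = DEFAULT_SIGNATURES
    signature_search_limit: int = 40  # residues of precursor scanned for a signature
    window: int = 30  # minimum length of a repetitive segment
    density_threshold: float = 0.4  # min fraction of a repetitive segment covered by motifs
    max_gap: int = 8  # motif matches closer than this merge into one segment
    polyq_min_len: int = 6
    omega_coverage_min: float = 0.2  # min omega-motif coverage for the omega call
    omega_cys_max: int = 1
    gamma_min_repeats: int = 4
    alpha_min_repeats: int = 3
    alpha_cys: tuple[int, int] = (5, 7)  # 6 +/- 1: tolerates the 7-Cys variant
    gamma_cys: tuple[int, int] = (7, 9)  # 8 +/- 1: tolerates the 9-Cys variants


DEFAULT_CONFIG = ClassifierConfig()


@dataclass(frozen=True)
class DomainSegmentation:
    """Contiguous, non-overlapping labelled segments covering a mature sequence."""

    segments: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for label, start, end in self.segments:
            if label not in SEGMENT_LABELS:
                raise ValueError(f"unknown segment label {label!r}")
            if start != prev_end or end <= start:
                raise ValueError("segments must be contiguous, non-empty and ordered")
            prev_end = end

    @property
    def length(self) -> int:
        return self.segments[-1][2] if self.segments else 0

    def of_label(self, label: str) -> list[tuple[int, int]]:
        return [(s, e) for lab, s, e in self.segments if lab == label]


@dataclass(frozen=True)
class GliadinProfile:
    """Everything the pipeline determines about one protein."""

    protein_id: str
    family: str
    subtype: str
    nterm_signature: str
    cys_count: int
    chain_terminator: bool
    has_33mer: bool
    mature_sequence: str
    segmentation: DomainSegmentation | None = None
    motif_counts: dict[str, MotifCount] = field(default_factory=dict)
    epitope_counts: dict[str, int] = field(default_factory=dict)
    genome_call: object | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")
        if self.subtype != "none" and self.family != "omega":
            raise ValueError("subtype is only defined for omega-gliadins")
        if self.chain_terminator != (self.cys_count % 2 == 1 and self.cys_count > 0):
            raise ValueError("chain_terminator must equal (cys_count odd and > 0)")


# ---------------------------------------------------------------------------
# Maturation


def mature(
    protein: ProteinRecord, signature_set: tuple[str, ...] | None = None,
    search_limit: int = 40,
) -> ProteinRecord:
    """Trim a precursor to its mature sequence by mature-start signature.

    The earliest occurrence of any known signature within the first
    ``search_limit`` residues marks the mature N-terminus; everything before
    it (the signal peptide) is removed.  Records already marked mature are
    returned unchanged; when no signature is found the record is returned
    unchanged with maturity ``unknown`` and a warning is logged.
    """
    if protein.maturity == "mature":
        return protein
    signatures = signature_set or DEFAULT_SIGNATURES
    prefix = protein.sequence[: search_limit + max(len(s) for s in signatures)]
    best = None
    for sig in signatures:
        pos = prefix.find(sig)
        if pos != -1 and pos <= search_limit and (best is None or pos < best):
            best = pos
    if best is None:
        logger.warning(
            "%s: no mature-start signature within the first %d residues; "
            "leaving sequence untrimmed",
            protein.id,
            search_limit,
        )
        return replace(protein, maturity="unknown")
    return replace(protein, sequence=protein.sequence[best:], maturity="mature")


def count_cysteines(mature_sequence: str) -> int:
    """Number of cysteine residues in a mature sequence."""
    return mature_sequence.count("C")


def flag_chain_terminator(cys_count: int) -> bool:
    """True iff the cysteine count is odd and positive.

    An even count pairs into intramolecular disulfide bonds; an odd count
    leaves one thiol free to cap glutenin polymer growth.
    """
    if cys_count < 0:
        raise ValueError("cysteine count must be >= 0")
    return cys_count > 0 and cys_count % 2 == 1


# ---------------------------------------------------------------------------
# Classification


def _union_coverage(spans: list[tuple[int, int]]) -> int:
    covered = 0
    last_end = -1
    for start, end in sorted(spans):
        if end <= last_end:
            continue
        covered += end - max(start, last_end)
        last_end = end
    return covered


def _motif_spans(sequence: str, motifs: tuple[str, ...]) -> list[tuple[int, int]]:
    spans = []
    for motif in motifs:
        for pos in motif_engine.find_occurrences(sequence, motif, "overlapping"):
            spans.append((pos, pos + len(motif)))
    return sorted(spans)


def classify(
    mature_protein, config: ClassifierConfig = DEFAULT_CONFIG
) -> tuple[str, str]:
    """Assign a (family, subtype) to a mature sequence.

    Rule cascade, in order:

    1. omega: at most ``omega_cys_max`` cysteines and omega-motif coverage
       above ``omega_coverage_min``.  The subtype follows the dominant
       repeat motif, not the N-terminal signature — an omega-gliadin opening
       with the omega-5 signature SRLL- but dominated by PQQPFP repeats is
       an omega-1,2 gliadin.
    2. gamma: at least ``gamma_min_repeats`` gamma-repeat matches and a
       cysteine count within ``gamma_cys`` (8 +/- 1).
    3. alpha: alpha repeat/33-mer content or the alpha mature-start
       signature, and a cysteine count within ``alpha_cys`` (6 +/- 1).
    4. otherwise unclassified (LMW-GS and non-gluten proteins land here).

    Classification is total and deterministic.
    """
    sequence = mature_protein if isinstance(mature_protein, str) else mature_protein.sequence
    cys = count_cysteines(sequence)

    omega_spans = _motif_spans(sequence, OMEGA_MOTIFS)
    omega_coverage = _union_coverage(omega_spans) / len(sequence)
    if cys <= config.omega_cys_max and omega_coverage >= config.omega_coverage_min:
        n_omega5 = (
            motif_engine.count_occurrences(sequence, "FPQQQ").count
            + motif_engine.count_occurrences(sequence, "QQIPQQ").count
        )
        n_omega12 = motif_engine.count_occurrences(sequence, "PQQPFP").count
        subtype = "omega_5" if n_omega5 > n_omega12 else "omega_1_2"
        return "omega", subtype

    if (
        motif_engine.count_gamma_repeat(sequence).count >= config.gamma_min_repeats
        and config.gamma_cys[0] <= cys <= config.gamma_cys[1]
    ):
        return "gamma", "none"

    alpha_repeats = sum(
        motif_engine.count_occurrences(sequence, m).count for m in ALPHA_REPEAT_MOTIFS
    )
    alpha_like = (
        bool(motif_engine.detect_33mer(sequence))
        or sequence.startswith("VRV")
        or alpha_repeats >= config.alpha_min_repeats
    )
    if alpha_like and config.alpha_cys[0] <= cys <= config.alpha_cys[1]:
        return "alpha", "none"

    return "unclassified", "none"


# ---------------------------------------------------------------------------
# Segmentation

_FAMILY_SEGMENT_MOTIFS = {
    "alpha": ALPHA_REPEAT_MOTIFS,
    "omega": OMEGA_MOTIFS,
}


def _repeat_spans(sequence: str, family: str) -> list[tuple[int, int]]:
    if family == "gamma":
        return motif_engine.gamma_repeat_spans(sequence)
    return _motif_spans(sequence, _FAMILY_SEGMENT_MOTIFS[family])


def segment_domains(
    mature_protein, family: str, config: ClassifierConfig = DEFAULT_CONFIG
) -> DomainSegmentation:
    """Segment a mature sequence into labelled domains.

    Family-motif matches closer than ``max_gap`` merge into candidate
    repetitive segments; candidates at least ``window`` residues long with
    motif coverage at least ``density_threshold`` are kept.  Polyglutamine
    runs outside repetitive segments become ``polyglutamine`` segments, a
    leading known mature-start signature becomes ``nterm_signature``, and
    the remainder is ``nonrepetitive``.  Segments tile the sequence exactly.
    """
    sequence = mature_protein if isinstance(mature_protein, str) else mature_protein.sequence
    if family not in ("alpha", "gamma", "omega"):
        raise ValueError(f"cannot segment family {family!r}")

    spans = _repeat_spans(sequence, family)
    merged: list[list[int]] = []
    for start, end in spans:
        if merged and start - merged[-1][1] <= config.max_gap:
            merged[-1][1] = max(merged[-1][1], end)
            merged[-1][2] += end - start  # rough motif mass for the density check
        else:
            merged.append([start, end, end - start])
    repetitive = [
        (s, e)
        for s, e, _ in merged
        if e - s >= config.window
        and _union_coverage([(a, b) for a, b in spans if a >= s and b <= e]) / (e - s)
        >= config.density_threshold
    ]

    taken = sorted(repetitive)
    polyq = [
        (s, e)
        for s, e in motif_engine.find_polyq_runs(sequence, config.polyq_min_len)
        if not any(rs < e and s < re for rs, re in taken)
    ]

    labelled = [("repetitive", s, e) for s, e in taken] + [
        ("polyglutamine", s, e) for s, e in polyq
    ]
    sig_len = next(
        (len(sig) for sig in config.signature_set if sequence.startswith(sig)), 0
    )
    if sig_len and not any(s < sig_len for _, s, _e in labelled):
        labelled.append(("nterm_signature", 0, sig_len))
    labelled.sort(key=lambda t: t[1])

    segments: list[tuple[str, int, int]] = []
    cursor = 0
    for label, start, end in labelled:
        if start > cursor:
            segments.append(("nonrepetitive", cursor, start))
        segments.append((label, start, end))
        cursor = end
    if cursor < len(sequence):
        segments.append(("nonrepetitive", cursor, len(sequence)))
    return DomainSegmentation(segments=tuple(segments))
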