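"""String-level computation on gliadin sequences.

Everything here is exact substring work: overlapping and non-overlapping
motif counting, epitope scanning with optional deamidated forms, the
degenerate gamma-repeat pattern, polyglutamine run detection, and detection
of the protease-resistant 33-mer peptide.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "THIRTY_THREE_MER",
    "MotifCount",
    "EpitopeHit",
    "find_occurrences",
    "count_occurrences",
    "scan_epitopes",
    "epitope_counts",
    "count_gamma_repeat",
    "find_polyq_runs",
    "detect_33mer",
]

#: The protease-resistant alpha-gliadin peptide carrying multiple
#: overlapping celiac-disease epitopes (one copy of PFPQPQLPY, three
#: overlapping copies of PQPQLPYPQ).
THIRTY_THREE_MER = "LQLQPFPQPQLPYPQPQLPYPQPQLPYPQPQPF"


@dataclass(frozen=True)
class MotifCount:
    """Occurrences of one motif (or pattern label) in one sequence."""

    motif: str
    count: int
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.count != len(self.positions):
            raise ValueError("count must equal the number of positions")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("positions must be strictly increasing")


@dataclass(frozen=True)
class EpitopeHit:
    """One located epitope core match."""

    protein_id: str
    epitope_name: str
    start: int
    end: int
    matched_text: str
    form: str  # "native" or "deamidated"

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.matched_text):
            raise ValueError("end - start must equal the matched core length")
        if self.form not in ("native", "deamidated"):
            raise ValueError("form must be 'native' or 'deamidated'")


def find_occurrences(
    sequence: str, motif: str, mode: str = "overlapping"
) -> tuple[int, ...]:
    """Start positions of ``motif`` in ``sequence``.

    ``overlapping`` reports every start position at which the motif matches;
    ``non_overlapping`` greedily consumes matches from the left, so
    subsequent matches cannot reuse consumed residues.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if mode not in ("overlapping", "non_overlapping"):
        raise ValueError(f"unknown counting mode {mode!r}")
    step = 1 if mode == "overlapping" else len(motif)
    positions: list[int] = []
    i = sequence.find(motif)
    while i != -1:
        positions.append(i)
        i = sequence.find(motif, i + step)
    return tuple(positions)


def count_occurrences(sequence: str, motif: str, mode: str = "overlapping") -> MotifCount:
    """Count motif occurrences; see :func:`find_occurrences` for the modes."""
    positions = find_occurrences(sequence, motif, mode)
    return MotifCount(motif=motif, count=len(positions), positions=positions)


def _sequence_of(protein) -> tuple[str, str]:
    if isinstance(protein, str):
        return "query", protein
    return protein.id, protein.sequence


def scan_epitopes(
    protein, catalog: Sequence, deamidation_mode: str = "native_only"
) -> list[EpitopeHit]:
    """Locate all overlapping epitope-core occurrences in a mature sequence.

    In mode ``both`` the deamidated core (where defined) is scanned as well;
    hits are deduplicated per (epitope, start), native form winning.  The
    default is ``native_only`` because deposited gliadin sequences are
    native: deamidation happens in the gut, not in the genome.
    """
    if deamidation_mode not in ("native_only", "both"):
        raise ValueError(f"unknown deamidation mode {deamidation_mode!r}")
    protein_id, sequence = _sequence_of(protein)
    hits: dict[tuple[str, int], EpitopeHit] = {}
    for epi in catalog:
        cores = [("native", epi.core_native)]
        if deamidation_mode == "both" and epi.core_deamidated is not None:
            cores.append(("deamidated", epi.core_deamidated))
        for form, core in cores:
            for start in find_occurrences(sequence, core, "overlapping"):
                key = (epi.name, start)
                if key in hits and hits[key].form == "native":
                    continue
                hits[key] = EpitopeHit(
                    protein_id=protein_id,
                    epitope_name=epi.name,
                    start=start,
                    end=start + len(core),
                    matched_text=sequence[start : start + len(core)],
                    form=form,
                )
    return sorted(hits.values(), key=lambda h: (h.epitope_name, h.start))


def epitope_counts(hits: Iterable[EpitopeHit], catalog: Sequence) -> dict[str, int]:
    """Per-epitope hit counts, with zero entries for unseen catalog epitopes."""
    counts = {epi.name: 0 for epi in catalog}
    for hit in hits:
        counts[hit.epitope_name] = counts.get(hit.epitope_name, 0) + 1
    return counts


# Expansions of the degenerate gamma-gliadin repeat PFP Q{1,2} (PQQ){1,2},
# longest first so the longest expansion wins at each start.
GAMMA_REPEAT_LABEL = "PFPQ{1,2}(PQQ){1,2}"
_GAMMA_EXPANSIONS = tuple(
    sorted(
        ("PFP" + "Q" * q + "PQQ" * r for q in (1, 2) for r in (1, 2)),
        key=len,
        reverse=True,
    )
)


def count_gamma_repeat(sequence: str) -> MotifCount:
    """Overlapping matches of the degenerate gamma-repeat pattern.

    At each start position the longest matching expansion wins and exactly
    one hit is recorded, so nested expansions are not double-counted.
    """
    positions = [
        i
        for i in range(len(sequence))
        if any(sequence.startswith(exp, i) for exp in _GAMMA_EXPANSIONS)
    ]
    return MotifCount(
        motif=GAMMA_REPEAT_LABEL, count=len(positions), positions=tuple(positions)
    )


def gamma_repeat_spans(sequence: str) -> list[tuple[int, int]]:
    """(start, end) spans of gamma-repeat matches, longest expansion per start."""
    spans = []
    for i in range(len(sequence)):
        for exp in _GAMMA_EXPANSIONS:
            if sequence.startswith(exp, i):
                spans.append((i, i + len(exp)))
                break
    return spans


def find_polyq_runs(sequence: str, min_len: int = 6) -> list[tuple[int, int]]:
    """Maximal runs of consecutive glutamine of length >= ``min_len``.

    Half-open coordinates; runs are maximal and therefore non-overlapping.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(sequence)
    while i < n:
        if sequence[i] == "Q":
            j = i
            while j < n and sequence[j] == "Q":
                j += 1
            if j - i >= min_len:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def detect_33mer(sequence: str) -> list[int]:
    """All overlapping occurrences of the literal 33-mer peptide."""
    return list(find_occurrences(sequence, THIRTY_THREE_MER, "overlapping"))
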