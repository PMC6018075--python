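"""Seeded generators for gliadin-like proteins and 2-DE spot tables.

The protein generator assembles sequences the way real gliadins are built:
signal peptide + mature-start signature + repetitive domain (family repeat
motifs with planted epitope copies) + polyglutamine runs + non-repetitive
domains carrying a controlled number of cysteines.  Every planted quantity
is recorded as exact ground truth.

Exactness guarantee: assembled blocks are separated by >=3-residue spacers
drawn from the alphabet {T, N, V, H, K, D}, which is disjoint from every
residue appearing in the repeat motifs and catalog epitope cores.  A motif
or core occurrence therefore cannot span a block boundary, so the planted
ground truth equals what any exact scanner finds.  Ground-truth counts are
computed analytically per block with a naive substring counter, not with
the motif engine, so generator and engine stay independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .classifier import (
    ALPHA_REPEAT_MOTIFS,
    OMEGA_MOTIFS,
    DomainSegmentation,
    GliadinProfile,
    flag_chain_terminator,
)
from .census_quant import CENSUS_MOTIFS, CompositionSummary
from .genome_assigner import PanelEntry, ReferencePanel
from .motif_engine import GAMMA_REPEAT_LABEL, THIRTY_THREE_MER, MotifCount
from .seqio import SPOT_CATEGORIES, ProteinRecord, SpotRecord, default_catalog

__all__ = [
    "SPACER_ALPHABET",
    "SIGNAL_PEPTIDE",
    "SyntheticSpec",
    "example_spec",
    "random_spec",
    "generate_protein",
    "generate_spot_table",
    "mutate_sequence",
    "make_reference_panel",
]

#: Spacer residues: absent from every repeat motif and catalog epitope core.
SPACER_ALPHABET = "TNVHKD"

#: Fixed cysteine-free signal-peptide template (gliadin signal peptides are
#: cysteine-free, so precursor and mature cysteine censuses agree).  It
#: contains no mature-start signature, so trimming is unambiguous.
SIGNAL_PEPTIDE = "MKTFLILALLAIVATTA"

_GAMMA_EXPANSIONS = tuple(
    sorted(
        ("PFP" + "Q" * q + "PQQ" * r for q in (1, 2) for r in (1, 2)),
        key=len,
        reverse=True,
    )
)

_FAMILY_SIGNATURES = {"alpha": "VRVP", "gamma": "NMQV"}


def _naive_positions(text: str, pattern: str) -> list[int]:
    """All overlapping occurrence starts, by brute-force sliding window."""
    return [
        i
        for i in range(len(text) - len(pattern) + 1)
        if text[i : i + len(pattern)] == pattern
    ]


def _naive_gamma_positions(text: str) -> list[int]:
    return [
        i
        for i in range(len(text))
        if any(text.startswith(exp, i) for exp in _GAMMA_EXPANSIONS)
    ]


@dataclass(frozen=True)
class SyntheticSpec:
    """Blueprint of one synthetic gliadin with exhaustively known truth."""

    family: str
    subtype: str = "none"
    signature: str = ""
    n_repeat_units: dict[str, int] = field(default_factory=dict)
    planted_epitopes: dict[str, int] = field(default_factory=dict)
    cys_count: int = 0
    include_33mer: bool = False
    include_cstt: bool = False  # plant the B-genome diagnostic CSTT motif (alpha)
    polyq_lengths: tuple[int, ...] = ()
    nonrep_lengths: tuple[int, ...] = (20,)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("alpha", "gamma", "omega"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "omega" and self.subtype not in ("omega_1_2", "omega_5"):
            raise ValueError("omega specs need subtype omega_1_2 or omega_5")
        if self.family != "omega" and self.subtype != "none":
            raise ValueError("subtype is only defined for omega specs")
        if any(n < 0 for n in self.n_repeat_units.values()) or any(
            n < 0 for n in self.planted_epitopes.values()
        ):
            raise ValueError("all counts must be >= 0")
        if self.cys_count < 0:
            raise ValueError("cys_count must be >= 0")
        allowed_units = {
            "alpha": set(ALPHA_REPEAT_MOTIFS),
            "gamma": {"gamma_repeat"},
            "omega": set(OMEGA_MOTIFS),
        }[self.family]
        bad = set(self.n_repeat_units) - allowed_units
        if bad:
            raise ValueError(f"{self.family} spec cannot use repeat units {sorted(bad)}")
        if self.subtype == "omega_5" and self.n_repeat_units.get("PQQPFP"):
            raise ValueError("omega_5 specs cannot carry PQQPFP units")
        if self.subtype == "omega_1_2" and (
            self.n_repeat_units.get("FPQQQ") or self.n_repeat_units.get("QQIPQQ")
        ):
            raise ValueError("omega_1_2 specs cannot carry FPQQQ/QQIPQQ units")
        if self.include_33mer and self.family != "alpha":
            raise ValueError("the 33-mer is an alpha-gliadin feature")
        if self.include_cstt and self.family != "alpha":
            raise ValueError("CSTT is an alpha-gliadin genome motif")


def example_spec(family: str, subtype: str = "none", seed: int = 0) -> SyntheticSpec:
    """Realistic default blueprints mirroring canonical study proteins.

    The omega-5 default reproduces the canonical architecture (SRLL- start,
    28 scannable FPQQQ and 10 scannable QQIPQQ once the planted WDEIA cores
    are accounted for, no cysteine); the omega-1,2 default an ARQL- protein
    with 12 scannable PQQPFP copies; alpha and gamma defaults carry the
    usual 6 and 8 cysteines.
    """
    if family == "alpha":
        return SyntheticSpec(
            family="alpha",
            signature="VRVP",
            n_repeat_units={"PQPQPFP": 4, "PQQPYP": 4},
            planted_epitopes={
                "DQ2.5-glia-α1a": 1,
                "DQ2.5-glia-α2": 1,
                "DQ2.5-glia-α3": 1,
            },
            cys_count=6,
            polyq_lengths=(12, 18),
            nonrep_lengths=(25, 30),
            seed=seed,
        )
    if family == "gamma":
        return SyntheticSpec(
            family="gamma",
            signature="NMQV",
            n_repeat_units={"gamma_repeat": 8},
            planted_epitopes={
                "DQ2.5-glia-γ1": 1,
                "DQ2.5-glia-γ3": 1,
                "DQ2.5-glia-γ4c": 2,
                "DQ2.5-glia-γ5": 1,
            },
            cys_count=8,
            polyq_lengths=(16,),
            nonrep_lengths=(24, 20),
            seed=seed,
        )
    if family == "omega" and subtype == "omega_5":
        # WD-1 QQIPQQQ contains one QQIPQQ, WD-2 QQFPQQQ one FPQQQ, so the
        # scannable totals are 16+12=28 FPQQQ and 6+4=10 QQIPQQ.
        return SyntheticSpec(
            family="omega",
            subtype="omega_5",
            signature="SRLL",
            n_repeat_units={"FPQQQ": 16, "QQIPQQ": 6},
            planted_epitopes={"WD-1": 4, "WD-2": 12, "WD-3": 1},
            cys_count=0,
            nonrep_lengths=(12,),
            seed=seed,
        )
    if family == "omega" and subtype == "omega_1_2":
        # DQ2.5-glia-γ4c contains one PQQPFP, so 11 units scan as 12 copies.
        return SyntheticSpec(
            family="omega",
            subtype="omega_1_2",
            signature="ARQL",
            n_repeat_units={"PQQPFP": 11},
            planted_epitopes={"DQ2.5-glia-γ4c": 1, "DQ2.5-glia-γ5": 3},
            cys_count=0,
            nonrep_lengths=(12,),
            seed=seed,
        )
    raise ValueError(f"no example spec for family={family!r} subtype={subtype!r}")


def random_spec(rng: np.random.Generator, seed: int | None = None) -> SyntheticSpec:
    """A random spec within the recoverable regime of the default classifier.

    Unit counts stay above the classification thresholds and cysteine
    counts within the family tolerance bands, so classification and census
    must recover every planted quantity exactly.
    """
    family = rng.choice(["alpha", "gamma", "omega"])
    seed = int(rng.integers(0, 2**31 - 1)) if seed is None else seed
    if family == "alpha":
        return SyntheticSpec(
            family="alpha",
            signature="VRVP",
            n_repeat_units={
                "PQPQPFP": int(rng.integers(3, 8)),
                "PQQPYP": int(rng.integers(0, 6)),
            },
            planted_epitopes={
                "DQ2.5-glia-α1a": int(rng.integers(0, 2)),
                "DQ2.5-glia-α2": int(rng.integers(0, 4)),
                "DQ2.5-glia-α3": int(rng.integers(0, 2)),
                "DQ8-glia-α1": int(rng.integers(0, 2)),
            },
            cys_count=int(rng.integers(5, 8)),
            include_33mer=bool(rng.integers(0, 2)),
            polyq_lengths=(int(rng.integers(6, 15)), int(rng.integers(8, 20))),
            nonrep_lengths=(int(rng.integers(15, 30)), int(rng.integers(15, 30))),
            seed=seed,
        )
    if family == "gamma":
        return SyntheticSpec(
            family="gamma",
            signature="NMQV",
            n_repeat_units={"gamma_repeat": int(rng.integers(4, 12))},
            planted_epitopes={
                "DQ2.5-glia-γ1": int(rng.integers(0, 2)),
                "DQ2.5-glia-γ2": int(rng.integers(0, 2)),
                "DQ2.5-glia-γ3": int(rng.integers(0, 2)),
                "DQ2.5-glia-γ4c": int(rng.integers(0, 9)),
                "DQ2.5-glia-γ5": int(rng.integers(0, 5)),
            },
            cys_count=int(rng.integers(7, 10)),
            polyq_lengths=(int(rng.integers(8, 20)),),
            nonrep_lengths=(int(rng.integers(15, 30)), int(rng.integers(12, 25))),
            seed=seed,
        )
    subtype = rng.choice(["omega_5", "omega_1_2"])
    if subtype == "omega_5":
        return SyntheticSpec(
            family="omega",
            subtype="omega_5",
            signature=str(rng.choice(["SRLL", "GRLL"])),
            n_repeat_units={
                "FPQQQ": int(rng.integers(10, 30)),
                "QQIPQQ": int(rng.integers(4, 12)),
            },
            planted_epitopes={
                "WD-1": int(rng.integers(0, 5)),
                "WD-2": int(rng.integers(0, 13)),
            },
            cys_count=int(rng.integers(0, 2)),
            nonrep_lengths=(int(rng.integers(8, 16)),),
            seed=seed,
        )
    return SyntheticSpec(
        family="omega",
        subtype="omega_1_2",
        signature=str(rng.choice(["AREL", "ARQL", "KELQ"])),
        n_repeat_units={"PQQPFP": int(rng.integers(10, 25))},
        planted_epitopes={
            "DQ2.5-glia-ω1": int(rng.integers(0, 2)),
            "DQ2.5-glia-ω2": int(rng.integers(0, 2)),
            "DQ2.5-glia-γ4c": int(rng.integers(0, 8)),
            "DQ2.5-glia-γ5": int(rng.integers(0, 10)),
        },
        cys_count=int(rng.integers(0, 2)),
        nonrep_lengths=(int(rng.integers(8, 16)),),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Protein assembly


def _spacer(rng: np.random.Generator, length: int = 3) -> str:
    return "".join(rng.choice(list(SPACER_ALPHABET), size=length))


def _nonrep_block(rng: np.random.Generator, length: int, n_cys: int) -> str:
    letters = list(rng.choice(list(SPACER_ALPHABET), size=max(length, n_cys)))
    if n_cys:
        for pos in rng.choice(len(letters), size=n_cys, replace=False):
            letters[pos] = "C"
    return "".join(letters)


def _repeat_unit_texts(spec: SyntheticSpec, rng: np.random.Generator) -> list[str]:
    units: list[str] = []
    for motif, n in sorted(spec.n_repeat_units.items()):
        if motif == "gamma_repeat":
            units.extend(
                str(rng.choice(_GAMMA_EXPANSIONS)) for _ in range(n)
            )
        else:
            units.extend([motif] * n)
    return units


def generate_protein(
    spec: SyntheticSpec, catalog: Sequence | None = None
) -> tuple[ProteinRecord, GliadinProfile]:
    """Assemble a precursor protein and its exact ground-truth profile.

    Deterministic under ``spec.seed``.  The returned record is the
    precursor (signal peptide attached, maturity ``precursor``); the
    ground-truth profile describes the mature sequence.
    """
    catalog = list(catalog) if catalog is not None else default_catalog()
    cores = {e.name: e.core_native for e in catalog}
    missing = set(spec.planted_epitopes) - set(cores)
    if missing:
        raise ValueError(f"planted epitopes not in catalog: {sorted(missing)}")

    rng = np.random.default_rng(spec.seed)
    signature = spec.signature or _FAMILY_SIGNATURES.get(spec.family, "VRVP")

    rep_items = _repeat_unit_texts(spec, rng)
    for name, copies in sorted(spec.planted_epitopes.items()):
        rep_items.extend([cores[name]] * copies)
    if spec.include_33mer:
        rep_items.append(THIRTY_THREE_MER)
    rep_items = [rep_items[i] for i in rng.permutation(len(rep_items))]

    # cysteines are distributed over the non-repetitive blocks
    n_blocks = max(len(spec.nonrep_lengths), 1)
    cys_per_block = [spec.cys_count // n_blocks] * n_blocks
    for i in range(spec.cys_count % n_blocks):
        cys_per_block[i] += 1
    if spec.include_cstt:
        cys_per_block[0] = max(cys_per_block[0] - 1, 0)
    nonrep_items = [
        _nonrep_block(rng, length, n_cys)
        for length, n_cys in zip(spec.nonrep_lengths, cys_per_block)
    ]
    if spec.include_cstt and nonrep_items:
        nonrep_items[0] = "CSTT" + nonrep_items[0]
    polyq_items = ["Q" * n for n in spec.polyq_lengths]

    # block order follows the family's domain architecture
    blocks: list[tuple[str, list[str]]] = [("nterm_signature", [signature])]
    if spec.family == "alpha":
        blocks.append(("repetitive", rep_items))
        for i, pq in enumerate(polyq_items):
            blocks.append(("polyglutamine", [pq]))
            if i < len(nonrep_items):
                blocks.append(("nonrepetitive", [nonrep_items[i]]))
        for item in nonrep_items[len(polyq_items):]:
            blocks.append(("nonrepetitive", [item]))
    elif spec.family == "gamma":
        blocks.append(("repetitive", rep_items))
        if nonrep_items:
            blocks.append(("nonrepetitive", [nonrep_items[0]]))
        for pq in polyq_items:
            blocks.append(("polyglutamine", [pq]))
        for item in nonrep_items[1:]:
            blocks.append(("nonrepetitive", [item]))
    else:
        blocks.append(("repetitive", rep_items))
        for item in nonrep_items:
            blocks.append(("nonrepetitive", [item]))
        for pq in polyq_items:
            blocks.append(("polyglutamine", [pq]))

    # assemble: spacers inside a block and between blocks; block-internal
    # spacers belong to the block's segment
    parts: list[str] = []
    item_offsets: list[tuple[int, str]] = []  # (offset, text) of every planted item
    segments: list[tuple[str, int, int]] = []
    cursor = 0

    def _append(text: str) -> None:
        nonlocal cursor
        parts.append(text)
        cursor += len(text)

    for b, (label, items) in enumerate(blocks):
        if b > 0:
            _append(_spacer(rng))
        if not items:
            continue
        start = cursor
        for k, item in enumerate(items):
            if k > 0:
                _append(_spacer(rng))
            item_offsets.append((cursor, item))
            _append(item)
        if cursor > start:
            segments.append((label, start, cursor))

    mature_seq = "".join(parts)

    # spacer runs between labelled blocks become nonrepetitive filler
    filled: list[tuple[str, int, int]] = []
    prev_end = 0
    for label, start, end in segments:
        if start > prev_end:
            filled.append(("nonrepetitive", prev_end, start))
        filled.append((label, start, end))
        prev_end = end
    if prev_end < len(mature_seq):
        filled.append(("nonrepetitive", prev_end, len(mature_seq)))
    merged: list[tuple[str, int, int]] = []
    for label, start, end in filled:
        if merged and merged[-1][0] == label and merged[-1][2] == start:
            merged[-1] = (label, merged[-1][1], end)
        else:
            merged.append((label, start, end))

    # analytic ground truth: counts summed over planted items (spacers make
    # cross-item occurrences impossible)
    motif_counts: dict[str, MotifCount] = {}
    for motif in CENSUS_MOTIFS:
        positions = sorted(
            off + p for off, text in item_offsets for p in _naive_positions(text, motif)
        )
        motif_counts[motif] = MotifCount(motif, len(positions), tuple(positions))
    gamma_positions = sorted(
        off + p for off, text in item_offsets for p in _naive_gamma_positions(text)
    )
    motif_counts[GAMMA_REPEAT_LABEL] = MotifCount(
        GAMMA_REPEAT_LABEL, len(gamma_positions), tuple(gamma_positions)
    )
    epitope_counts = {
        epi.name: sum(
            len(_naive_positions(text, epi.core_native)) for _, text in item_offsets
        )
        for epi in catalog
    }

    truth = GliadinProfile(
        protein_id=f"syn-{spec.family}-{spec.seed}",
        family=spec.family,
        subtype=spec.subtype,
        nterm_signature=mature_seq[:4],
        cys_count=spec.cys_count,
        chain_terminator=flag_chain_terminator(spec.cys_count),
        has_33mer=spec.include_33mer,
        mature_sequence=mature_seq,
        segmentation=DomainSegmentation(segments=tuple(merged)),
        motif_counts=motif_counts,
        epitope_counts=epitope_counts,
    )
    record = ProteinRecord(
        id=truth.protein_id,
        sequence=SIGNAL_PEPTIDE + mature_seq,
        description=f"synthetic {spec.family} gliadin seed={spec.seed}",
        maturity="precursor",
    )
    return record, truth


# ---------------------------------------------------------------------------
# Mutation and reference panels


def mutate_sequence(
    sequence: str, rate: float, rng: np.random.Generator
) -> str:
    """Substitute a ``rate`` fraction of positions with random other residues."""
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0, 1]")
    n_mut = int(round(rate * len(sequence)))
    if n_mut == 0:
        return sequence
    letters = list(sequence)
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    for pos in rng.choice(len(letters), size=n_mut, replace=False):
        choices = alphabet.replace(letters[pos], "")
        letters[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(letters)


def make_reference_panel(family: str, seed: int = 0) -> ReferencePanel:
    """A synthetic genome-labelled mature reference panel for one family.

    One entry per genome, with genome-consistent diagnostic features (ARE-/
    ARQ- omega-1,2 starts, SRLL- omega-5 start, CSTT in the B-genome alpha)
    and diverged repeat/domain structure between genomes.
    """
    specs: dict[str, SyntheticSpec]
    if family == "alpha":
        base = example_spec("alpha")
        specs = {
            "A": SyntheticSpec(
                **{**base.__dict__, "seed": seed * 3 + 1,
                   "n_repeat_units": {"PQPQPFP": 5, "PQQPYP": 3},
                   "polyq_lengths": (10, 14)},
            ),
            "B": SyntheticSpec(
                **{**base.__dict__, "seed": seed * 3 + 2, "include_cstt": True,
                   "n_repeat_units": {"PQPQPFP": 7, "PQQPYP": 6},
                   "planted_epitopes": {"DQ8-glia-α1": 1},
                   "polyq_lengths": (8, 22)},
            ),
            "D": SyntheticSpec(
                **{**base.__dict__, "seed": seed * 3 + 3, "include_33mer": True,
                   "n_repeat_units": {"PQPQPFP": 3, "PQQPYP": 5},
                   "planted_epitopes": {"DQ2.5-glia-α3": 1, "DQ8-glia-α1": 1},
                   "polyq_lengths": (14, 10)},
            ),
        }
    elif family == "gamma":
        base = example_spec("gamma")
        specs = {
            "A": SyntheticSpec(
                **{**base.__dict__, "seed": seed * 3 + 1,
                   "n_repeat_units": {"gamma_repeat": 6},
                   "planted_epitopes": {"DQ2.5-glia-γ1": 1, "DQ2.5-glia-γ4c": 4}},
            ),
            "B": SyntheticSpec(
                **{**base.__dict__, "seed": seed * 3 + 2,
                   "n_repeat_units": {"gamma_repeat": 9},
                   "planted_epitopes": {"DQ2.5-glia-γ1": 1, "DQ2.5-glia-γ4c": 8,
                                        "DQ2.5-glia-γ5": 4}},
            ),
            "D": SyntheticSpec(
                **{**base.__dict__, "seed": seed * 3 + 3,
                   "n_repeat_units": {"gamma_repeat": 12},
                   "planted_epitopes": {"DQ2.5-glia-γ1": 1, "DQ2.5-glia-γ2": 1,
                                        "DQ2.5-glia-γ4c": 6, "DQ2.5-glia-γ5": 3}},
            ),
        }
    elif family == "omega":
        o5 = example_spec("omega", "omega_5")
        o12 = example_spec("omega", "omega_1_2")
        specs = {
            "A": SyntheticSpec(
                **{**o12.__dict__, "seed": seed * 3 + 1, "signature": "ARQL",
                   "n_repeat_units": {"PQQPFP": 11}},
            ),
            "B": SyntheticSpec(**{**o5.__dict__, "seed": seed * 3 + 2}),
            "D": SyntheticSpec(
                **{**o12.__dict__, "seed": seed * 3 + 3, "signature": "AREL",
                   "n_repeat_units": {"PQQPFP": 17},
                   "planted_epitopes": {"DQ2.5-glia-ω1": 1, "DQ2.5-glia-ω2": 1,
                                        "DQ2.5-glia-γ4c": 7, "DQ2.5-glia-γ5": 9}},
            ),
        }
    else:
        raise ValueError(f"unknown family {family!r}")
    entries = []
    for genome, spec in specs.items():
        _, truth = generate_protein(spec)
        entries.append(
            PanelEntry(
                protein_id=f"ref-{family}-{genome}",
                genome=genome,
                family=family,
                sequence=truth.mature_sequence,
            )
        )
    return ReferencePanel(entries=tuple(entries))


# ---------------------------------------------------------------------------
# Spot tables


def generate_spot_table(
    n_spots: int, category_weights: dict[str, float], seed: int
) -> tuple[list[SpotRecord], CompositionSummary]:
    """Random spot table with Dirichlet volumes normalized to 100.

    Categories are sampled with probability proportional to the weights;
    the returned ground truth holds the exact per-category group sums.
    """
    if n_spots <= 0:
        raise ValueError("n_spots must be positive")
    if not category_weights or any(w < 0 for w in category_weights.values()):
        raise ValueError("weights must be >= 0, with at least one positive")
    total_w = sum(category_weights.values())
    if total_w <= 0:
        raise ValueError("at least one weight must be positive")
    bad = set(category_weights) - set(SPOT_CATEGORIES)
    if bad:
        raise ValueError(f"unknown categories {sorted(bad)}")

    rng = np.random.default_rng(seed)
    volumes = rng.dirichlet(np.ones(n_spots)) * 100.0
    names = sorted(category_weights)
    probs = np.array([category_weights[c] for c in names]) / total_w
    cats = rng.choice(names, size=n_spots, p=probs)
    records = [
        SpotRecord(
            spot_id=f"S{i + 1:03d}",
            volume_norm=float(volumes[i]),
            protein_id=f"P{i + 1:03d}",
            category=str(cats[i]),
        )
        for i in range(n_spots)
    ]
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for rec in records:
        sums[rec.category] = sums.get(rec.category, 0.0) + rec.volume_norm
        counts[rec.category] = counts.get(rec.category, 0) + 1
    ordered = [c for c in SPOT_CATEGORIES if c in counts]
    truth = CompositionSummary(
        rows=tuple((c, counts[c], sums[c]) for c in ordered),
        total_spots=n_spots,
        total_pct=sum(sums.values()),
    )
    return records, truth
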