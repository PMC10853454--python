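"""Protease specificity rules and in-silico digestion.

A protease is modelled as a set of residues it cuts next to, a side (C- or
N-terminal to the recognised residue) and an optional set of vetoing
successors (e.g. proline for plain trypsin; ``Trypsin/P`` has no veto).
Digestion is offered with *full* specificity (both peptide termini at
enzymatic cut points or protein termini) or *semi* specificity (one terminus
free), the mode that exposes peptides created by an in-vivo protease such as
a sheddase: the free, non-enzymatic terminus marks the cleavage event.

Coordinates are 1-based and inclusive throughout; a cleavage *point* ``p``
denotes the bond between residues ``p`` and ``p + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class CutSide(str, Enum):
    """Which side of the recognised residue the scissile bond lies on."""

    AFTER = "after"    # C-terminal to the cut residue (trypsin-like)
    BEFORE = "before"  # N-terminal to the cut residue (AspN-like)


class TerminusLabel(str, Enum):
    PROTEASE_CONSISTENT = "protease_consistent"
    PROTEIN_TERMINUS = "protein_terminus"
    NON_CANONICAL = "non_canonical"


class InvalidResidueError(ValueError):
    """A sequence contains a letter outside the 20 standard residues."""

    def __init__(self, residue: str, position: int):
        self.residue = residue
        self.position = position
        super().__init__(
            f"invalid residue {residue!r} at position {position} "
            "(only the 20 standard amino-acid letters are accepted)"
        )


def _validate_sequence(sequence: str) -> None:
    for i, aa in enumerate(sequence, start=1):
        if aa not in STANDARD_RESIDUES:
            raise InvalidResidueError(aa, i)


@dataclass(frozen=True)
class ProteaseSpec:
    """Cleavage specificity of one protease.

    Parameters
    ----------
    name:
        Registry identifier, e.g. ``"trypsinP"``.
    cut_residues:
        Residues the protease recognises.
    side:
        ``CutSide.AFTER`` cuts C-terminal to a recognised residue,
        ``CutSide.BEFORE`` cuts N-terminal to it.
    blocked_next:
        Residues that veto a cut when they immediately follow the scissile
        bond (classic "not before proline"). Empty set = no veto.
    """

    name: str
    cut_residues: frozenset[str]
    side: CutSide = CutSide.AFTER
    blocked_next: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "cut_residues", frozenset(self.cut_residues))
        object.__setattr__(self, "blocked_next", frozenset(self.blocked_next))
        if not self.cut_residues:
            raise ValueError("cut_residues must be non-empty")
        self.side if isinstance(self.side, CutSide) else object.__setattr__(
            self, "side", CutSide(self.side)
        )


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with 1-based residue coordinates."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError("protein sequence must be non-empty")
        _validate_sequence(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        return self.sequence[position - 1]

    def subsequence(self, start: int, end: int) -> str:
        """Residues ``start..end`` inclusive, 1-based."""
        return self.sequence[start - 1 : end]


@dataclass(frozen=True, order=True)
class PeptideMatch:
    """A peptide located on a protein (1-based inclusive span)."""

    protein_id: str
    start: int
    end: int
    peptide: str
    protease: str

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid span {self.start}..{self.end}")
        if len(self.peptide) != self.end - self.start + 1:
            raise ValueError("peptide length inconsistent with span")

    def validate_against(self, protein: ProteinRecord) -> None:
        if self.protein_id != protein.id:
            raise ValueError(f"peptide maps to {self.protein_id}, not {protein.id}")
        if self.end > len(protein):
            raise ValueError("peptide span exceeds protein length")
        if protein.subsequence(self.start, self.end) != self.peptide:
            raise ValueError(
                f"peptide {self.peptide!r} does not match protein "
                f"{protein.id} at {self.start}..{self.end}"
            )


# --- default registry -------------------------------------------------------
# Trypsin/P cuts after K/R with no proline veto (the MaxQuant enzyme of that
# name); chymotrypsin here is the large-hydrophobic F/W/Y/L rule; AspN cuts
# N-terminal to aspartate. All are plain data and can be overridden per run.
DEFAULT_PROTEASES: dict[str, ProteaseSpec] = {
    p.name: p
    for p in (
        ProteaseSpec("trypsinP", frozenset("KR"), CutSide.AFTER),
        ProteaseSpec("trypsin", frozenset("KR"), CutSide.AFTER, frozenset("P")),
        ProteaseSpec("lysC", frozenset("K"), CutSide.AFTER),
        ProteaseSpec("chymotrypsin", frozenset("FWYL"), CutSide.AFTER),
        ProteaseSpec("aspN", frozenset("D"), CutSide.BEFORE),
    )
}


def enumerate_cleavage_points(
    protein: ProteinRecord, protease: ProteaseSpec
) -> list[int]:
    """All positions ``p`` where the protease cuts the bond ``p | p+1``.

    Returns a strictly increasing list of 1-based positions in
    ``[1, len(protein) - 1]``.
    """
    seq = protein.sequence
    points = []
    for p in range(1, len(seq)):  # bond between residue p and p+1
        if protease.side is CutSide.AFTER:
            hit = seq[p - 1] in protease.cut_residues and (
                seq[p] not in protease.blocked_next
            )
        else:
            hit = seq[p] in protease.cut_residues
        if hit:
            points.append(p)
    return points


def _boundaries(protein: ProteinRecord, protease: ProteaseSpec) -> list[int]:
    """Cut points plus the protein termini, as peptide start-boundaries.

    Boundary ``b`` means a peptide may start at ``b + 1``; 0 and len are the
    protein termini.
    """
    return [0] + enumerate_cleavage_points(protein, protease) + [len(protein)]


def digest(
    protein: ProteinRecord,
    protease: ProteaseSpec,
    specificity: str = "full",
    missed_cleavages: int = 0,
    length_range: tuple[int, int] = (6, 40),
) -> set[PeptideMatch]:
    """Enumerate peptides from an in-silico digest.

    ``specificity="full"`` yields peptides whose both termini sit at cut
    points or protein termini, spanning at most ``missed_cleavages`` internal
    cut points. ``"semi"`` relaxes exactly one terminus: every substring with
    at least one enzymatic/protein terminus is returned (still limited to
    ``missed_cleavages`` internal cut points). The semi set is a superset of
    the full set at equal parameters.
    """
    lo, hi = length_range
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid length range {length_range}")
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    if specificity not in ("full", "semi"):
        raise ValueError(f"unknown specificity {specificity!r}")

    cuts = enumerate_cleavage_points(protein, protease)
    bounds = [0] + cuts + [len(protein)]
    cutset = set(cuts)
    out: set[PeptideMatch] = set()

    def add(start: int, end: int) -> None:
        if lo <= end - start + 1 <= hi:
            out.add(
                PeptideMatch(
                    protein.id, start, end, protein.subsequence(start, end), protease.name
                )
            )

    if specificity == "full":
        for i in range(len(bounds) - 1):
            for j in range(i + 1, min(i + 1 + missed_cleavages + 1, len(bounds))):
                add(bounds[i] + 1, bounds[j])
        return out

    # semi: anchor one terminus at a boundary and slide the other freely;
    # a cut point strictly inside the peptide consumes one missed cleavage.
    n = len(protein)
    for b in bounds[:-1]:  # N-terminus anchored at boundary b (start = b+1)
        start = b + 1
        internal = 0
        for end in range(start, n + 1):
            if end > start and end - 1 in cutset:
                internal += 1
                if internal > missed_cleavages:
                    break
            add(start, end)
    for b in bounds[1:]:  # C-terminus anchored at boundary b (end = b)
        end = b
        internal = 0
        for start in range(end, 0, -1):
            if start < end and start in cutset:
                internal += 1
                if internal > missed_cleavages:
                    break
            add(start, end)
    return out


def classify_termini(
    match: PeptideMatch, protein: ProteinRecord, protease: ProteaseSpec
) -> tuple[TerminusLabel, TerminusLabel]:
    """Label each peptide terminus as enzymatic, protein terminus or neither.

    The N-terminus is judged by the bond ``start-1 | start`` and the
    C-terminus by the bond ``end | end+1``; a terminus explained by neither
    the protease nor the protein boundary is *non-canonical* — evidence for
    an in-vivo cleavage event.
    """
    match.validate_against(protein)
    cutset = set(enumerate_cleavage_points(protein, protease))

    if match.start == 1:
        n_label = TerminusLabel.PROTEIN_TERMINUS
    elif match.start - 1 in cutset:
        n_label = TerminusLabel.PROTEASE_CONSISTENT
    else:
        n_label = TerminusLabel.NON_CANONICAL

    if match.end == len(protein):
        c_label = TerminusLabel.PROTEIN_TERMINUS
    elif match.end in cutset:
        c_label = TerminusLabel.PROTEASE_CONSISTENT
    else:
        c_label = TerminusLabel.NON_CANONICAL

    return n_label, c_label


def make_registry(specs: Iterable[ProteaseSpec] = ()) -> dict[str, ProteaseSpec]:
    """Default registry with optional overrides/additions."""
    reg = dict(DEFAULT_PROTEASES)
    for s in specs:
        reg[s.name] = s
    return reg
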