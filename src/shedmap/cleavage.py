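"""Cleavage-site calling from non-canonical peptide termini.

A proteolytic event at the bond ``p | p+1`` leaves two products. Digesting
each product with a specificity-known protease produces, among ordinary
enzymatic peptides, one peptide whose C-terminus ends at ``p`` (from the
N-terminal product) and one whose N-terminus starts at ``p + 1`` (from the
C-terminal product) — termini the digestion protease cannot explain. A site
supported by evidence from *both* product sides is called *concordant*;
requiring concordance is what distinguishes a genuine cleavage event from
stray in-source fragmentation or decoy identifications.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum

from .proteolysis import (
    PeptideMatch,
    ProteaseSpec,
    ProteinRecord,
    TerminusLabel,
    classify_termini,
)


class ProductSide(str, Enum):
    """Which cleavage product the evidencing peptide derives from."""

    N_PRODUCT_C_TERMINUS = "n_product_c_terminus"  # peptide ends at the site
    C_PRODUCT_N_TERMINUS = "c_product_n_terminus"  # peptide starts just after


@dataclass(frozen=True)
class TerminusEvidence:
    """One non-canonical peptide terminus mapped to a candidate site.

    ``site`` is the 1-based index ``p`` of the residue N-terminal to the
    inferred scissile bond ``p | p+1``.
    """

    protein_id: str
    site: int
    product_side: ProductSide
    peptide: str
    protease: str
    ambiguous: bool = False  # peptide maps to more than one locus


@dataclass
class CleavageSiteCall:
    """A candidate cleavage site with its supporting peptides."""

    protein_id: str
    site: int
    n_side_peptides: list[str] = field(default_factory=list)
    c_side_peptides: list[str] = field(default_factory=list)
    proteases: set[str] = field(default_factory=set)

    @property
    def concordant(self) -> bool:
        """True when both cleavage products contributed evidence."""
        return bool(self.n_side_peptides) and bool(self.c_side_peptides)

    @property
    def n_peptides(self) -> int:
        return len(self.n_side_peptides) + len(self.c_side_peptides)


def map_peptide(protein: ProteinRecord, peptide: str) -> list[tuple[int, int]]:
    """All exact occurrences of ``peptide`` in the protein, 1-based inclusive."""
    if not peptide:
        raise ValueError("peptide must be non-empty")
    spans = []
    pos = protein.sequence.find(peptide)
    while pos != -1:
        spans.append((pos + 1, pos + len(peptide)))
        pos = protein.sequence.find(peptide, pos + 1)
    return spans


def locate_peptides(
    peptides: list[PeptideMatch],
    proteins: dict[str, ProteinRecord],
) -> list[tuple[PeptideMatch, bool]]:
    """Resolve spans for peptides, remapping when coordinates are absent.

    Returns (match, ambiguous) pairs; a peptide occurring at several loci
    yields one pair per locus, each flagged ambiguous.
    """
    out = []
    for m in peptides:
        protein = proteins.get(m.protein_id)
        if protein is None:
            raise KeyError(f"unknown protein {m.protein_id!r}")
        if m.start >= 1 and protein.subsequence(m.start, m.end) == m.peptide:
            occurrences = map_peptide(protein, m.peptide)
            out.append((m, len(occurrences) > 1))
        else:
            occurrences = map_peptide(protein, m.peptide)
            for start, end in occurrences:
                out.append(
                    (
                        PeptideMatch(m.protein_id, start, end, m.peptide, m.protease),
                        len(occurrences) > 1,
                    )
                )
    return out


def collect_terminus_evidence(
    peptides: list[PeptideMatch],
    proteins: dict[str, ProteinRecord],
    proteases: dict[str, ProteaseSpec],
) -> list[TerminusEvidence]:
    """Extract one evidence record per non-canonical peptide terminus.

    Each peptide is judged against its own digestion protease only — the
    per-protease searches are independent experiments. A peptide may yield
    zero records (fully enzymatic), one, or two (both termini unexplained).
    """
    evidence: list[TerminusEvidence] = []
    for match, ambiguous in locate_peptides(peptides, proteins):
        protease = proteases.get(match.protease)
        if protease is None:
            raise KeyError(f"unknown protease {match.protease!r}")
        protein = proteins[match.protein_id]
        n_label, c_label = classify_termini(match, protein, protease)
        if n_label is TerminusLabel.NON_CANONICAL:
            # peptide starts at `start`: inferred bond is (start-1)|start
            evidence.append(
                TerminusEvidence(
                    match.protein_id,
                    match.start - 1,
                    ProductSide.C_PRODUCT_N_TERMINUS,
                    match.peptide,
                    match.protease,
                    ambiguous,
                )
            )
        if c_label is TerminusLabel.NON_CANONICAL:
            evidence.append(
                TerminusEvidence(
                    match.protein_id,
                    match.end,
                    ProductSide.N_PRODUCT_C_TERMINUS,
                    match.peptide,
                    match.protease,
                    ambiguous,
                )
            )
    return evidence


def call_cleavage_sites(
    evidence: list[TerminusEvidence],
    min_products: int = 2,
    min_proteases: int = 1,
    include_ambiguous: bool = False,
) -> list[CleavageSiteCall]:
    """Aggregate terminus evidence into per-site calls.

    With ``min_products=2`` (the default) only concordant sites — supported
    by peptides from both cleavage products — are returned. Ambiguously
    mapping peptides are excluded unless ``include_ambiguous`` is set.
    Output is sorted by (protein, site) and independent of input order.
    """
    if min_products not in (1, 2):
        raise ValueError("min_products must be 1 or 2")
    grouped: dict[tuple[str, int], CleavageSiteCall] = {}
    for ev in evidence:
        if ev.ambiguous and not include_ambiguous:
            continue
        key = (ev.protein_id, ev.site)
        call = grouped.setdefault(key, CleavageSiteCall(ev.protein_id, ev.site))
        bucket = (
            call.n_side_peptides
            if ev.product_side is ProductSide.N_PRODUCT_C_TERMINUS
            else call.c_side_peptides
        )
        if ev.peptide not in bucket:
            bucket.append(ev.peptide)
        call.proteases.add(ev.protease)

    calls = [c for c in grouped.values() if len(c.proteases) >= min_proteases]
    if min_products == 2:
        calls = [c for c in calls if c.concordant]
    for c in calls:
        c.n_side_peptides.sort()
        c.c_side_peptides.sort()
    return sorted(calls, key=lambda c: (c.protein_id, c.site))
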