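"""Published gene-structure table for the Atlantic salmon NILT cluster.

These are the printed nucleotide lengths of the coding exons and introns of
the six salmon NILT genes, together with the reported signalling-motif counts,
connecting-peptide Ser/Thr tallies, Ig-domain cysteine-spacing classes and
group assignments.  They serve two purposes: as reference rows for the
structure report, and as the default templates for the synthetic-locus
generator (:mod:`niltkit.simulate`).

Exon roles, in transcription order:

====  =======================================
LP    leader peptide (exon 1)
Ig1   first V-type Ig domain (exon 2)
Ig2   second Ig domain (exon 2a, NILT3 only)
CP    connecting peptide (exon 3)
TM    transmembrane + start of cytoplasmic
      region (exon 4)
Cyt1  cytoplasmic region (exon 5)
Cyt2  cytoplasmic region + ITIMs (exon 6)
====  =======================================

Exon-1 lengths are coding lengths (5'UTR excluded) and the terminal stop codon
is counted inside the Cyt2 exon, so per-gene exon sums equal the ORF lengths.
The NILT5 intron 2 is only bounded in the source ("> 2381"); the lower bound
is used here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Canonical exon role order (transcription order).
ROLE_ORDER = ("LP", "Ig1", "Ig2", "CP", "TM", "Cyt1", "Cyt2")

#: Roles that encode an Ig domain.
IG_ROLES = ("Ig1", "Ig2")


@dataclass(frozen=True)
class GeneTemplate:
    """Blueprint of one NILT-like gene for simulation and reporting.

    Parameters
    ----------
    name :
        Gene identifier, e.g. ``"Ssa-NILT1"``.
    exon_roles :
        Roles of the coding exons in transcription order (subset of
        :data:`ROLE_ORDER`, in that order).
    exon_lengths :
        Coding lengths in nucleotides, one per exon.
    intron_lengths :
        Intron lengths in nucleotides (``len(exon_roles) - 1`` entries).
    strand :
        ``+`` or ``-``; orientation of the gene on the locus.
    cys_classes :
        Cysteine-spacing class per Ig role (``CX3C``, ``CX6C`` or ``CX7C``).
    group :
        Diagnostic-residue group (1 or 2) or ``None`` when the gene carries a
        non-CX3C domain and is unclassified.
    itim_count :
        Number of inhibitory (ITIM) motifs planted in the Cyt2 exon.
    st_count :
        Number of Ser/Thr residues planted in the connecting peptide.
    tm_charged :
        Whether a positively charged residue (R/K) is planted in the
        transmembrane helix (activating-receptor hallmark; the salmon NILTs
        are inhibitory, so the defaults are all ``False``).
    """

    name: str
    exon_roles: tuple[str, ...]
    exon_lengths: tuple[int, ...]
    intron_lengths: tuple[int, ...]
    strand: str = "+"
    cys_classes: dict = field(default_factory=dict)
    group: int | None = None
    itim_count: int = 4
    st_count: int = 0
    tm_charged: bool = False

    def __post_init__(self) -> None:
        if len(self.exon_lengths) != len(self.exon_roles):
            raise ValueError("one length per exon role required")
        if len(self.intron_lengths) != max(len(self.exon_roles) - 1, 0):
            raise ValueError("intron count must be exon count - 1")
        order = [r for r in ROLE_ORDER if r in self.exon_roles]
        if tuple(order) != self.exon_roles:
            raise ValueError(f"exon roles out of canonical order: {self.exon_roles}")

    @property
    def orf_length(self) -> int:
        """Total coding length in nucleotides (includes the stop codon)."""
        return sum(self.exon_lengths)

    @property
    def protein_length(self) -> int:
        """Length of the translated product, stop codon excluded."""
        return self.orf_length // 3 - 1


_ONE_IG = ("LP", "Ig1", "CP", "TM", "Cyt1", "Cyt2")
_TWO_IG = ("LP", "Ig1", "Ig2", "CP", "TM", "Cyt1", "Cyt2")


def salmon_templates() -> dict[str, GeneTemplate]:
    """The six salmon NILT genes as simulation-ready templates.

    Strand assignments alternate to emulate a cluster with genes in both
    orientations; the source reports mixed orientations without per-gene
    strands.
    """
    return {
        t.name: t
        for t in (
            GeneTemplate(
                "Ssa-NILT1", _ONE_IG, (46, 348, 168, 96, 50, 324),
                (275, 2056, 1074, 218, 753), "+",
                {"Ig1": "CX3C"}, group=1, itim_count=5, st_count=29,
            ),
            GeneTemplate(
                "Ssa-NILT2", _ONE_IG, (46, 348, 135, 120, 50, 294),
                (180, 2067, 1063, 286, 511), "-",
                {"Ig1": "CX3C"}, group=1, itim_count=4, st_count=22,
            ),
            GeneTemplate(
                "Ssa-NILT3", _TWO_IG, (46, 330, 321, 99, 105, 50, 327),
                (275, 469, 11068, 610, 242, 410), "+",
                {"Ig1": "CX6C", "Ig2": "CX7C"}, group=None, itim_count=5,
                st_count=15,
            ),
            GeneTemplate(
                "Ssa-NILT4", _ONE_IG, (46, 354, 204, 96, 44, 318),
                (275, 8112, 941, 212, 1728), "-",
                {"Ig1": "CX3C"}, group=2, itim_count=4, st_count=36,
            ),
            GeneTemplate(
                "Ssa-NILT5", _ONE_IG, (46, 342, 117, 96, 50, 282),
                (275, 2381, 619, 288, 227), "+",
                {"Ig1": "CX3C"}, group=2, itim_count=4, st_count=22,
            ),
            GeneTemplate(
                "Ssa-NILT6", _ONE_IG, (46, 348, 111, 96, 50, 294),
                (275, 1789, 1072, 308, 526), "-",
                {"Ig1": "CX3C"}, group=2, itim_count=4, st_count=20,
            ),
        )
    }
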