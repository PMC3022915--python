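"""Receptor-level annotation of NILT-like genes.

Translates an intact gene model, partitions the product into the canonical
receptor regions (leader peptide, Ig domain(s), connecting peptide,
transmembrane helix, cytoplasmic tail), and annotates the features that define
this family:

* the V-type Ig fold's canonical cysteine pair (alignment positions 17/89,
  1-based) plus an additional pair whose spacing — CX3C, CX6C or CX7C —
  classifies the domain;
* ITIMs in the cytoplasmic tail, consensus ``(S/I/V/L)xYxx(I/V/L)`` with the
  short form ``Yxx(I/V/L)``;
* the Ser/Thr-rich connecting peptide (stalk) composition;
* a charged transmembrane residue (R/K), the hallmark of adaptor-coupled
  activating receptors;
* the two diagnostic-residue groups of CX3C domains: group 1 carries H at
  position 20, an SLYY motif at 32-35 (immediately after the third cysteine)
  and L at 66; group 2 carries Q20, a (P/R)V(F/L)N motif at 32-35 and I66.

Region boundaries come from the exon roles, not from predictors: a phase-1
exon junction assigns the split codon to the downstream region.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from . import align as _align
from .genestruct import extract_cds, validate_gene
from .seqio import GeneModel

#: Default transmembrane-helix length (aa) carved from the start of the TM
#: exon; the exon remainder joins the cytoplasmic region.
DEFAULT_TM_AA = 23

#: 1-based anchor positions of the fold cysteines within an Ig domain.
CYS_ANCHORS = (17, 89)
#: Search window (aa) around each anchor.
CYS_WINDOW = 5

ITIM_LONG = re.compile(r"(?=([SIVL].Y..[IVL]))")
ITIM_SHORT = re.compile(r"(?=(Y..[IVL]))")

GROUP2_MOTIF = re.compile(r"[PR]V[FL]N")


class AnnotationError(ValueError):
    """Raised when a gene cannot be annotated as an intact receptor."""


# ---------------------------------------------------------------------------
# Translation and region partition
# ---------------------------------------------------------------------------

def region_spans(exon_roles, exon_lengths, tm_aa: int = DEFAULT_TM_AA):
    """Amino-acid spans (0-based half-open) of receptor regions and exons.

    Returns ``(regions, exon_spans)``.  ``regions`` maps LP/Ig1/[Ig2]/CP/TM/
    Cyt to protein intervals; the cytoplasmic region is the TM-exon remainder
    plus the Cyt1 and Cyt2 exons.  ``exon_spans`` maps each exon role to its
    own aa interval (stop codon excluded).  At a phase-1 or phase-2 junction
    the split codon belongs to the downstream interval.
    """
    total_nt = sum(exon_lengths)
    protein_len = total_nt // 3 - 1
    bounds = []
    acc = 0
    for length in exon_lengths:
        bounds.append(acc)
        acc += length
    exon_spans = {}
    for i, role in enumerate(exon_roles):
        start = bounds[i] // 3
        end = (bounds[i] + exon_lengths[i]) // 3 if i + 1 < len(exon_roles) else protein_len
        exon_spans[role] = (start, min(end, protein_len))

    regions = {}
    for role in ("LP", "Ig1", "Ig2", "CP"):
        if role in exon_spans:
            regions[role] = exon_spans[role]
    if "TM" in exon_spans:
        tm_start, tm_exon_end = exon_spans["TM"]
        tm_end = min(tm_start + tm_aa, tm_exon_end)
        regions["TM"] = (tm_start, tm_end)
        regions["Cyt"] = (tm_end, protein_len)
    elif regions:
        # partial gene without a TM exon: last region runs to the end
        last = max(regions, key=lambda r: regions[r][0])
        regions[last] = (regions[last][0], protein_len)
    return regions, exon_spans


def translate_and_partition(model: GeneModel, locus_seq: str,
                            tm_aa: int = DEFAULT_TM_AA) -> "ReceptorAnnotation":
    """Translate an intact gene and partition the product into regions.

    The terminal stop codon is stripped, so the protein length is always
    ORF/3 − 1.  Pseudogenes are refused: run
    :func:`niltkit.genestruct.validate_gene` first to characterise them.
    """
    report = validate_gene(model, locus_seq)
    if report.flags - {"bad_splice"}:
        raise AnnotationError(
            f"{model.gene_id} is not an intact gene ({', '.join(sorted(report.flags))}); "
            "see validate_gene for the pseudogene report"
        )
    cds = extract_cds(model, locus_seq)
    if set(cds) - set("ACGT"):
        bad = "".join(sorted(set(cds) - set("ACGT")))
        raise AnnotationError(
            f"{model.gene_id}: degenerate nucleotides {bad!r} in CDS; cannot translate"
        )
    protein = str(Seq(cds).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    regions, exon_spans = region_spans(model.roles, model.exon_lengths, tm_aa)
    return ReceptorAnnotation(
        gene_id=model.gene_id, protein=protein, regions=regions,
        exon_spans=exon_spans,
    )


# ---------------------------------------------------------------------------
# Feature scanners
# ---------------------------------------------------------------------------

@dataclass
class CysProfile:
    """Cysteine architecture of one Ig domain (0-based positions)."""

    canonical_pair: tuple[int, int] | None
    extra_pair: tuple[int, int] | None
    spacing_class: str  # CX3C | CX6C | CX7C | other | none
    warnings: tuple[str, ...] = ()


def cys_profile(ig_seq: str) -> CysProfile:
    """Classify the cysteine spacing of an Ig-domain sequence.

    The fold (canonical) cysteines are the ones nearest the 1-based anchor
    positions 17 and 89, within ±5 residues; an additional pair strictly
    between them defines the spacing class ``CXnC`` with ``n`` the number of
    residues separating the two extra cysteines.
    """
    cys = [i for i, c in enumerate(ig_seq) if c == "C"]
    if len(cys) < 2:
        return CysProfile(None, None, "none", ("fewer than two cysteines",))

    warnings = []
    anchors = []
    for pos1 in CYS_ANCHORS:
        target = pos1 - 1
        near = [c for c in cys if abs(c - target) <= CYS_WINDOW]
        if not near:
            warnings.append(f"no cysteine within {CYS_WINDOW} aa of position {pos1}")
            anchors.append(None)
        else:
            anchors.append(min(near, key=lambda c: (abs(c - target), c)))
    if None in anchors or anchors[0] >= anchors[1]:
        return CysProfile(None, None, "none", tuple(warnings) or ("anchors not found",))

    lo, hi = anchors
    inner = [c for c in cys if lo < c < hi]
    if not inner:
        return CysProfile((lo, hi), None, "none", tuple(warnings))
    if len(inner) != 2:
        warnings.append(f"{len(inner)} cysteines between the canonical pair")
        return CysProfile((lo, hi), None, "other", tuple(warnings))
    gap = inner[1] - inner[0] - 1
    cls = {3: "CX3C", 6: "CX6C", 7: "CX7C"}.get(gap, "other")
    return CysProfile((lo, hi), (inner[0], inner[1]), cls, tuple(warnings))


@dataclass(frozen=True)
class ItimHit:
    """One inhibitory-motif match; ``y_position`` is 0-based in the scanned
    sequence."""

    y_position: int
    form: str  # long | short
    matched_text: str


def scan_itims(cyt_seq: str) -> list[ItimHit]:
    """Scan a cytoplasmic sequence for ITIMs.

    Every long-form match ``(S/I/V/L)xYxx(I/V/L)`` is reported; short-form
    matches ``Yxx(I/V/L)`` are added only for tyrosines not already covered by
    a long-form hit, so each distinct Y yields at most one hit.  Hits are
    ordered by tyrosine position.
    """
    hits: dict[int, ItimHit] = {}
    for m in ITIM_LONG.finditer(cyt_seq):
        y = m.start() + 2
        hits.setdefault(y, ItimHit(y, "long", m.group(1)))
    for m in ITIM_SHORT.finditer(cyt_seq):
        y = m.start()
        hits.setdefault(y, ItimHit(y, "short", m.group(1)))
    return [hits[y] for y in sorted(hits)]


def st_composition(cp_seq: str) -> tuple[int, int]:
    """(Ser+Thr count, length) of a connecting-peptide sequence."""
    return cp_seq.count("S") + cp_seq.count("T"), len(cp_seq)


def tm_charge_check(tm_seq: str) -> bool:
    """True iff the transmembrane segment carries R or K (activating
    receptors pair with ITAM adaptors through such a charged residue)."""
    return "R" in tm_seq or "K" in tm_seq


# ---------------------------------------------------------------------------
# Diagnostic-residue group classification
# ---------------------------------------------------------------------------

@dataclass
class GroupCall:
    """Group assignment of a CX3C Ig domain with its three diagnostics.

    ``evidence`` holds the residues observed at reference positions 20,
    32-35 and 66 (``None`` where the alignment puts a gap).  A group is
    called only when at least two diagnostics agree; otherwise
    ``unclassified`` with a reason.
    """

    group: str  # "1" | "2" | "unclassified"
    evidence: dict = field(default_factory=dict)
    reason: str | None = None


def _build_reference_ig() -> str:
    """Synthetic 116-aa reference Ig domain used to anchor the diagnostic
    coordinate frame (positions 17/89 cysteines, extra pair at 27/31, group-1
    diagnostics).  It is a constructed stand-in, not a natural sequence; any
    real Ig domain can be supplied instead via ``reference_ig=``."""
    bg = "GKETLQPDRFAGNVEHW"
    seq = list((bg * 8)[:116])
    for pos1, res in [(17, "C"), (20, "H"), (27, "C"), (31, "C"),
                      (32, "S"), (33, "L"), (34, "Y"), (35, "Y"),
                      (66, "L"), (89, "C")]:
        seq[pos1 - 1] = res
    return "".join(seq)


REFERENCE_IG = _build_reference_ig()

#: 1-based diagnostic positions in the reference Ig frame.
DIAGNOSTIC_POSITIONS = (20, 32, 33, 34, 35, 66)


def _map_reference_positions(query: str, reference: str):
    """Map 1-based reference positions to query residues via global
    alignment; returns {ref_pos: residue or None}."""
    aln = _align.global_align(reference, query, alphabet="aa")
    mapping: dict[int, str | None] = {}
    ref_i = 0
    for a, b in zip(aln.aligned_a, aln.aligned_b):
        if a != "-":
            ref_i += 1
            if ref_i in DIAGNOSTIC_POSITIONS:
                mapping[ref_i] = None if b == "-" else b
    return mapping


def classify_ig(ig_seq: str, spacing_class: str,
                reference_ig: str = REFERENCE_IG) -> GroupCall:
    """Classify one Ig domain into diagnostic group 1 or 2.

    Only CX3C domains are classifiable.  Diagnostic positions are located by
    aligning the domain to *reference_ig* (which fixes the 20/32-35/66
    coordinate frame); the call requires a 2-of-3 majority, tolerating the
    motif degeneracy within each group.
    """
    if spacing_class != "CX3C":
        return GroupCall("unclassified", reason="spacing_class")
    mapped = _map_reference_positions(ig_seq, reference_ig)
    res20 = mapped.get(20)
    motif = "".join(mapped.get(p) or "-" for p in (32, 33, 34, 35))
    res66 = mapped.get(66)
    evidence = {"res20": res20, "motif32_35": motif, "res66": res66}
    g1 = (res20 == "H") + (motif == "SLYY") + (res66 == "L")
    g2 = (res20 == "Q") + bool(GROUP2_MOTIF.fullmatch(motif)) + (res66 == "I")
    if g1 >= 2:
        return GroupCall("1", evidence)
    if g2 >= 2:
        return GroupCall("2", evidence)
    return GroupCall("unclassified", evidence, reason="diagnostics disagree")


# ---------------------------------------------------------------------------
# Whole-receptor annotation
# ---------------------------------------------------------------------------

@dataclass
class ReceptorAnnotation:
    """Annotated receptor: protein, region partition and feature calls.

    ``regions`` and ``exon_spans`` are 0-based half-open aa intervals; the
    region intervals tile the protein exactly.
    """

    gene_id: str
    protein: str
    regions: dict
    exon_spans: dict = field(default_factory=dict)
    cys_profiles: dict = field(default_factory=dict)
    itims: list = field(default_factory=list)
    st_count: int = 0
    cp_length: int = 0
    tm_charged: bool = False
    group: GroupCall | None = None

    def region_seq(self, role: str) -> str:
        s, e = self.regions[role]
        return self.protein[s:e]


def annotate_receptor(model: GeneModel, locus_seq: str,
                      tm_aa: int = DEFAULT_TM_AA,
                      reference_ig: str = REFERENCE_IG) -> ReceptorAnnotation:
    """Full receptor annotation of one intact gene model."""
    ann = translate_and_partition(model, locus_seq, tm_aa=tm_aa)
    for role in ("Ig1", "Ig2"):
        if role in ann.regions:
            ann.cys_profiles[role] = cys_profile(ann.region_seq(role))
    if "Cyt" in ann.regions:
        ann.itims = scan_itims(ann.region_seq("Cyt"))
    if "CP" in ann.regions:
        ann.st_count, ann.cp_length = st_composition(ann.region_seq("CP"))
    if "TM" in ann.regions:
        ann.tm_charged = tm_charge_check(ann.region_seq("TM"))
    if "Ig1" in ann.cys_profiles:
        ann.group = classify_ig(
            ann.region_seq("Ig1"), ann.cys_profiles["Ig1"].spacing_class,
            reference_ig,
        )
    return ann


def receptor_table(annotations) -> pd.DataFrame:
    """One row per annotated gene, TSV-ready."""
    rows = []
    for ann in annotations:
        cys = {role: p.spacing_class for role, p in ann.cys_profiles.items()}
        rows.append({
            "gene": ann.gene_id,
            "protein_length": len(ann.protein),
            "regions": ";".join(f"{r}:{s}-{e}" for r, (s, e) in ann.regions.items()),
            "ig1_class": cys.get("Ig1", "-"),
            "ig2_class": cys.get("Ig2", "-"),
            "itim_count": len(ann.itims),
            "itim_y_positions": ",".join(str(h.y_position) for h in ann.itims) or "-",
            "st_count": ann.st_count,
            "cp_length": ann.cp_length,
            "tm_charged": ann.tm_charged,
            "group": ann.group.group if ann.group else "-",
        })
    return pd.DataFrame(rows)
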