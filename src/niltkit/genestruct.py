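"""Gene structure: CDS assembly, exon/intron tables, intron phases, validation.

The NILT genes have six coding exons (leader peptide, Ig domain, connecting
peptide, transmembrane, and two cytoplasmic exons) separated by five introns;
the two-Ig variant carries an additional Ig exon and intron.  Introns 1-4 fall
in phase 1 (after the first base of a codon) and the final intron, upstream of
the ITIM-bearing exon, in phase 0 — the hallmark of functional inhibitory
receptors in this family.  Phase of intron *i* is the cumulative coding length
of exons 1..*i* modulo 3.

Exon-1 lengths are coding lengths (5'UTR excluded) and the terminal stop codon
is counted inside the last exon, so exon sums equal ORF lengths exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .seqio import GeneModel, reverse_complement
from .tables import ROLE_ORDER

STOP_CODONS = ("TAA", "TAG", "TGA")

#: Structure-report column layout (one-Ig genes leave the Ig2 cells as "-").
TABLE_COLUMNS = (
    "gene", "LP Exon 1", "Intron 1", "Ig1 Exon 2", "Intron 2", "Ig2 Exon 2a",
    "Intron 2a", "CP Exon 3", "Intron 3", "TM Exon 4", "Intron 4",
    "Cyt1 Exon 5", "Intron 5", "Cyt2 Exon 6", "ORF", "Signalling motif",
)

_EXON_COLUMN = {
    "LP": "LP Exon 1", "Ig1": "Ig1 Exon 2", "Ig2": "Ig2 Exon 2a",
    "CP": "CP Exon 3", "TM": "TM Exon 4", "Cyt1": "Cyt1 Exon 5",
    "Cyt2": "Cyt2 Exon 6",
}
# Intron column is named after the exon it follows.
_INTRON_COLUMN = {
    "LP": "Intron 1", "Ig1": "Intron 2", "Ig2": "Intron 2a",
    "CP": "Intron 3", "TM": "Intron 4", "Cyt1": "Intron 5",
}


def extract_cds(model: GeneModel, locus_seq: str) -> str:
    """Concatenate the exon sequences of *model* in transcription order.

    Minus-strand exons are reverse-complemented, so the result always reads
    5'→3' on the coding strand.
    """
    n = len(locus_seq)
    parts = []
    for exon in model.exons:
        if exon.end > n:
            raise ValueError(
                f"exon [{exon.start},{exon.end}) of {model.gene_id} outside "
                f"locus of length {n}"
            )
        sub = locus_seq[exon.start : exon.end]
        parts.append(reverse_complement(sub) if model.strand == "-" else sub)
    return "".join(parts)


def intron_phases_from_lengths(exon_lengths) -> tuple[int, ...]:
    """Intron phases given exon coding lengths (nt), transcription order."""
    phases = []
    total = 0
    for length in list(exon_lengths)[:-1]:
        total += length
        phases.append(total % 3)
    return tuple(phases)


def intron_phases(model: GeneModel) -> tuple[int, ...]:
    """Phases of the introns of *model* (empty for single-exon genes)."""
    return intron_phases_from_lengths(model.exon_lengths)


def intron_sequences(model: GeneModel, locus_seq: str) -> tuple[str, ...]:
    """Intron sequences on the transcribed strand, transcription order."""
    out = []
    for a, b in model.introns:
        sub = locus_seq[a:b]
        out.append(reverse_complement(sub) if model.strand == "-" else sub)
    return tuple(out)


def structure_table(models, itim_counts: dict | None = None) -> pd.DataFrame:
    """Per-gene exon/intron length table in the canonical column layout.

    Cells for roles a gene lacks are rendered as ``"-"``.  ``itim_counts``
    (gene_id → int), when given, fills the signalling-motif column; it is
    normally produced by :mod:`niltkit.receptor`.
    """
    rows = []
    for model in models:
        row = {c: "-" for c in TABLE_COLUMNS}
        row["gene"] = model.gene_id
        for exon, length in zip(model.exons, model.exon_lengths):
            row[_EXON_COLUMN[exon.role]] = length
        for exon, ilen in zip(model.exons, model.intron_lengths):
            row[_INTRON_COLUMN[exon.role]] = ilen
        row["ORF"] = sum(model.exon_lengths)
        if itim_counts and model.gene_id in itim_counts:
            k = itim_counts[model.gene_id]
            row["Signalling motif"] = f"{k} ITIM" + ("s" if k != 1 else "")
        rows.append(row)
    return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))


@dataclass
class PseudogeneReport:
    """Validation findings for one gene.

    A non-empty ``flags`` set classifies the gene as a pseudogene.  Flags:
    ``internal_stop`` (in-frame stop before the final codon, with the locus
    coordinate of the first such stop), ``missing_role_exon`` (no CP, TM or
    Cyt2 exon while LP and an Ig exon are present), ``frameshift`` (coding
    length not a multiple of 3) and ``bad_splice`` (an intron that does not
    begin GT and end AG on the transcribed strand).
    """

    gene_id: str
    flags: set = field(default_factory=set)
    stop_position: int | None = None
    missing_role: str | None = None

    @property
    def is_pseudogene(self) -> bool:
        return bool(self.flags)


def _cds_index_to_locus(model: GeneModel, idx: int) -> int:
    """Locus coordinate of CDS position *idx* (transcribed-strand order)."""
    for exon in model.exons:
        n = len(exon)
        if idx < n:
            if model.strand == "+":
                return exon.start + idx
            return exon.end - 1 - idx
        idx -= n
    raise IndexError("CDS index out of range")


def validate_gene(model: GeneModel, locus_seq: str) -> PseudogeneReport:
    """Screen one gene model for pseudogenizing lesions.

    Findings are reported as flags, never raised: a locus is allowed to carry
    broken gene copies and the survey must describe them.
    """
    report = PseudogeneReport(model.gene_id)
    cds = extract_cds(model, locus_seq)

    if len(cds) % 3 != 0:
        report.flags.add("frameshift")

    n_codons = len(cds) // 3
    for i in range(n_codons - 1):
        codon = cds[3 * i : 3 * i + 3]
        if codon in STOP_CODONS:
            report.flags.add("internal_stop")
            report.stop_position = _cds_index_to_locus(model, 3 * i)
            break

    roles = set(model.roles)
    if "LP" in roles and ("Ig1" in roles or "Ig2" in roles):
        for needed in ("CP", "TM", "Cyt2"):
            if needed not in roles:
                report.flags.add("missing_role_exon")
                report.missing_role = needed
                break

    for intron in intron_sequences(model, locus_seq):
        if len(intron) < 4 or not (intron.startswith("GT") and intron.endswith("AG")):
            report.flags.add("bad_splice")
            break

    return report


def pseudogene_table(reports) -> pd.DataFrame:
    rows = [
        {
            "gene": r.gene_id,
            "pseudogene": r.is_pseudogene,
            "flags": ",".join(sorted(r.flags)) or "-",
            "stop_position": r.stop_position if r.stop_position is not None else "-",
            "missing_role": r.missing_role or "-",
        }
        for r in reports
    ]
    return pd.DataFrame(
        rows, columns=["gene", "pseudogene", "flags", "stop_position", "missing_role"]
    )
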