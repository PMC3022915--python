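"""Checks against a deposited locus record (e.g. GenBank GU552297).

The BAC contig carrying the salmon NILT cluster is deposited as GU552297.
Given that sequence plus exon-level annotations in this package's GFF3
convention, :func:`accession_report` recomputes the headline receptor
quantities straight from the pipeline: the Ig-exon amino-acid identity
between NILT1 and NILT2, the Ser/Thr composition of the NILT1 connecting
peptide, and the NILT1 ITIM count.

:func:`fetch_genbank` downloads a record from NCBI efetch when the machine
is online; everything else here is offline.
"""

from __future__ import annotations

import urllib.request

from Bio import SeqIO

from . import align as _align
from . import receptor as _receptor
from .seqio import NamedSequence, read_fasta, read_gff3, build_gene_models

EFETCH = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
          "?db=nuccore&id={acc}&rettype={rettype}&retmode=text")


def fetch_genbank(accession: str, path: str, rettype: str = "fasta",
                  timeout: float = 30.0) -> str:
    """Download *accession* from NCBI efetch to *path*; returns the path.

    Raises ``OSError`` when the network is unavailable.
    """
    url = EFETCH.format(acc=accession, rettype=rettype)
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        data = resp.read()
    if not data or data[:1] not in (b">", b"L"):  # FASTA or GenBank LOCUS
        raise OSError(f"unexpected efetch payload for {accession}")
    with open(path, "wb") as fh:
        fh.write(data)
    return path


def load_locus(path) -> NamedSequence:
    """Load a locus sequence from FASTA or GenBank flat file."""
    text_path = str(path)
    if text_path.endswith((".gb", ".gbk", ".genbank")):
        rec = next(SeqIO.parse(text_path, "genbank"))
        return NamedSequence(rec.id, str(rec.seq).upper(), "nt")
    return read_fasta(text_path, alphabet="nt")[0]


def accession_report(locus_path, gff3_path,
                     gene_a: str = "Ssa-NILT1", gene_b: str = "Ssa-NILT2") -> dict:
    """Recompute the accession-backed receptor quantities.

    Returns ``ig_identity_pct`` (Ig-exon aa identity between *gene_a* and
    *gene_b*), ``st_count``/``cp_length`` (connecting peptide of *gene_a*)
    and ``itim_count`` (*gene_a*).
    """
    locus = load_locus(locus_path)
    models = {m.gene_id: m for m in build_gene_models(read_gff3(gff3_path))}
    for gid in (gene_a, gene_b):
        if gid not in models:
            raise ValueError(f"gene {gid!r} not present in {gff3_path}")
    ann_a = _receptor.annotate_receptor(models[gene_a], locus.seq)
    ann_b = _receptor.annotate_receptor(models[gene_b], locus.seq)
    aln = _align.global_align(ann_a.region_seq("Ig1"), ann_b.region_seq("Ig1"),
                              alphabet="aa")
    return {
        "ig_identity_pct": aln.identity_pct,
        "st_count": ann_a.st_count,
        "cp_length": ann_a.cp_length,
        "itim_count": len(ann_a.itims),
    }
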