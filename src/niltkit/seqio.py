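"""Input/output for the standard formats and gene-model assembly.

Reads and writes FASTA, GFF3, Newick and the TSV reports, and turns
role-labelled exon features into per-gene models.  Internal coordinates are
0-based half-open throughout; GFF3 files on disk are 1-based inclusive, as the
format requires.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from gffutils.feature import feature_from_line
import skbio

from .tables import ROLE_ORDER

#: IUPAC nucleotide alphabet, degenerate codes included.
NT_IUPAC = set("ACGTUNRYSWKMBDHV")
#: Unambiguous amino-acid alphabet (with X for unknown and * for stop).
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")


class FormatError(ValueError):
    """Raised on malformed input files."""


@dataclass(frozen=True)
class NamedSequence:
    """A named nucleotide or amino-acid sequence.

    ``alphabet`` is ``"nt"`` or ``"aa"``.  Degenerate IUPAC nucleotide codes
    (R, S, Y, ...) are legal on input — the pan-Ig primers contain them — but
    are rejected later at CDS-translation time.
    """

    id: str
    seq: str
    alphabet: str = "nt"

    def __post_init__(self):
        if not self.seq:
            raise FormatError(f"empty sequence for record {self.id!r}")
        if self.alphabet not in ("nt", "aa"):
            raise ValueError(f"alphabet must be 'nt' or 'aa', got {self.alphabet!r}")

    def __len__(self) -> int:
        return len(self.seq)

    def ungapped(self) -> str:
        return self.seq.replace("-", "")


def infer_alphabet(seq: str) -> str:
    """Guess whether *seq* is nucleotide or amino acid.

    A sequence is called nucleotide when every symbol is an IUPAC nucleotide
    code *and* at least half the symbols are unambiguous (A/C/G/T/U/N) —
    degenerate primers pass, but short protein fragments whose residues all
    happen to be IUPAC ambiguity letters do not.
    """
    letters = [c for c in seq.upper() if c != "-"]
    if not letters:
        raise FormatError("cannot infer alphabet of an all-gap sequence")
    if all(c in NT_IUPAC for c in letters):
        plain = sum(c in "ACGTUN" for c in letters)
        if plain / len(letters) >= 0.5:
            return "nt"
    if all(c in AA_ALPHABET for c in letters):
        return "aa"
    bad = sorted({c for c in letters if c not in AA_ALPHABET | NT_IUPAC})
    raise FormatError(f"unrecognised sequence symbols: {''.join(bad)}")


def read_fasta(path, alphabet: str | None = None) -> list[NamedSequence]:
    """Read a FASTA file into :class:`NamedSequence` records.

    Sequences are uppercased; gaps are preserved (aligned FASTA is accepted).
    Duplicate identifiers and empty records are format errors.
    """
    with _open(path) as fh:
        first = fh.read(1)
        if first and first not in ">;":
            raise FormatError(f"{path}: not FASTA — line 1 does not start with '>'")
        fh.seek(0)
        records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    out: list[NamedSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty record {rec.id!r}")
        out.append(NamedSequence(rec.id, seq, alphabet or infer_alphabet(seq)))
    return out


def write_fasta(records, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def _open(path):
    if hasattr(path, "read"):
        return path
    return open(path)


# ---------------------------------------------------------------------------
# Exon features and gene models
# ---------------------------------------------------------------------------

VALID_ROLES = set(ROLE_ORDER)


@dataclass(frozen=True)
class ExonFeature:
    """One role-labelled coding exon, 0-based half-open on the locus."""

    gene_id: str
    role: str
    start: int
    end: int
    strand: str
    rank: int = 0
    seqid: str = "locus"

    def __post_init__(self):
        if self.role not in VALID_ROLES:
            raise FormatError(f"unknown role {self.role!r} for gene {self.gene_id!r}")
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid exon interval [{self.start}, {self.end}) for {self.gene_id}"
            )
        if self.strand not in "+-":
            raise FormatError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """One gene: its exons in transcription order and the derived introns.

    ``introns`` are genomic intervals (0-based half-open), listed in
    transcription order: ascending coordinates on ``+``, descending on ``-``.
    """

    gene_id: str
    strand: str
    exons: tuple[ExonFeature, ...]
    seqid: str = "locus"

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((a.end, b.start))
            else:
                out.append((b.end, a.start))
        return tuple(out)

    @property
    def roles(self) -> tuple[str, ...]:
        return tuple(e.role for e in self.exons)

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(len(e) for e in self.exons)

    @property
    def intron_lengths(self) -> tuple[int, ...]:
        return tuple(b - a for a, b in self.introns)

    @property
    def span(self) -> tuple[int, int]:
        return min(e.start for e in self.exons), max(e.end for e in self.exons)


def read_gff3(path) -> list[ExonFeature]:
    """Read exon features from a GFF3 file.

    Only ``exon``-type rows are considered.  Each must carry ``gene_id`` and
    ``role`` attributes; coordinates are converted from GFF3's 1-based
    inclusive convention to the internal 0-based half-open one.
    """
    feats: list[ExonFeature] = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                f = feature_from_line(line)
            except Exception as exc:  # gffutils raises bare exceptions
                raise FormatError(f"{path}:{lineno}: bad GFF3 row ({exc})") from exc
            if f.featuretype != "exon":
                continue
            if "gene_id" not in f.attributes:
                raise FormatError(f"{path}:{lineno}: exon row missing gene_id attribute")
            if "role" not in f.attributes:
                raise FormatError(f"{path}:{lineno}: exon row missing role attribute")
            if f.end < f.start:
                raise FormatError(f"{path}:{lineno}: end < start")
            rank = int(f.attributes["rank"][0]) if "rank" in f.attributes else 0
            try:
                feats.append(
                    ExonFeature(
                        gene_id=f.attributes["gene_id"][0],
                        role=f.attributes["role"][0],
                        start=f.start - 1,
                        end=f.end,
                        strand=f.strand,
                        rank=rank,
                        seqid=f.seqid,
                    )
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return feats


def write_gff3(features, path, source: str = "niltkit") -> None:
    """Write exon features as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"gene_id={f.gene_id};role={f.role};rank={f.rank}"
            fh.write(
                f"{f.seqid}\t{source}\texon\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )


def build_gene_models(features) -> list[GeneModel]:
    """Group exon features by gene and derive transcription-ordered models.

    Exons are sorted in transcription order (ascending genomic coordinates on
    the plus strand, descending on the minus strand) and re-ranked 1..n.
    A gene with overlapping exons, or split across strands, is rejected.
    """
    by_gene: dict[str, list[ExonFeature]] = {}
    for f in features:
        by_gene.setdefault(f.gene_id, []).append(f)
    models = []
    for gene_id in sorted(by_gene):
        exons = by_gene[gene_id]
        strands = {e.strand for e in exons}
        if len(strands) > 1:
            raise FormatError(f"gene {gene_id!r} has exons on both strands")
        strand = strands.pop()
        exons.sort(key=lambda e: e.start, reverse=(strand == "-"))
        by_coord = sorted(exons, key=lambda e: e.start)
        for a, b in zip(by_coord, by_coord[1:]):
            if b.start < a.end:
                raise FormatError(
                    f"gene {gene_id!r}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        exons = [replace(e, rank=i + 1) for i, e in enumerate(exons)]
        models.append(
            GeneModel(gene_id=gene_id, strand=strand, exons=tuple(exons),
                      seqid=exons[0].seqid)
        )
    return models


# ---------------------------------------------------------------------------
# Newick and report bundles
# ---------------------------------------------------------------------------

def read_newick(path) -> "skbio.TreeNode":
    return skbio.TreeNode.read(str(path) if not hasattr(path, "read") else path,
                               format="newick")


def write_newick(tree, path) -> None:
    tree.write(str(path), format="newick")


def write_reports(outdir, *, structure=None, pseudogenes=None, receptors=None,
                  identity=None, entropy=None, tree=None, features=None) -> list[str]:
    """Write whichever report components are supplied into *outdir*.

    ``structure``/``pseudogenes``/``receptors``/``identity``/``entropy`` are
    pandas DataFrames (written as TSV), ``tree`` an skbio TreeNode (Newick)
    and ``features`` exon features (GFF3).  Returns the paths written.
    GFF3 output round-trips losslessly through :func:`read_gff3`.
    """
    os.makedirs(outdir, exist_ok=True)
    written = []

    def _tsv(df, name):
        p = os.path.join(outdir, name)
        df.to_csv(p, sep="\t", index=False)
        written.append(p)

    if structure is not None:
        _tsv(structure, "structure.tsv")
    if pseudogenes is not None:
        _tsv(pseudogenes, "pseudogene_report.tsv")
    if receptors is not None:
        _tsv(receptors, "receptor_annotations.tsv")
    if identity is not None:
        p = os.path.join(outdir, "ig_identity_matrix.tsv")
        identity.to_csv(p, sep="\t")
        written.append(p)
    if entropy is not None:
        _tsv(entropy, "entropy.tsv")
    if tree is not None:
        p = os.path.join(outdir, "ig_tree.nwk")
        write_newick(tree, p)
        written.append(p)
    if features is not None:
        p = os.path.join(outdir, "annotations.gff3")
        write_gff3(features, p)
        written.append(p)
    return written


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
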