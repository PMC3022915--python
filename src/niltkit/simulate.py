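"""Ground-truthed synthetic NILT loci and clone libraries.

The generator emulates the study system: a BAC-scale locus carrying multiple
six-exon (or seven-exon, two-Ig) NILT genes on both strands, with the
published exon/intron lengths, GT-AG splice sites, phase-1 introns upstream
of the ITIM-bearing final exon (phase 0), planted Ig-domain cysteine pairs
(CX3C/CX6C/CX7C), diagnostic-residue groups, Ser/Thr-rich connecting
peptides, optional pseudogenizing lesions, and replicate-PCR clone libraries
with per-base substitution error.

Everything planted is recorded as truth, and the generator self-verifies: it
re-annotates each gene with the analysis modules and regenerates (bounded
retries) if a random background ever produces an accidental feature.  Planted
motif counts are exact by construction — cysteine and tyrosine are excluded
from background draws, so the only Cys pairs and ITIM tyrosines present are
the planted ones.

Backgrounds are uniform over the permitted alphabet; coding sequence is
produced by drawing a random synonymous codon per residue, so in-frame stops
cannot occur except where planted.  The clone-library error model is
substitution-only (indels would change the amplicon length, and the survey
compares equal-length Ig intervals).  All randomness flows from a single
integer seed through numpy's PCG64 generator, so outputs are byte-identical
across runs and platforms for a fixed seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from . import receptor as _receptor
from .genestruct import intron_phases_from_lengths, validate_gene
from .seqio import (ExonFeature, NamedSequence, build_gene_models, write_fasta,
                    write_gff3)
from .tables import GeneTemplate, salmon_templates

_MAX_RETRIES = 100

#: General protein background: no Cys (spacing classes stay exact) and no Tyr
#: (ITIM counts stay exact).
_BG = "ADEFGHIKLMNPQRSTVW"
#: Connecting-peptide background additionally excludes Ser/Thr so the planted
#: S/T count is exact.
_BG_CP = "ADEFGHIKLMNPQRVW"
#: Transmembrane background: hydrophobic, uncharged.
_BG_TM = "AFGILMVW"

_CODONS = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()
_STOPS = tuple(sorted(standard_dna_table.stop_codons))

#: Region-local 1-based positions of the planted extra cysteine pair.
EXTRA_CYS = {"CX3C": (27, 31), "CX6C": (24, 31), "CX7C": (23, 31)}

PSEUDOGENE_MODES = ("internal_stop", "delete_role_exon", "frameshift")


@dataclass
class GeneSpec:
    """One gene to embed: a template plus optional overrides."""

    template: GeneTemplate
    gene_id: str | None = None
    strand: str | None = None
    pseudogene: str | None = None  # one of PSEUDOGENE_MODES or None


@dataclass
class LocusConfig:
    """Locus-level generation parameters."""

    genes: list
    spacer_length: int = 10000
    locus_id: str = "locus"


@dataclass
class GeneTruth:
    """Everything planted for one gene (the downstream oracle)."""

    gene_id: str
    template_name: str
    strand: str
    exon_roles: tuple
    exon_lengths: tuple
    intron_lengths: tuple
    orf_length: int
    intron_phases: tuple
    protein: str | None
    cys_classes: dict
    itim_count: int
    group: int | None
    st_count: int
    cp_length: int
    tm_charged: bool
    pseudogene_mode: str | None = None
    pseudogene_flags: tuple = ()
    stop_position: int | None = None
    missing_role: str | None = None


@dataclass
class SyntheticTruth:
    """A generated locus with its complete ground truth."""

    locus: NamedSequence
    features: list
    genes: dict
    clone_truth: dict | None = None

    def models(self):
        return build_gene_models(self.features)

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        write_fasta([self.locus], os.path.join(outdir, "locus.fasta"))
        write_gff3(self.features, os.path.join(outdir, "annotations.gff3"))
        payload = {
            gid: {k: (sorted(v) if isinstance(v, (set, frozenset)) else v)
                  for k, v in asdict(t).items()}
            for gid, t in self.genes.items()
        }
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            json.dump(payload, fh, indent=1, default=list)


class TemplateError(ValueError):
    """Raised when a template cannot host the requested features."""


def _rand_nt(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _choice(rng, alphabet: str) -> str:
    return alphabet[int(rng.integers(0, len(alphabet)))]


def _design_protein(template: GeneTemplate, rng) -> tuple[str, dict]:
    """Plant all receptor features into a random background protein."""
    regions, exon_spans = _receptor.region_spans(
        template.exon_roles, template.exon_lengths
    )
    plen = template.protein_length
    cp_span = regions.get("CP")
    tm_span = regions["TM"]

    seq = []
    for i in range(plen):
        if cp_span and cp_span[0] <= i < cp_span[1]:
            seq.append(_choice(rng, _BG_CP))
        elif tm_span[0] <= i < tm_span[1]:
            seq.append(_choice(rng, _BG_TM))
        else:
            seq.append(_choice(rng, _BG))
    seq[0] = "M"

    # Ig domains: canonical cysteines at 17/89 (1-based, region-local), the
    # class-defining extra pair, and the diagnostic residues.
    for role in ("Ig1", "Ig2"):
        if role not in regions:
            continue
        s, e = regions[role]
        if e - s < 89:
            raise TemplateError(f"{role} of {template.name} shorter than 89 aa")
        cls = template.cys_classes.get(role, "CX3C")
        if cls not in EXTRA_CYS:
            raise TemplateError(f"unknown cysteine class {cls!r}")
        for pos1 in (17, 89) + EXTRA_CYS[cls]:
            seq[s + pos1 - 1] = "C"
        if template.group == 1:
            for pos1, res in zip((20, 32, 33, 34, 35, 66), "HSLYYL"):
                seq[s + pos1 - 1] = res
        elif template.group == 2:
            motif = _choice(rng, "PR") + "V" + _choice(rng, "FL") + "N"
            for pos1, res in zip((20, 32, 33, 34, 35, 66), "Q" + motif + "I"):
                seq[s + pos1 - 1] = res
        else:
            seq[s + 19] = "Q"
            seq[s + 65] = "I"

    # Connecting peptide: exactly st_count Ser/Thr.
    cp_len = 0
    if cp_span:
        cp_len = cp_span[1] - cp_span[0]
        if template.st_count > cp_len:
            raise TemplateError(
                f"{template.name}: {template.st_count} S/T requested in a "
                f"{cp_len}-aa connecting peptide"
            )
        pos = rng.choice(np.arange(cp_span[0], cp_span[1]),
                         size=template.st_count, replace=False)
        for p in pos:
            seq[int(p)] = _choice(rng, "ST")

    if template.tm_charged:
        seq[(tm_span[0] + tm_span[1]) // 2] = "R"

    # ITIMs in the Cyt2 exon (the phase-0 terminal exon).
    cyt2 = exon_spans[template.exon_roles[-1]]
    span = cyt2[1] - cyt2[0]
    k = template.itim_count
    if 6 * k > span:
        raise TemplateError(
            f"{template.name}: {k} ITIMs do not fit in a {span}-aa Cyt2 exon"
        )
    slot = span // k
    for m in range(k):
        start = cyt2[0] + m * slot + int(rng.integers(0, slot - 6 + 1))
        motif = (_choice(rng, "SIVL") + _choice(rng, _BG) + "Y"
                 + _choice(rng, _BG) + _choice(rng, _BG) + _choice(rng, "IVL"))
        seq[start : start + 6] = list(motif)

    return "".join(seq), regions


def _back_translate(protein: str, rng) -> str:
    codons = [_CODONS[aa][int(rng.integers(0, len(_CODONS[aa])))] for aa in protein]
    codons.append(_STOPS[int(rng.integers(0, len(_STOPS)))])
    return "".join(codons)


def _gene_block(template: GeneTemplate, cds: str, exon_lengths, intron_lengths,
                rng) -> tuple[str, list]:
    """Assemble exons+introns in transcribed orientation; returns the block
    and block-local exon intervals (transcription order)."""
    parts, intervals = [], []
    pos = 0
    acc = 0
    for i, elen in enumerate(exon_lengths):
        exon_seq = cds[acc : acc + elen]
        acc += elen
        parts.append(exon_seq)
        intervals.append((pos, pos + elen))
        pos += elen
        if i < len(exon_lengths) - 1:
            ilen = intron_lengths[i]
            if ilen < 4:
                raise TemplateError("introns must be at least 4 nt (GT..AG)")
            intron = "GT" + _rand_nt(rng, ilen - 4) + "AG"
            parts.append(intron)
            pos += ilen
    return "".join(parts), intervals


def _apply_lesion(template: GeneTemplate, cds: str, mode: str, rng):
    """Apply a pseudogenizing lesion; returns (cds, exon_roles, exon_lengths,
    intron_lengths)."""
    roles = list(template.exon_roles)
    elens = list(template.exon_lengths)
    ilens = list(template.intron_lengths)
    if mode == "internal_stop":
        # stop immediately after the last (position-89) Ig1 cysteine
        _, exon_spans = _receptor.region_spans(template.exon_roles, template.exon_lengths)
        codon = exon_spans["Ig1"][0] + 89
        cds = cds[: 3 * codon] + "TAA" + cds[3 * codon + 3 :]
    elif mode == "delete_role_exon":
        idx = roles.index("CP")
        start = sum(elens[:idx])
        cds = cds[:start] + cds[start + elens[idx] :]
        del roles[idx], elens[idx], ilens[idx]
    elif mode == "frameshift":
        _, exon_spans = _receptor.region_spans(template.exon_roles, template.exon_lengths)
        nt = 3 * (exon_spans["Ig1"][0] + 40) + 1  # inside the Ig1 exon
        cds = cds[:nt] + cds[nt + 1 :]
        elens[roles.index("Ig1")] -= 1
    else:
        raise ValueError(f"unknown pseudogene mode {mode!r}")
    return cds, tuple(roles), tuple(elens), tuple(ilens)


_EXPECTED_FLAGS = {
    "internal_stop": {"internal_stop"},
    "delete_role_exon": {"missing_role_exon"},
}


def _verify_intact(gene_id, model, locus_seq, template, truth: GeneTruth) -> bool:
    """Re-annotate a freshly placed intact gene and compare with its truth."""
    report = validate_gene(model, locus_seq)
    if report.flags:
        return False
    ann = _receptor.annotate_receptor(model, locus_seq)
    if ann.protein != truth.protein:
        return False
    for role, cls in template.cys_classes.items():
        if ann.cys_profiles[role].spacing_class != cls:
            return False
    if len(ann.itims) != template.itim_count:
        return False
    if (ann.st_count, ann.cp_length) != (truth.st_count, truth.cp_length):
        return False
    if ann.tm_charged != template.tm_charged:
        return False
    expected_group = str(template.group) if template.group else "unclassified"
    if (ann.group.group if ann.group else None) != expected_group:
        return False
    return True


def simulate_locus(config: LocusConfig, seed: int = 0) -> SyntheticTruth:
    """Generate a locus per *config*; deterministic for a fixed seed.

    Genes are embedded left to right with random spacer sequence between and
    around them.  Each gene is built, placed on a private scaffold, and
    re-annotated with the analysis modules; if an accidental feature slips
    through (bounded probability from the random background), the gene is
    regenerated, up to 100 attempts.
    """
    rng = np.random.default_rng(int(seed))
    chunks: list[str] = []
    features: list[ExonFeature] = []
    truths: dict[str, GeneTruth] = {}
    offset = 0

    for gi, spec in enumerate(config.genes):
        template = spec.template
        gene_id = spec.gene_id or template.name
        strand = spec.strand or template.strand
        spacer = _rand_nt(rng, config.spacer_length)
        chunks.append(spacer)
        offset += len(spacer)

        placed = None
        for _attempt in range(_MAX_RETRIES):
            protein, _regions = _design_protein(template, rng)
            cds = _back_translate(protein, rng)
            roles, elens, ilens = (template.exon_roles, template.exon_lengths,
                                   template.intron_lengths)
            if spec.pseudogene:
                cds, roles, elens, ilens = _apply_lesion(
                    template, cds, spec.pseudogene, rng
                )
            block, intervals = _gene_block(template, cds, elens, ilens, rng)
            if strand == "-":
                from .seqio import reverse_complement
                placed_block = reverse_complement(block)
                genomic = [
                    (offset + len(block) - e, offset + len(block) - s)
                    for s, e in intervals
                ]
            else:
                placed_block = block
                genomic = [(offset + s, offset + e) for s, e in intervals]
            gene_feats = [
                ExonFeature(gene_id=gene_id, role=role, start=s, end=e,
                            strand=strand, rank=r + 1,
                            seqid=config.locus_id)
                for r, (role, (s, e)) in enumerate(zip(roles, genomic))
            ]
            # verify on a private scaffold before committing
            scaffold = "".join(chunks) + placed_block
            model = build_gene_models(gene_feats)[0]
            truth = GeneTruth(
                gene_id=gene_id, template_name=template.name, strand=strand,
                exon_roles=roles, exon_lengths=elens, intron_lengths=ilens,
                orf_length=sum(elens),
                intron_phases=intron_phases_from_lengths(elens),
                protein=None if spec.pseudogene else protein,
                cys_classes=dict(template.cys_classes),
                itim_count=template.itim_count, group=template.group,
                st_count=template.st_count,
                cp_length=(template.exon_lengths[template.exon_roles.index("CP")] // 3
                           if "CP" in template.exon_roles else 0),
                tm_charged=template.tm_charged,
                pseudogene_mode=spec.pseudogene,
            )
            if spec.pseudogene:
                report = validate_gene(model, scaffold)
                expected = _EXPECTED_FLAGS.get(spec.pseudogene)
                if expected is not None and report.flags != expected:
                    continue
                if spec.pseudogene == "frameshift" and "frameshift" not in report.flags:
                    continue
                truth.pseudogene_flags = tuple(sorted(report.flags))
                truth.stop_position = report.stop_position
                truth.missing_role = report.missing_role
            else:
                if not _verify_intact(gene_id, model, scaffold, template, truth):
                    continue
            placed = (placed_block, gene_feats, truth)
            break
        if placed is None:
            raise TemplateError(
                f"could not generate {gene_id} without accidental features "
                f"after {_MAX_RETRIES} attempts"
            )
        block_seq, gene_feats, truth = placed
        chunks.append(block_seq)
        offset += len(block_seq)
        features.extend(gene_feats)
        truths[gene_id] = truth

    chunks.append(_rand_nt(rng, config.spacer_length))
    locus = NamedSequence(config.locus_id, "".join(chunks), "nt")
    return SyntheticTruth(locus=locus, features=features, genes=truths)


def salmon_bac_config(spacer_length: int = 10000) -> LocusConfig:
    """The default study emulation: the six salmon NILT genes plus two
    pseudogenes (a two-Ig gene with an internal stop in Ig1, and a two-Ig
    gene lacking its connecting-peptide exon)."""
    t = salmon_templates()
    genes = [GeneSpec(t[name]) for name in sorted(t)]
    genes.append(GeneSpec(t["Ssa-NILT3"], gene_id="Ssa-NILTp1",
                          pseudogene="internal_stop"))
    genes.append(GeneSpec(t["Ssa-NILT3"], gene_id="Ssa-NILTp2", strand="-",
                          pseudogene="delete_role_exon"))
    return LocusConfig(genes=genes, spacer_length=spacer_length)


# ---------------------------------------------------------------------------
# Clone libraries
# ---------------------------------------------------------------------------

from .repertoire import Clone, CloneSet  # noqa: E402


def simulate_clone_library(templates: dict, n_pcr: int = 10,
                           clones_per_pcr: int = 10,
                           error_rate: float = 0.002,
                           seed: int = 0,
                           weights: dict | None = None):
    """Draw a replicate-PCR clone library from Ig-amplicon templates.

    ``templates`` maps template name → amplicon nucleotide sequence;
    ``weights`` (same keys) biases the draw, default uniform.  Each clone
    acquires independent per-base substitutions at *error_rate*.  Returns
    ``(CloneSet, truth)`` where truth records each clone's source template
    and error count plus per-template multiplicities.
    """
    if not templates:
        raise ValueError("empty template set")
    names = sorted(templates)
    w = np.array([float((weights or {}).get(n, 1.0)) for n in names])
    w = w / w.sum()
    rng = np.random.default_rng(int(seed))
    clones, truth_clones = [], {}
    multiplicities = {n: 0 for n in names}
    total_errors = 0
    alphabet = "ACGT"
    for pcr in range(1, n_pcr + 1):
        for c in range(1, clones_per_pcr + 1):
            name = names[int(rng.choice(len(names), p=w))]
            seq = list(templates[name])
            n_err = 0
            if error_rate > 0:
                hits = np.flatnonzero(rng.random(len(seq)) < error_rate)
                for i in hits:
                    orig = seq[i]
                    seq[i] = _choice(rng, alphabet.replace(orig, ""))
                n_err = len(hits)
            clone_id = f"pcr{pcr}_clone{c}"
            clones.append(Clone(clone_id, "".join(seq), pcr))
            truth_clones[clone_id] = {"template": name, "n_errors": n_err}
            multiplicities[name] += 1
            total_errors += n_err
    truth = {
        "clones": truth_clones,
        "multiplicities": multiplicities,
        "total_errors": total_errors,
    }
    return CloneSet(clones), truth
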