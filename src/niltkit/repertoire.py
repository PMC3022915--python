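"""Single-individual clone-repertoire survey of Ig-domain amplicons.

The survey procedure: clones from replicate PCRs are screened for
NILT-likeness (best translated identity to a known Ig domain above a
threshold), deduplicated exactly at the nucleotide level, and only sequences
observed more than once are retained as putative genes; sequences observed
once are tallied as singletons after translation and deduplication at the
amino-acid level (synonymous singletons collapse).  Retained sequences are
assigned to known genes by exact nucleotide identity over the amplified
interval; anything else is novel and is group-classified by its diagnostic
residues.

The published headline counts (81 positive clones, 7 sequences, 19
singletons) came from one fish's genome and real PCR and are not reproduced
here; the procedure is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from . import align as _align
from . import receptor as _receptor
from .seqio import NamedSequence

DEFAULT_MIN_IDENTITY = 70.0

#: Degenerate IUPAC codes trimmed from amplicon ends before exact matching.
_DEGENERATE = set("RYSWKMBDHVN")


@dataclass(frozen=True)
class Clone:
    """One sequenced clone with its source PCR replicate (1-based)."""

    id: str
    seq: str
    replicate: int


@dataclass
class CloneSet:
    clones: list

    def __len__(self) -> int:
        return len(self.clones)

    def replicates(self) -> set:
        return {c.replicate for c in self.clones}


@dataclass
class RepertoireSummary:
    """Outcome of the dedup/retention procedure.

    ``retained`` maps each distinct nucleotide sequence observed ≥2 times to
    its clone count; ``singleton_seqs_aa`` are the distinct amino-acid
    translations of the once-observed sequences.  Every positive clone is
    accounted for exactly once across retained groups and singleton support.
    """

    n_positive: int
    retained: dict = field(default_factory=dict)
    singleton_support: int = 0
    singletons_aa: int = 0
    singleton_seqs_aa: tuple = ()
    retained_aa_count: int = 0
    assignments: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sequence": seq,
                "count": count,
                "assignment": self.assignments.get(seq, "-"),
            }
            for seq, count in sorted(
                self.retained.items(), key=lambda kv: (-kv[1], kv[0])
            )
        ]
        return pd.DataFrame(rows, columns=["sequence", "count", "assignment"])


def _best_translation(nt: str) -> str | None:
    """Longest-ORF-style translation: the first forward frame whose full
    translation is stop-free; None when every frame hits a stop."""
    for frame in range(3):
        sub = nt[frame : frame + 3 * ((len(nt) - frame) // 3)]
        if not sub:
            continue
        aa = str(Seq(sub).translate())
        if "*" not in aa:
            return aa
    return None


def screen_positive(clones: CloneSet, known_igs,
                    min_identity: float = DEFAULT_MIN_IDENTITY) -> CloneSet:
    """Keep clones whose best translated identity to any known Ig domain
    reaches *min_identity* percent.

    ``known_igs`` are amino-acid sequences (strings or NamedSequence).
    Untranslatable clones (a stop in every forward frame) are excluded with a
    warning.
    """
    refs = [s.seq if isinstance(s, NamedSequence) else str(s) for s in known_igs]
    if not refs:
        raise ValueError("need at least one known Ig domain to screen against")
    kept = []
    for clone in clones.clones:
        aa = _best_translation(clone.seq)
        if aa is None:
            warnings.warn(f"clone {clone.id!r} untranslatable in any frame; excluded")
            continue
        best = max(
            _align.global_align(aa, ref, alphabet="aa").identity_pct for ref in refs
        )
        if best >= min_identity:
            kept.append(clone)
    return CloneSet(kept)


def summarize_clones(positive: CloneSet) -> RepertoireSummary:
    """Dedup at the nucleotide level and apply the observed-more-than-once
    retention rule; tally singletons at the amino-acid level."""
    counts: dict[str, int] = {}
    for clone in positive.clones:
        counts[clone.seq] = counts.get(clone.seq, 0) + 1
    retained = {seq: k for seq, k in counts.items() if k >= 2}
    single_nt = [seq for seq, k in counts.items() if k == 1]
    single_aa = []
    for seq in single_nt:
        aa = _best_translation(seq)
        single_aa.append(aa if aa is not None else seq)
    distinct_aa = tuple(sorted(set(single_aa)))
    retained_aa = {_best_translation(s) or s for s in retained}
    return RepertoireSummary(
        n_positive=len(positive),
        retained=retained,
        singleton_support=len(single_nt),
        singletons_aa=len(distinct_aa),
        singleton_seqs_aa=distinct_aa,
        retained_aa_count=len(retained_aa),
    )


def _trim_degenerate(seq: str) -> str:
    start, end = 0, len(seq)
    while start < end and seq[start] in _DEGENERATE:
        start += 1
    while end > start and seq[end - 1] in _DEGENERATE:
        end -= 1
    return seq[start:end]


def match_known(summary: RepertoireSummary, known_genes,
                reference_ig: str = _receptor.REFERENCE_IG) -> dict:
    """Assign retained sequences to known genes by exact nucleotide identity.

    ``known_genes`` maps gene id → Ig-domain amplicon nucleotide sequence.
    Degenerate primer bases are trimmed from both amplicon ends before
    comparison.  A retained sequence matching two different genes exactly is
    ambiguous and raises.  Unmatched sequences are labelled ``novel`` and
    group-classified from their translation; the call is recorded as
    ``novel (group N)`` when classifiable.  Assignments are stored on the
    summary and returned.
    """
    knowns = {
        gid: _trim_degenerate(s.seq if isinstance(s, NamedSequence) else str(s))
        for gid, s in dict(known_genes).items()
    }
    assignments: dict[str, str] = {}
    for seq in summary.retained:
        trimmed = _trim_degenerate(seq)
        hits = sorted(gid for gid, ref in knowns.items() if ref == trimmed)
        if len(hits) > 1:
            raise ValueError(
                f"retained sequence matches multiple known genes: {', '.join(hits)}"
            )
        if hits:
            assignments[seq] = hits[0]
            continue
        label = "novel"
        aa = _best_translation(trimmed)
        if aa is not None:
            profile = _receptor.cys_profile(aa)
            call = _receptor.classify_ig(aa, profile.spacing_class, reference_ig)
            if call.group in ("1", "2"):
                label = f"novel (group {call.group})"
        assignments[seq] = label
    summary.assignments = assignments
    return assignments
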