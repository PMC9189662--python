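"""Mature and precursor tRNA transcript models and the consensus coordinate system.

tRNA genes are named ``Isotype-Anticodon-TranscriptNo-GeneCopy`` (e.g.
``Arg-CCT-2-1``).  Mature transcripts are the isodecoder-level objects
(``Arg-CCT-2``): introns spliced out, the post-transcriptional ``CCA``
appended, genes with identical mature sequence collapsed into one transcript.
Precursor transcripts keep the unspliced body and add 5' leader / 3' trailer
flanks; trailer bases are labelled ``T1, T2, ...`` (leader ``L1`` counting
toward the 5' end) so that precursor-derived fragments are nameable.

All positional analyses of mature-derived fragments happen on a single
consensus axis 1..76 with the anticodon pinned at 34-36 and the CCA tail at
74-76.  Transcripts whose length differs from 76 are mapped onto that axis by
piecewise anchoring (5' arm forward from 1, anticodon forced to 35, 3' arm
anchored backward from 76).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "TRNAGene",
    "TRNATranscript",
    "GENE_NAME_RE",
    "load_reference",
    "build_mature",
    "collapse_isodecoders",
    "build_precursor",
    "consensus_map",
    "consensus_position",
    "position_for_consensus",
    "write_transcript_table",
    "SmallRNA",
    "ReferenceBundle",
]

GENE_NAME_RE = re.compile(
    r"^(?P<isotype>[A-Za-z]{3,4})-(?P<anticodon>[ACGT]{3})"
    r"-(?P<transcript_no>\d+)-(?P<gene_copy>\d+)$"
)

_VALID_BASES = set("ACGTN")

# consensus anchors (canonical cloverleaf numbering)
ANTICODON_CENTER = 35
CCA_FIRST = 74
CONSENSUS_LEN = 76


def _check_seq(seq: str, what: str) -> str:
    seq = seq.upper()
    if seq and not set(seq) <= _VALID_BASES:
        bad = sorted(set(seq) - _VALID_BASES)
        raise ValueError(f"{what} contains invalid characters {bad}")
    return seq


@dataclass(frozen=True)
class TRNAGene:
    """One genomic tRNA gene, introns included, with flanking sequences."""

    gene_name: str
    isotype: str
    anticodon: str
    transcript_no: int
    gene_copy: int
    body_seq: str
    intron_intervals: tuple[tuple[int, int], ...] = ()
    leader_seq: str = ""
    trailer_seq: str = ""
    species: str = "synthetic"

    def __post_init__(self) -> None:
        m = GENE_NAME_RE.match(self.gene_name)
        if m is None:
            raise ValueError(
                f"gene name {self.gene_name!r} does not match "
                "'Isotype-Anticodon-TranscriptNo-GeneCopy'"
            )
        if (
            m["isotype"] != self.isotype
            or m["anticodon"] != self.anticodon
            or int(m["transcript_no"]) != self.transcript_no
            or int(m["gene_copy"]) != self.gene_copy
        ):
            raise ValueError(f"gene name {self.gene_name!r} disagrees with its fields")
        object.__setattr__(self, "body_seq", _check_seq(self.body_seq, "body_seq"))
        object.__setattr__(self, "leader_seq", _check_seq(self.leader_seq, "leader_seq"))
        object.__setattr__(self, "trailer_seq", _check_seq(self.trailer_seq, "trailer_seq"))
        last = 0
        for start, end in self.intron_intervals:
            if not (1 <= start <= end <= len(self.body_seq)):
                raise ValueError(f"intron [{start},{end}] outside body of {self.gene_name}")
            if start <= last:
                raise ValueError(f"introns of {self.gene_name} overlap or are unsorted")
            last = end

    @property
    def spliced_body(self) -> str:
        body = self.body_seq
        for start, end in reversed(self.intron_intervals):
            body = body[: start - 1] + body[end:]
        return body

    @property
    def isodecoder_name(self) -> str:
        return f"{self.isotype}-{self.anticodon}-{self.transcript_no}"


@dataclass(frozen=True)
class TRNATranscript:
    """A mature (isodecoder) or precursor tRNA transcript.

    ``coord_labels[i]`` is the position label of base ``i+1``: plain integers
    (as strings) for body positions, ``"L<i>"`` / ``"T<i>"`` for precursor
    leader / trailer bases.
    """

    transcript_name: str
    kind: str  # "mature" | "precursor"
    seq: str
    coord_labels: tuple[str, ...]
    isotype: str
    anticodon: str
    transcript_no: int
    gene_copy: int | None = None
    copy_count: int = 1
    source_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("mature", "precursor"):
            raise ValueError(f"unknown transcript kind {self.kind!r}")
        if len(self.coord_labels) != len(self.seq):
            raise ValueError("coord_labels length must equal sequence length")
        if self.kind == "mature" and not self.seq.endswith("CCA"):
            raise ValueError(f"mature transcript {self.transcript_name} does not end in CCA")

    @property
    def length(self) -> int:
        return len(self.seq)

    def label(self, pos: int) -> str:
        """Position label (1-based transcript position)."""
        if not 1 <= pos <= self.length:
            raise IndexError(f"position {pos} outside transcript of length {self.length}")
        return self.coord_labels[pos - 1]

    def position_of_label(self, label: str) -> int:
        try:
            return self.coord_labels.index(str(label)) + 1
        except ValueError:
            raise KeyError(f"label {label!r} not present on {self.transcript_name}") from None

    @property
    def sort_key(self) -> tuple:
        return (self.isotype, self.anticodon, self.transcript_no, self.gene_copy or 0)


def load_reference(fasta_path: str | Path, annotation_path: str | Path) -> list[TRNAGene]:
    """Load tRNA genes from a FASTA plus a TSV annotation table.

    The annotation table has columns ``gene_name, isotype, anticodon,
    intron_start, intron_end, leader_seq, trailer_seq``; empty intron fields
    mean intronless, comma-separated values mean multiple introns.  Returns
    genes sorted lexicographically by name.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    names = [r.id for r in records]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise ValueError(f"duplicate gene names in FASTA: {dupes}")

    annot = pd.read_csv(annotation_path, sep="\t", dtype=str).fillna("")
    annot = annot.set_index("gene_name", verify_integrity=True)

    genes = []
    for rec in records:
        m = GENE_NAME_RE.match(rec.id)
        if m is None:
            raise ValueError(
                f"FASTA record {rec.id!r} does not match the "
                "'Isotype-Anticodon-TranscriptNo-GeneCopy' grammar"
            )
        if rec.id not in annot.index:
            raise ValueError(f"no annotation row for gene {rec.id!r}")
        row = annot.loc[rec.id]
        starts = [int(x) for x in str(row["intron_start"]).split(",") if x.strip()]
        ends = [int(x) for x in str(row["intron_end"]).split(",") if x.strip()]
        if len(starts) != len(ends):
            raise ValueError(f"intron_start/intron_end mismatch for {rec.id}")
        genes.append(
            TRNAGene(
                gene_name=rec.id,
                isotype=m["isotype"],
                anticodon=m["anticodon"],
                transcript_no=int(m["transcript_no"]),
                gene_copy=int(m["gene_copy"]),
                body_seq=str(rec.seq),
                intron_intervals=tuple(zip(starts, ends)),
                leader_seq=str(row.get("leader_seq", "")),
                trailer_seq=str(row.get("trailer_seq", "")),
            )
        )
    genes.sort(key=lambda g: g.gene_name)
    return genes


def build_mature(gene: TRNAGene) -> TRNATranscript:
    """Mature transcript of a single gene: introns spliced, CCA appended."""
    seq = gene.spliced_body + "CCA"
    return TRNATranscript(
        transcript_name=gene.isodecoder_name,
        kind="mature",
        seq=seq,
        coord_labels=tuple(str(i) for i in range(1, len(seq) + 1)),
        isotype=gene.isotype,
        anticodon=gene.anticodon,
        transcript_no=gene.transcript_no,
        gene_copy=None,
        copy_count=1,
        source_genes=(gene.gene_name,),
    )


def collapse_isodecoders(genes: list[TRNAGene]) -> list[TRNATranscript]:
    """Build mature transcripts, collapsing genes with identical mature sequence.

    The collapsed transcript takes the name of the canonically first gene
    (lexicographic by (isotype, anticodon, transcript number)) and records how
    many gene copies share the sequence.
    """
    by_seq: dict[str, list[TRNAGene]] = {}
    for gene in sorted(genes, key=lambda g: (g.isotype, g.anticodon, g.transcript_no, g.gene_copy)):
        by_seq.setdefault(build_mature(gene).seq, []).append(gene)
    out = []
    for seq, members in by_seq.items():
        rep = members[0]
        t = build_mature(rep)
        out.append(
            TRNATranscript(
                transcript_name=t.transcript_name,
                kind="mature",
                seq=t.seq,
                coord_labels=t.coord_labels,
                isotype=t.isotype,
                anticodon=t.anticodon,
                transcript_no=t.transcript_no,
                gene_copy=None,
                copy_count=len(members),
                source_genes=tuple(g.gene_name for g in members),
            )
        )
    out.sort(key=lambda t: t.sort_key)
    return out


def build_precursor(gene: TRNAGene, leader_len: int = 0, trailer_len: int = 0) -> TRNATranscript:
    """Precursor transcript: leader suffix + unspliced body + trailer prefix.

    No CCA is appended.  Trailer bases are labelled ``T1..T<trailer_len>``,
    leader bases ``L<leader_len>..L1`` (L1 adjacent to the body).
    """
    if leader_len > len(gene.leader_seq):
        raise ValueError(
            f"requested leader {leader_len} exceeds available "
            f"{len(gene.leader_seq)} for {gene.gene_name}"
        )
    if trailer_len > len(gene.trailer_seq):
        raise ValueError(
            f"requested trailer {trailer_len} exceeds available "
            f"{len(gene.trailer_seq)} for {gene.gene_name}"
        )
    leader = gene.leader_seq[len(gene.leader_seq) - leader_len :] if leader_len else ""
    trailer = gene.trailer_seq[:trailer_len]
    seq = leader + gene.body_seq + trailer
    labels = (
        tuple(f"L{i}" for i in range(leader_len, 0, -1))
        + tuple(str(i) for i in range(1, len(gene.body_seq) + 1))
        + tuple(f"T{i}" for i in range(1, trailer_len + 1))
    )
    return TRNATranscript(
        transcript_name=gene.gene_name,
        kind="precursor",
        seq=seq,
        coord_labels=labels,
        isotype=gene.isotype,
        anticodon=gene.anticodon,
        transcript_no=gene.transcript_no,
        gene_copy=gene.gene_copy,
        copy_count=1,
        source_genes=(gene.gene_name,),
    )


def _anticodon_center(transcript: TRNATranscript) -> int:
    """Transcript position of the anticodon's middle base.

    The anticodon 3-mer occurrence closest to its canonical location (scaled
    to transcript length) is used; if the 3-mer is absent the canonical
    position is assumed.
    """
    L = transcript.length
    target = round(ANTICODON_CENTER * L / CONSENSUS_LEN)
    candidates = [
        p + 1
        for p in range(1, L - 1)
        if transcript.seq[p - 1 : p + 2] == transcript.anticodon
    ]
    if not candidates:
        return min(max(target, 3), L - 2)
    return min(candidates, key=lambda c: abs(c - target))


def consensus_map(transcript: TRNATranscript) -> np.ndarray:
    """Map transcript positions 1..L of a mature tRNA onto the consensus 1..76 axis.

    Piecewise anchoring: the 5' arm is indexed forward from 1, the anticodon
    block is forced to 34-36, and the 3' arm is anchored backward from 76 so
    that the CCA tail always lands on 74-76.  Extra variable-loop bases of
    long tRNAs share label 37 (nearest label, ties toward 5').  Returns an
    array ``cmap`` with ``cmap[p-1]`` the consensus label of position ``p``.
    """
    if transcript.kind != "mature":
        raise ValueError("consensus positions are defined for mature transcripts only")
    L = transcript.length
    a_c = _anticodon_center(transcript)
    cmap = np.empty(L, dtype=int)
    for p in range(1, a_c - 1):
        cmap[p - 1] = min(p, ANTICODON_CENTER - 2)
    for offset, label in zip((-1, 0, 1), (34, 35, 36)):
        idx = a_c + offset
        if 1 <= idx <= L:
            cmap[idx - 1] = label
    for p in range(a_c + 2, L + 1):
        cmap[p - 1] = max(37, CONSENSUS_LEN - (L - p))
    return cmap


def consensus_position(transcript: TRNATranscript, pos: int) -> int:
    """Consensus label of 1-based transcript position ``pos`` (mature only)."""
    if transcript.kind != "mature":
        raise ValueError("consensus positions are defined for mature transcripts only")
    if not 1 <= pos <= transcript.length:
        raise IndexError(f"position {pos} outside 1..{transcript.length}")
    return int(consensus_map(transcript)[pos - 1])


def position_for_consensus(transcript: TRNATranscript, label: int, side: str = "5p") -> int:
    """Inverse consensus lookup: a transcript position mapping to ``label``.

    When several positions share the label, ``side="5p"`` returns the first
    and ``side="3p"`` the last; when the label is absent (a deletion relative
    to the consensus) the nearest labelled position is returned.
    """
    cmap = consensus_map(transcript)
    hits = np.flatnonzero(cmap == label)
    if hits.size == 0:
        nearest = int(np.argmin(np.abs(cmap - label)))
        return nearest + 1
    return int(hits[0] + 1) if side == "5p" else int(hits[-1] + 1)


@dataclass(frozen=True)
class SmallRNA:
    """A non-tRNA small-RNA feature (miRNA or other annotated small ncRNA)."""

    name: str
    seq: str
    kind: str  # "miRNA" | "other"

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", _check_seq(self.seq, f"{self.name} seq"))
        if self.kind not in ("miRNA", "other"):
            raise ValueError(f"unknown small RNA kind {self.kind!r}")


@dataclass
class ReferenceBundle:
    """Everything the pipeline aligns against and names with.

    ``mature`` holds isodecoder-collapsed transcripts, ``precursors`` the
    per-gene precursor transcripts (with flanks), ``smallrnas`` the annotated
    non-tRNA features.
    """

    genes: list[TRNAGene] = field(default_factory=list)
    mature: list[TRNATranscript] = field(default_factory=list)
    precursors: list[TRNATranscript] = field(default_factory=list)
    smallrnas: list[SmallRNA] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [t.transcript_name for t in self.mature + self.precursors] + [
            s.name for s in self.smallrnas
        ]
        if len(names) != len(set(names)):
            raise ValueError("duplicate feature names in reference bundle")

    @property
    def transcripts(self) -> list[TRNATranscript]:
        return self.mature + self.precursors

    def transcript(self, name: str) -> TRNATranscript:
        for t in self.transcripts:
            if t.transcript_name == name:
                return t
        raise KeyError(f"no transcript named {name!r}")

    def alignment_targets(self) -> list[tuple[str, str, str]]:
        """(name, sequence, kind) triples for the aligner index."""
        out = [(t.transcript_name, t.seq, "mature") for t in self.mature]
        out += [(t.transcript_name, t.seq, "precursor") for t in self.precursors]
        out += [(s.name, s.seq, s.kind) for s in self.smallrnas]
        return out


def write_transcript_table(transcripts: list[TRNATranscript], path: str | Path) -> pd.DataFrame:
    """Serialize transcripts as a TSV (name, kind, length, seq) for inspection."""
    df = pd.DataFrame(
        {
            "name": [t.transcript_name for t in transcripts],
            "kind": [t.kind for t in transcripts],
            "length": [t.length for t in transcripts],
            "copy_count": [t.copy_count for t in transcripts],
            "seq": [t.seq for t in transcripts],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return df
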