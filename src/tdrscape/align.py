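"""Adapter trimming, ungapped transcript alignment, and fragment counting.

tDRs are contiguous subsequences of mature or precursor tRNA transcripts, so
alignment is an exact ungapped end-to-end search: every placement of the read
on every reference feature with at most ``max_mismatches`` mismatches is a
hit, reported up to ``max_hits`` per read, and the minimal-mismatch hits are
flagged best.  Reads are assumed sense-strand.

Counting uses only the best hits of each read ("primary alignments"): the set
of best-hit transcripts plus the fragment boundaries and any shared
mismatches (variant codes) define one fragment key, and each read contributes
exactly one count to exactly one record — multi-mapping reads are never
double counted.  Non-tRNA reads are assigned to the annotated miRNA/other
feature they best align to.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .naming import VariantCode, format_name
from .reference import ReferenceBundle, TRNATranscript

__all__ = [
    "AlignmentHit",
    "TDRRecord",
    "CountMatrix",
    "trim_read",
    "trim_reads",
    "AlignmentIndex",
    "align_reads",
    "group_to_records",
    "record_name",
    "count_features",
    "quantify_samples",
    "ingest_sam",
    "write_sam",
]

logger = logging.getLogger(__name__)

_BASE_CODE = {b: i for i, b in enumerate("ACGTN")}


@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    target: str  # feature name
    kind: str  # mature | precursor | miRNA | other
    start: int  # 1-based position on the target
    end: int  # 1-based inclusive
    mismatches: tuple[tuple[int, str, str], ...]  # (fragment-relative pos, ref, obs)
    score: int  # mismatch count, lower is better
    is_best: bool = False


@dataclass
class TDRRecord:
    """One unique tDR fragment with per-sample counts."""

    transcript_set: tuple[str, ...]
    start_label: str
    end_label: str
    variants: tuple[VariantCode, ...]
    representative: str
    counts: dict = field(default_factory=dict)
    kind: str = "tDR"

    @property
    def fragment_key(self) -> tuple:
        return (self.transcript_set, self.start_label, self.end_label, self.variants)

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class CountMatrix:
    """Features x samples integer counts with per-feature kind metadata."""

    counts: pd.DataFrame
    kind: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate feature names in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.counts.loc[self.kind[self.kind == kind].index]

    def write(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "kind", self.kind)
        out.to_csv(path, sep="\t", index_label="feature")


# ---------------------------------------------------------------------------
# trimming


def trim_read(seq: str, adapter: str) -> str:
    """Remove the longest read suffix that is an adapter prefix.

    A suffix qualifies if it matches the adapter prefix exactly over >= 6
    bases, or equals the full adapter with at most one mismatch.
    """
    max_k = min(len(seq), len(adapter))
    for k in range(max_k, 5, -1):
        suffix = seq[-k:]
        prefix = adapter[:k]
        if suffix == prefix:
            return seq[:-k]
        if k == len(adapter) and sum(a != b for a, b in zip(suffix, prefix)) <= 1:
            return seq[:-k]
    return seq


def trim_reads(
    fastq: str | Path | list[tuple[str, str]],
    adapter: str,
    min_len: int = 15,
) -> tuple[list[tuple[str, str]], dict]:
    """Adapter-trim a FASTQ (path or (id, seq) pairs); drop reads < ``min_len``.

    Returns ``(kept_reads, stats)`` where stats counts input, kept and
    discarded reads.
    """
    if len(adapter) < 10:
        raise ValueError("adapter must be at least 10 bases")
    if isinstance(fastq, (str, Path)):
        try:
            with pysam.FastxFile(str(fastq)) as fh:
                pairs = [(entry.name, entry.sequence.upper()) for entry in fh]
        except OSError as exc:
            raise ValueError(f"malformed or unreadable FASTQ {fastq}: {exc}") from exc
    else:
        pairs = [(rid, seq.upper()) for rid, seq in fastq]
    kept, discarded = [], 0
    for rid, seq in pairs:
        trimmed = trim_read(seq, adapter)
        if len(trimmed) < min_len:
            discarded += 1
        else:
            kept.append((rid, trimmed))
    stats = {"input": len(pairs), "kept": len(kept), "discarded_short": discarded}
    if discarded:
        logger.info("discarded %d reads shorter than %d after trimming", discarded, min_len)
    return kept, stats


# ---------------------------------------------------------------------------
# alignment


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class AlignmentIndex:
    """Windowed view of the reference for vectorized Hamming search.

    The reference here is tiny (tens of short transcripts), so alignment is
    an exact scan over all length-m windows of all features, vectorized with
    numpy; no heuristics, no seeds, no missed hits.
    """

    def __init__(self, targets: list[tuple[str, str, str]]):
        if not targets:
            raise ValueError("empty reference")
        self.targets = targets  # (name, seq, kind)
        self._encoded = [_encode(seq) for _, seq, _ in targets]
        self._window_cache: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_bundle(cls, reference: ReferenceBundle) -> "AlignmentIndex":
        return cls(reference.alignment_targets())

    def _windows(self, m: int):
        if m not in self._window_cache:
            mats, tidx, starts = [], [], []
            for i, enc in enumerate(self._encoded):
                if len(enc) < m:
                    continue
                w = np.lib.stride_tricks.sliding_window_view(enc, m)
                mats.append(w)
                tidx.append(np.full(len(w), i))
                starts.append(np.arange(1, len(w) + 1))
            if mats:
                self._window_cache[m] = (
                    np.ascontiguousarray(np.concatenate(mats)),
                    np.concatenate(tidx),
                    np.concatenate(starts),
                )
            else:
                self._window_cache[m] = (
                    np.empty((0, m), dtype=np.uint8),
                    np.empty(0, dtype=int),
                    np.empty(0, dtype=int),
                )
        return self._window_cache[m]

    def hits_for_seq(
        self, seq: str, max_hits: int = 100, max_mismatches: int = 2
    ) -> list[tuple[int, int, int, tuple]]:
        """All placements of ``seq`` with <= max_mismatches, as
        (target index, start, score, mismatch tuple), capped at ``max_hits``
        after sorting by (score, target order, position)."""
        m = len(seq)
        windows, tidx, starts = self._windows(m)
        if windows.shape[0] == 0:
            return []
        enc = _encode(seq)
        neq = windows != enc
        scores = neq.sum(axis=1)
        rows = np.flatnonzero(scores <= max_mismatches)
        if rows.size == 0:
            return []
        order = np.lexsort((starts[rows], tidx[rows], scores[rows]))
        rows = rows[order][:max_hits]
        out = []
        for r in rows:
            t_i = int(tidx[r])
            target_seq = self.targets[t_i][1]
            start = int(starts[r])
            mm = tuple(
                (int(p) + 1, target_seq[start - 1 + int(p)], seq[int(p)])
                for p in np.flatnonzero(neq[r])
            )
            out.append((t_i, start, int(scores[r]), mm))
        return out


def align_reads(
    reads: list[tuple[str, str]],
    index: AlignmentIndex | ReferenceBundle,
    max_hits: int = 100,
    max_mismatches: int = 2,
) -> tuple[dict[str, list[AlignmentHit]], list[str]]:
    """Align trimmed reads; returns ``(hits_by_read, unaligned_read_ids)``.

    Hit lists are shared between reads with identical sequence (the search is
    memoized per unique sequence).
    """
    if isinstance(index, ReferenceBundle):
        index = AlignmentIndex.from_bundle(index)
    cache: dict[str, list] = {}
    hits_by_read: dict[str, list[AlignmentHit]] = {}
    unaligned: list[str] = []
    for rid, seq in reads:
        if seq not in cache:
            cache[seq] = index.hits_for_seq(seq, max_hits=max_hits, max_mismatches=max_mismatches)
        raw = cache[seq]
        if not raw:
            unaligned.append(rid)
            continue
        best_score = min(score for _, _, score, _ in raw)
        hits = [
            AlignmentHit(
                read_id=rid,
                target=index.targets[t_i][0],
                kind=index.targets[t_i][2],
                start=start,
                end=start + len(seq) - 1,
                mismatches=mm,
                score=score,
                is_best=(score == best_score),
            )
            for t_i, start, score, mm in raw
        ]
        hits_by_read[rid] = hits
    return hits_by_read, unaligned


# ---------------------------------------------------------------------------
# grouping and counting


def _canonical_sort_key(reference: ReferenceBundle):
    lookup = {t.transcript_name: t for t in reference.transcripts}

    def key(name: str):
        t = lookup[name]
        return (t.isotype, t.anticodon, t.transcript_no, t.gene_copy or 0)

    return key


def assign_read(
    hits: list[AlignmentHit], reference: ReferenceBundle
) -> tuple[str, object]:
    """Resolve one read's best hits to a single assignment.

    Returns ``("tDR", (transcript_set, start_label, end_label, variants,
    representative))`` for tRNA-derived reads, or ``("feature", name)`` for
    miRNA/other reads.  tRNA hits outrank small-RNA hits at equal score;
    mature hits outrank precursor hits unless only precursors explain the
    read (leader/trailer fragments).  When best hits disagree on boundaries
    the canonical-first transcript's placement defines the key.
    """
    best = [h for h in hits if h.is_best]
    trna = [h for h in best if h.kind in ("mature", "precursor")]
    if not trna:
        return "feature", sorted(h.target for h in best)[0]
    mature = [h for h in trna if h.kind == "mature"]
    chosen = mature if mature else trna
    sort_key = _canonical_sort_key(reference)
    chosen.sort(key=lambda h: (sort_key(h.target), h.start))
    names = []
    for h in chosen:
        if h.target not in names:
            names.append(h.target)
    rep_hit = chosen[0]
    rep = reference.transcript(rep_hit.target)
    start_label = rep.label(rep_hit.start)
    end_label = rep.label(rep_hit.end)
    variants = tuple(
        VariantCode("substitution", pos, ref, obs)
        for pos, ref, obs in rep_hit.mismatches
        if ref != obs and obs in "ACGT" and ref in "ACGT"
    )
    return "tDR", (tuple(names), start_label, end_label, variants, rep_hit.target)


def group_to_records(
    hits_by_read: dict[str, list[AlignmentHit]],
    sample: str,
    reference: ReferenceBundle,
    records: dict[tuple, TDRRecord] | None = None,
    feature_counts: dict[str, dict[str, int]] | None = None,
) -> tuple[dict[tuple, TDRRecord], dict[str, dict[str, int]]]:
    """Aggregate per-read best-hit assignments into fragment records.

    Each read contributes exactly one count: to a :class:`TDRRecord` keyed by
    (transcript set, boundaries, variant codes) for tRNA-derived reads, or to
    a named miRNA/other feature otherwise.  Pass ``records``/``feature_counts``
    across samples to accumulate a multi-sample table.
    """
    records = {} if records is None else records
    feature_counts = {} if feature_counts is None else feature_counts
    for rid, hits in hits_by_read.items():
        what, payload = assign_read(hits, reference)
        if what == "feature":
            feature_counts.setdefault(payload, {}).setdefault(sample, 0)
            feature_counts[payload][sample] += 1
            continue
        transcript_set, start_label, end_label, variants, rep = payload
        key = (transcript_set, start_label, end_label, variants)
        if key not in records:
            records[key] = TDRRecord(
                transcript_set=transcript_set,
                start_label=start_label,
                end_label=end_label,
                variants=variants,
                representative=rep,
            )
        records[key].counts[sample] = records[key].counts.get(sample, 0) + 1
    return records, feature_counts


def record_name(record: TDRRecord, reference: ReferenceBundle) -> str:
    """Canonical tDR name for a record (see :mod:`tdrscape.naming`)."""
    rep = reference.transcript(record.representative)
    n_isodecoders = len(record.transcript_set)
    return format_name(
        start_label=record.start_label,
        end_label=record.end_label,
        isotype=rep.isotype,
        anticodon=rep.anticodon,
        transcript_no=rep.transcript_no,
        gene_copy=rep.gene_copy if rep.kind == "precursor" else None,
        multimap_k=n_isodecoders,
        variants=record.variants,
    )


def count_features(
    records: dict[tuple, TDRRecord],
    feature_counts: dict[str, dict[str, int]],
    samples: list[str],
    reference: ReferenceBundle,
) -> CountMatrix:
    """Assemble the features x samples count matrix.

    Rows are named tDR records plus annotated miRNA/other features; column
    sums equal the number of aligned reads per sample.
    """
    kind_by_feature = {s.name: s.kind for s in reference.smallrnas}
    rows, kinds, index = [], [], []
    for key in sorted(records, key=lambda k: (k[0], str(k[1]), str(k[2]))):
        rec = records[key]
        name = record_name(rec, reference)
        if name in index:
            raise ValueError(f"fragment name collision: {name}")
        index.append(name)
        kinds.append("tDR")
        rows.append([rec.counts.get(s, 0) for s in samples])
    for fname in sorted(feature_counts):
        if fname not in kind_by_feature:
            raise ValueError(f"feature {fname!r} missing from annotation")
        index.append(fname)
        kinds.append(kind_by_feature[fname])
        rows.append([feature_counts[fname].get(s, 0) for s in samples])
    counts = pd.DataFrame(rows, index=index, columns=samples, dtype=int)
    return CountMatrix(counts=counts, kind=pd.Series(kinds, index=index, name="kind"))


def quantify_samples(
    fastq_by_sample: dict[str, str | Path],
    reference: ReferenceBundle,
    adapter: str,
    min_len: int = 15,
    max_hits: int = 100,
    max_mismatches: int = 2,
) -> tuple[CountMatrix, dict[tuple, TDRRecord], dict]:
    """Trim, align and count a set of per-sample FASTQ files in one call.

    Returns ``(count_matrix, tdr_records, per_sample_stats)``; stats include
    trim and alignment read counts per sample.
    """
    index = AlignmentIndex.from_bundle(reference)
    records: dict[tuple, TDRRecord] = {}
    feature_counts: dict[str, dict[str, int]] = {}
    stats: dict[str, dict] = {}
    samples = list(fastq_by_sample)
    for sample, path in fastq_by_sample.items():
        reads, trim_stats = trim_reads(path, adapter, min_len=min_len)
        hits, unaligned = align_reads(
            reads, index, max_hits=max_hits, max_mismatches=max_mismatches
        )
        records, feature_counts = group_to_records(
            hits, sample, reference, records, feature_counts
        )
        stats[sample] = {**trim_stats, "aligned": len(hits), "unaligned": len(unaligned)}
    cm = count_features(records, feature_counts, samples, reference)
    return cm, records, stats


# ---------------------------------------------------------------------------
# SAM interchange


def write_sam(
    hits_by_read: dict[str, list[AlignmentHit]],
    index: AlignmentIndex,
    path: str | Path,
) -> None:
    """Write hits as a SAM file (first hit primary, others secondary)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq, _ in index.targets],
    }
    name_to_tid = {name: i for i, (name, _, _) in enumerate(index.targets)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rid, hits in hits_by_read.items():
            for i, h in enumerate(hits):
                a = pysam.AlignedSegment(out.header)
                a.query_name = rid
                length = h.end - h.start + 1
                target_seq = index.targets[name_to_tid[h.target]][1]
                seq = list(target_seq[h.start - 1 : h.end])
                for pos, _ref, obs in h.mismatches:
                    seq[pos - 1] = obs
                a.query_sequence = "".join(seq)
                a.flag = 0 if i == 0 else 256
                a.reference_id = name_to_tid[h.target]
                a.reference_start = h.start - 1
                a.mapping_quality = 255
                a.cigarstring = f"{length}M"
                a.set_tag("NM", h.score)
                out.write(a)


def ingest_sam(
    path: str | Path,
    index: AlignmentIndex | ReferenceBundle,
    max_hits: int = 100,
) -> dict[str, list[AlignmentHit]]:
    """Reconstruct alignment hits from an external SAM/BAM run.

    The SAM must be aligned against the same transcript FASTA (reference
    names are checked).  The NM tag supplies the mismatch score; primary and
    secondary alignments are honored; alignments beyond ``max_hits`` per read
    are ignored with a warning.  Downstream grouping/counting is identical to
    the internal path.
    """
    if isinstance(index, ReferenceBundle):
        index = AlignmentIndex.from_bundle(index)
    known = {name: seq for name, seq, _ in index.targets}
    kinds = {name: kind for name, _, kind in index.targets}
    raw: dict[str, list[AlignmentHit]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_supplementary:
                continue
            if aln.reference_name not in known:
                raise ValueError(f"unknown reference name {aln.reference_name!r} in {path}")
            start = aln.reference_start + 1
            seq = aln.query_sequence or ""
            end = start + len(seq) - 1
            target_seq = known[aln.reference_name]
            mm = tuple(
                (i + 1, target_seq[start - 1 + i], seq[i])
                for i in range(len(seq))
                if target_seq[start - 1 + i] != seq[i]
            )
            score = aln.get_tag("NM") if aln.has_tag("NM") else len(mm)
            raw.setdefault(aln.query_name, []).append(
                AlignmentHit(
                    read_id=aln.query_name,
                    target=aln.reference_name,
                    kind=kinds[aln.reference_name],
                    start=start,
                    end=end,
                    mismatches=mm,
                    score=int(score),
                    is_best=False,
                )
            )
    out: dict[str, list[AlignmentHit]] = {}
    for rid, hits in raw.items():
        if len(hits) > max_hits:
            logger.warning(
                "read %s has %d alignments; keeping the best %d", rid, len(hits), max_hits
            )
            hits = sorted(hits, key=lambda h: h.score)[:max_hits]
        best = min(h.score for h in hits)
        out[rid] = [
            AlignmentHit(
                read_id=h.read_id,
                target=h.target,
                kind=h.kind,
                start=h.start,
                end=h.end,
                mismatches=h.mismatches,
                score=h.score,
                is_best=(h.score == best),
            )
            for h in hits
        ]
    return out
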