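"""Fragment classification and positional summaries on the consensus tRNA axis.

Fragments are classified by where their boundaries fall on the consensus
1..76 coordinate system: 5' halves start at the transcript 5' end and stop in
the anticodon region (canonically position 33), 3' halves start there and run
to the CCA tail, with the CCA status read off the 3' end (76 = intact CCA,
75 = CC, 74 = the single remaining cytosine of a trimmed tail).  Precursor
fragments overlapping leader or trailer bases are categorized separately.

The three positional summaries mirror standard tDR profiling outputs:
abundance-weighted read-length distributions per RNA kind, per-consensus-
position coverage, and the 3'-end frequency distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import CountMatrix, TDRRecord
from .reference import ReferenceBundle, consensus_map

__all__ = [
    "FRAGMENT_CLASSES",
    "CCA_STATUSES",
    "ClassifyConfig",
    "classify_fragment",
    "classify_record",
    "length_distribution",
    "consensus_coverage",
    "end_frequency",
    "ProfileSet",
    "profile_records",
]

FRAGMENT_CLASSES = (
    "five_prime_half",
    "five_prime_fragment",
    "three_prime_half",
    "three_prime_fragment",
    "internal",
    "pre_leader",
    "pre_trailer",
)
CCA_STATUSES = ("intact", "two_C", "single_C", "absent")


@dataclass(frozen=True)
class ClassifyConfig:
    """Boundary windows for half/fragment calls (consensus coordinates).

    The empirical end peaks sit at 33, 74 and 76; the windows around them are
    an operational choice and are exposed here rather than hard-coded.
    """

    five_prime_max_start: int = 3
    half_5p_end: tuple[int, int] = (30, 40)
    half_3p_start: tuple[int, int] = (30, 44)
    three_prime_min_end: int = 74


def classify_fragment(
    start_label: str | int,
    end_label: str | int,
    config: ClassifyConfig = ClassifyConfig(),
) -> tuple[str, str]:
    """Classify a fragment from its boundary labels; total and deterministic.

    ``start_label``/``end_label`` are consensus positions for mature-derived
    fragments or ``L<i>``/``T<i>`` strings for precursor flanks.  Returns
    ``(fragment_class, cca_status)``.
    """
    s, e = str(start_label), str(end_label)
    if s.startswith("L"):
        return "pre_leader", "absent"
    if s.startswith("T") or e.startswith("T"):
        return "pre_trailer", "absent"
    if e.startswith("L"):
        return "pre_leader", "absent"
    start, end = int(s), int(e)

    if end >= 76:
        cca = "intact"
    elif end == 75:
        cca = "two_C"
    elif end == 74:
        cca = "single_C"
    else:
        cca = "absent"

    if start <= config.five_prime_max_start:
        lo, hi = config.half_5p_end
        if lo <= end <= hi:
            return "five_prime_half", cca
        if end < lo:
            return "five_prime_fragment", cca
        return "internal", cca
    if end >= config.three_prime_min_end:
        lo, hi = config.half_3p_start
        if lo <= start <= hi:
            return "three_prime_half", cca
        if start > hi:
            return "three_prime_fragment", cca
    return "internal", cca


def _consensus_bounds(record: TDRRecord, reference: ReferenceBundle) -> tuple[str, str]:
    """Record boundaries translated onto the consensus axis (mature only)."""
    rep = reference.transcript(record.representative)
    if rep.kind != "mature":
        return record.start_label, record.end_label
    cmap = consensus_map(rep)
    return (
        str(int(cmap[int(record.start_label) - 1])),
        str(int(cmap[int(record.end_label) - 1])),
    )


def classify_record(
    record: TDRRecord,
    reference: ReferenceBundle,
    config: ClassifyConfig = ClassifyConfig(),
) -> tuple[str, str]:
    """Classify a counted fragment record (boundaries mapped to consensus)."""
    start_c, end_c = _consensus_bounds(record, reference)
    return classify_fragment(start_c, end_c, config)


def length_distribution(lengths, weights=None) -> dict[int, float]:
    """Abundance-weighted proportion of reads at each length.

    Empty input returns an empty map rather than dividing by zero.
    """
    lengths = np.asarray(list(lengths), dtype=int)
    if lengths.size == 0:
        return {}
    w = np.ones_like(lengths, dtype=float) if weights is None else np.asarray(
        list(weights), dtype=float
    )
    total = w.sum()
    if total <= 0:
        return {}
    out: dict[int, float] = {}
    for length in np.unique(lengths):
        out[int(length)] = float(w[lengths == length].sum() / total)
    return out


def _mature_records(records, reference: ReferenceBundle):
    for rec in records:
        if reference.transcript(rec.representative).kind == "mature":
            yield rec


def consensus_coverage(
    records: list[TDRRecord], reference: ReferenceBundle, sample: str | None = None
) -> dict[int, float]:
    """Proportion of total tDR abundance covering each consensus position.

    Precursor-derived records are excluded (consensus positions are defined
    on mature tRNA only).  The sum over positions equals the abundance-
    weighted mean fragment span in consensus positions.
    """
    cov = np.zeros(77)
    total = 0.0
    for rec in _mature_records(records, reference):
        n = rec.total() if sample is None else rec.counts.get(sample, 0)
        if n == 0:
            continue
        rep = reference.transcript(rec.representative)
        cmap = consensus_map(rep)
        labels = np.unique(cmap[int(rec.start_label) - 1 : int(rec.end_label)])
        cov[labels] += n
        total += n
    if total == 0:
        return {}
    return {int(p): float(cov[p] / total) for p in range(1, 77) if cov[p] > 0}


def end_frequency(
    records: list[TDRRecord], reference: ReferenceBundle, sample: str | None = None
) -> dict[int, float]:
    """Distribution of fragment 3' ends over consensus positions (sums to 1)."""
    freq: dict[int, float] = {}
    total = 0.0
    for rec in _mature_records(records, reference):
        n = rec.total() if sample is None else rec.counts.get(sample, 0)
        if n == 0:
            continue
        _, end_c = _consensus_bounds(rec, reference)
        freq[int(end_c)] = freq.get(int(end_c), 0.0) + n
        total += n
    if total == 0:
        return {}
    return {p: v / total for p, v in sorted(freq.items())}


@dataclass
class ProfileSet:
    """The three positional summaries plus per-class abundance fractions."""

    length_dist: dict = field(default_factory=dict)  # kind -> {length: prop}
    coverage: dict = field(default_factory=dict)  # consensus pos -> prop
    end_freq: dict = field(default_factory=dict)  # consensus pos -> prop
    class_fractions: dict = field(default_factory=dict)  # fragment class -> prop
    cca_fractions: dict = field(default_factory=dict)  # cca status -> prop

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for kind, dist in self.length_dist.items():
            rows += [("length", kind, k, v) for k, v in sorted(dist.items())]
        rows += [("coverage", "tDR", k, v) for k, v in sorted(self.coverage.items())]
        rows += [("end_freq", "tDR", k, v) for k, v in sorted(self.end_freq.items())]
        rows += [("class_fraction", "tDR", k, v) for k, v in self.class_fractions.items()]
        rows += [("cca_fraction", "tDR", k, v) for k, v in self.cca_fractions.items()]
        return pd.DataFrame(rows, columns=["summary", "kind", "key", "proportion"])


def profile_records(
    records: list[TDRRecord],
    reference: ReferenceBundle,
    counts: CountMatrix | None = None,
    sample: str | None = None,
    config: ClassifyConfig = ClassifyConfig(),
) -> ProfileSet:
    """Full positional profile of a set of counted fragments.

    Length distributions are computed per RNA kind (tDR from the records;
    miRNA/other from the count matrix when given).  Class and CCA fractions
    are abundance-weighted over tDR records.
    """
    weight = (lambda r: r.total()) if sample is None else (
        lambda r: r.counts.get(sample, 0)
    )
    lengths, weights = [], []
    class_w: dict[str, float] = {}
    cca_w: dict[str, float] = {}
    for rec in records:
        n = weight(rec)
        if n == 0:
            continue
        rep = reference.transcript(rec.representative)
        start = rep.position_of_label(rec.start_label)
        end = rep.position_of_label(rec.end_label)
        lengths.append(end - start + 1)
        weights.append(n)
        cls, cca = classify_record(rec, reference, config)
        class_w[cls] = class_w.get(cls, 0.0) + n
        cca_w[cca] = cca_w.get(cca, 0.0) + n
    total = sum(weights)
    length_dist = {"tDR": length_distribution(lengths, weights)}
    if counts is not None:
        for kind in ("miRNA", "other"):
            sub = counts.of_kind(kind)
            if sub.empty:
                continue
            col = sub.sum(axis=1) if sample is None else sub[sample]
            seq_by_name = {s.name: s.seq for s in reference.smallrnas}
            feat_lengths = [len(seq_by_name[n]) for n in sub.index]
            length_dist[kind] = length_distribution(feat_lengths, col.to_numpy())
    return ProfileSet(
        length_dist=length_dist,
        coverage=consensus_coverage(records, reference, sample),
        end_freq=end_frequency(records, reference, sample),
        class_fractions={k: v / total for k, v in class_w.items()} if total else {},
        cca_fractions={k: v / total for k, v in cca_w.items()} if total else {},
    )
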