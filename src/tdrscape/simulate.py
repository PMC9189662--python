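"""Synthetic ARM-seq libraries with known ground truth.

This module emulates the statistical structure the downstream analysis
assumes, so that every step of the pipeline can be tested against a known
truth:

* compartment-specific fragment-class mixtures — extracellular profiles are
  dominated by 31-33 nt 5' halves ending at consensus position 33 and 3'
  halves with a trimmed CCA ending at 74; cellular profiles by 3' fragments
  with an intact CCA ending at 76 and broad lengths;
* modification-dependent reverse-transcription truncation at m1A58 — without
  AlkB demethylation the RT stalls at the modification with high probability
  and the emitted read keeps only the bases 3' of it; with AlkB treatment it
  reads through, occasionally recording a misincorporation;
* a miRNA background, per-base sequencing error, 3' adapter contamination;
* condition-specific abundance shifts applied on the log2 scale to
  fragment-level expected counts.  Per-sample read totals are negative-
  binomially jittered around their targets and reads are then allocated to
  fragment cells multinomially, so within-sample class fractions converge
  to the configured mixture at binomial rate.  The NB feature-level count
  model the differential module assumes is provided directly by the
  count-level simulators (:func:`simulate_nb_counts`,
  :func:`simulate_ko_design`, :func:`simulate_condition_matrix`).

Reads are emitted already adapter-merged single-end, capped at the read
length.  Everything is reproducible from ``(config, seed)``; per-sample
randomness uses substreams derived from ``(seed, sample index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .reference import (
    ReferenceBundle,
    SmallRNA,
    TRNAGene,
    TRNATranscript,
    build_precursor,
    collapse_isodecoders,
    consensus_map,
    position_for_consensus,
)

__all__ = [
    "FragmentClassSpec",
    "ModificationModel",
    "ConditionProfile",
    "SampleSpec",
    "LibraryConfig",
    "GroundTruthRead",
    "toy_reference",
    "extracellular_mixture",
    "cellular_mixture",
    "sample_fragment",
    "apply_rt_stop",
    "simulate_library",
    "simulate_nb_counts",
    "simulate_ko_design",
    "simulate_condition_matrix",
    "DEFAULT_ADAPTER",
]

DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTC"

TDR_CLASS_IDS = (
    "five_prime_half",
    "five_prime_fragment",
    "three_prime_half_trimmed",
    "three_prime_fragment_intact",
    "internal",
    "pre_leader",
    "pre_trailer",
)
CLASS_IDS = TDR_CLASS_IDS + ("mirna", "other")


@dataclass(frozen=True)
class FragmentClassSpec:
    """One mixture component: a fragment class with boundary distributions.

    ``start_dist`` / ``end_dist`` map position labels (consensus integers for
    mature-derived classes, ``"T<i>"``/``"L<i>"`` strings for precursor
    classes) to probabilities.  A point mass is ``{33: 1.0}``.
    """

    class_id: str
    start_dist: dict = field(default_factory=dict)
    end_dist: dict = field(default_factory=dict)
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.class_id not in CLASS_IDS:
            raise ValueError(f"unknown fragment class {self.class_id!r}")
        if self.weight < 0:
            raise ValueError("mixture weight must be nonnegative")
        for dist in (self.start_dist, self.end_dist):
            if dist and not np.isclose(sum(dist.values()), 1.0):
                raise ValueError("boundary distribution must sum to 1")


@dataclass(frozen=True)
class ModificationModel:
    """RT behaviour at modified positions (default: m1A58 only).

    ``read_through_no_alkb`` is the probability the RT extends through a
    modified base without AlkB demethylation; ``read_through_alkb`` with it.
    A read-through event records a random non-reference base at the modified
    position with probability ``misincorporation_rate``.
    """

    modified_positions: tuple[int, ...] = (58,)
    read_through_no_alkb: float = 0.1
    read_through_alkb: float = 0.99
    misincorporation_rate: float = 0.3

    def __post_init__(self) -> None:
        for p in (self.read_through_no_alkb, self.read_through_alkb, self.misincorporation_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.read_through_alkb < self.read_through_no_alkb:
            raise ValueError("AlkB read-through must be >= untreated read-through")

    def read_through(self, alkb: bool) -> float:
        return self.read_through_alkb if alkb else self.read_through_no_alkb


@dataclass
class ConditionProfile:
    """Expected composition of one library: what a condition/compartment emits.

    ``baseline`` maps transcript (or small-RNA feature) names to relative
    abundances; ``effects`` maps ``(transcript_name, class_id)`` to log2
    effect sizes applied on top of the baseline mixture.
    """

    condition: str = "control"
    compartment: str = "Ex"  # "cell" | "Ex"
    genotype: str = "WT"
    baseline: dict = field(default_factory=dict)
    effects: dict = field(default_factory=dict)
    nb_dispersion: float = 0.05
    mixture: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if any(v <= 0 for v in self.baseline.values()):
            raise ValueError("baseline abundances must be positive")
        total = sum(c.weight for c in self.mixture)
        if self.mixture and total <= 0:
            raise ValueError("mixture has zero total weight")

    @property
    def class_weights(self) -> dict:
        total = sum(c.weight for c in self.mixture)
        return {c.class_id: c.weight / total for c in self.mixture}


@dataclass(frozen=True)
class SampleSpec:
    sample: str
    profile: ConditionProfile
    n_reads: int
    alkb: bool = True


@dataclass(frozen=True)
class LibraryConfig:
    read_length: int = 75
    adapter: str = DEFAULT_ADAPTER
    seq_error_rate: float = 0.001
    adapter_contam_prob: float = 0.15
    mod_model: ModificationModel = ModificationModel()


@dataclass(frozen=True)
class GroundTruthRead:
    read_id: str
    sample: str
    source: str
    start_label: str
    end_label: str
    class_id: str
    truncated: bool
    truncation_position: int | None


# ---------------------------------------------------------------------------
# toy reference


def _random_body(rng: np.random.Generator, anticodon: str, length: int = 73) -> str:
    """Random tRNA-like body with the anticodon planted at positions 34-36."""
    bases = np.array(list("ACGT"))
    seq = list(rng.choice(bases, size=length))
    seq[33:36] = list(anticodon)
    return "".join(seq)


def toy_reference(seed: int = 0) -> ReferenceBundle:
    """A small synthetic reference for simulations and fixtures.

    Contains isodecoders spanning the frequently observed isotypes (Glu, Gly,
    Asp, Pro, Arg, Ser, ...), two gene copies sharing a mature sequence (so
    isodecoder collapsing is exercised), two isodecoders sharing their 5'
    half (so multi-mapping ``-M2`` grouping is exercised), one intron-carrying
    gene, one length-75 mature transcript, precursor flanks, 20 synthetic
    miRNAs and 3 other small ncRNAs.  Entirely synthetic sequences.
    """
    rng = np.random.default_rng(seed)
    specs = [
        # (isotype, anticodon, transcript_no, gene_copy)
        ("Glu", "CTC", 1, 1),
        ("Glu", "CTC", 2, 1),
        ("Glu", "TTC", 1, 1),
        ("Gly", "CCC", 1, 1),
        ("Gly", "GCC", 1, 1),
        ("Asp", "GTC", 1, 1),
        ("Asp", "GTC", 2, 1),
        ("Asp", "GTC", 2, 2),
        ("Pro", "AGG", 1, 1),
        ("Arg", "CCT", 2, 1),
        ("Ser", "TGA", 1, 1),
        ("Ser", "GCT", 1, 1),
        ("Met", "CAT", 1, 1),
    ]
    bodies: dict[tuple, str] = {}
    for isotype, anticodon, tno, copy in specs:
        if (isotype, anticodon, tno) in {k[:3] for k in bodies}:
            # additional gene copy: identical body
            src = next(k for k in bodies if k[:3] == (isotype, anticodon, tno))
            bodies[(isotype, anticodon, tno, copy)] = bodies[src]
            continue
        length = 72 if (isotype, anticodon) == ("Ser", "GCT") else 73  # one short variant
        bodies[(isotype, anticodon, tno, copy)] = _random_body(rng, anticodon, length)
    # make Glu-CTC-1 and Glu-CTC-2 share their 5' half (multi-mapped 5' tDRs)
    donor = bodies[("Glu", "CTC", 1, 1)]
    bodies[("Glu", "CTC", 2, 1)] = donor[:40] + bodies[("Glu", "CTC", 2, 1)][40:]

    genes = []
    for (isotype, anticodon, tno, copy), body in bodies.items():
        introns: tuple[tuple[int, int], ...] = ()
        if (isotype, anticodon) == ("Met", "CAT"):
            intron = "".join(rng.choice(np.array(list("ACGT")), size=10))
            body = body[:45] + intron + body[45:]
            introns = ((46, 55),)
        genes.append(
            TRNAGene(
                gene_name=f"{isotype}-{anticodon}-{tno}-{copy}",
                isotype=isotype,
                anticodon=anticodon,
                transcript_no=tno,
                gene_copy=copy,
                body_seq=body,
                intron_intervals=introns,
                leader_seq="".join(rng.choice(np.array(list("ACGT")), size=20)),
                trailer_seq="".join(rng.choice(np.array(list("ACGT")), size=31)),
            )
        )
    mature = collapse_isodecoders(genes)
    precursors = [
        build_precursor(g, leader_len=15, trailer_len=31)
        for g in genes
        if g.gene_name in ("Arg-CCT-2-1", "Ser-TGA-1-1")
    ]
    smallrnas = [
        SmallRNA(f"mir-{i + 1}", "".join(rng.choice(np.array(list("ACGT")), size=22)), "miRNA")
        for i in range(20)
    ] + [
        SmallRNA(f"sno-{i + 1}", "".join(rng.choice(np.array(list("ACGT")), size=45)), "other")
        for i in range(3)
    ]
    return ReferenceBundle(genes=genes, mature=mature, precursors=precursors, smallrnas=smallrnas)


# ---------------------------------------------------------------------------
# mixtures


def extracellular_mixture(
    five_prime_weight: float = 0.70,
    three_prime_weight: float = 0.20,
    mirna_weight: float = 0.10,
) -> list[FragmentClassSpec]:
    """Extracellular mixture: 5' halves ending at 33, trimmed 3' halves ending
    at 74, and a miRNA background."""
    return [
        FragmentClassSpec(
            "five_prime_half", {1: 1.0}, {33: 1.0}, weight=five_prime_weight
        ),
        FragmentClassSpec(
            "three_prime_half_trimmed", {39: 0.5, 41: 0.5}, {74: 1.0}, weight=three_prime_weight
        ),
        FragmentClassSpec("mirna", {}, {}, weight=mirna_weight),
    ]


def cellular_mixture(mirna_weight: float = 0.15) -> list[FragmentClassSpec]:
    """Cellular mixture: 3' fragments with intact CCA (end 76) over broad
    start positions, some internal fragments, and a miRNA background."""
    starts_3p = {s: 1 / 6 for s in (45, 48, 52, 55, 58, 62)}
    return [
        FragmentClassSpec("three_prime_fragment_intact", starts_3p, {76: 1.0}, weight=0.55),
        FragmentClassSpec("three_prime_half_trimmed", {39: 1.0}, {76: 1.0}, weight=0.10),
        FragmentClassSpec("internal", {37: 0.5, 40: 0.5}, {60: 0.5, 65: 0.5}, weight=0.10),
        FragmentClassSpec("five_prime_fragment", {1: 1.0}, {18: 0.5, 22: 0.5}, weight=0.10),
        FragmentClassSpec("mirna", {}, {}, weight=mirna_weight),
    ]


# ---------------------------------------------------------------------------
# sampling


def _draw(dist: dict, rng: np.random.Generator):
    keys = list(dist.keys())
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _class_sources(class_id: str, profile: ConditionProfile, reference: ReferenceBundle):
    if class_id in ("pre_leader", "pre_trailer"):
        pool = reference.precursors
        return [(t.transcript_name, t) for t in pool]
    if class_id == "mirna":
        return [(s.name, s) for s in reference.smallrnas if s.kind == "miRNA"]
    if class_id == "other":
        return [(s.name, s) for s in reference.smallrnas if s.kind == "other"]
    return [(t.transcript_name, t) for t in reference.mature]


def _realize_boundaries(
    transcript: TRNATranscript, spec: FragmentClassSpec, rng: np.random.Generator
) -> tuple[int, int] | None:
    """Transcript start/end positions for one draw from a class spec."""
    if spec.class_id in ("pre_leader", "pre_trailer"):
        start_lab = str(_draw(spec.start_dist, rng))
        end_lab = str(_draw(spec.end_dist, rng))
        try:
            start = transcript.position_of_label(start_lab)
            end = transcript.position_of_label(end_lab)
        except KeyError:
            return None
    else:
        start_c = int(_draw(spec.start_dist, rng))
        end_c = int(_draw(spec.end_dist, rng))
        start = position_for_consensus(transcript, start_c, side="5p")
        end = position_for_consensus(transcript, end_c, side="3p")
    if start >= end:
        return None
    return start, end


def sample_fragment(
    profile: ConditionProfile,
    reference: ReferenceBundle,
    rng: np.random.Generator,
    max_tries: int = 100,
):
    """Draw one fragment: (source name, start pos, end pos, class_id, sequence).

    The class is drawn from the mixture, the source transcript from the
    profile baseline restricted to sources that support the class, and the
    boundaries from the class spec realized through the inverse consensus
    map.  Unsupported draws (boundaries that do not fit the transcript) are
    resampled up to ``max_tries`` times.
    """
    weights = np.array([c.weight for c in profile.mixture], dtype=float)
    weights = weights / weights.sum()
    for _ in range(max_tries):
        spec = profile.mixture[rng.choice(len(profile.mixture), p=weights)]
        sources = _class_sources(spec.class_id, profile, reference)
        if not sources:
            continue
        base = np.array([profile.baseline.get(name, 1.0) for name, _ in sources], dtype=float)
        name, src = sources[rng.choice(len(sources), p=base / base.sum())]
        if isinstance(src, SmallRNA):
            return name, 1, len(src.seq), spec.class_id, src.seq
        bounds = _realize_boundaries(src, spec, rng)
        if bounds is None:
            continue
        start, end = bounds
        return name, start, end, spec.class_id, src.seq[start - 1 : end]
    raise RuntimeError(
        f"could not realize a fragment for profile {profile.condition!r} "
        f"after {max_tries} tries"
    )


def apply_rt_stop(
    seq: str,
    consensus_labels,
    model: ModificationModel,
    alkb: bool,
    rng: np.random.Generator,
) -> tuple[str, list, bool, int | None]:
    """Apply modification-dependent RT truncation/misincorporation to a read.

    ``consensus_labels[i]`` is the consensus position of base ``i`` (None for
    bases without one, e.g. miRNA reads).  Scanning 3'->5' — the direction
    reverse transcription proceeds — each covered modified position either
    stops the RT (the emitted read keeps only the bases strictly 3' of the
    modification) or is read through, in which case a random non-reference
    base replaces the true base with probability ``misincorporation_rate``.

    Returns ``(sequence, labels, truncated, truncation_position)``.
    """
    labels = list(consensus_labels)
    p_rt = model.read_through(alkb)
    covered = sorted(
        (i for i, lab in enumerate(labels) if lab in model.modified_positions),
        reverse=True,
    )
    seq_list = list(seq)
    for i in covered:
        if rng.random() >= p_rt:  # RT stalls
            return (
                "".join(seq_list[i + 1 :]),
                labels[i + 1 :],
                True,
                int(labels[i]),
            )
        if rng.random() < model.misincorporation_rate:
            others = [b for b in "ACGT" if b != seq_list[i]]
            seq_list[i] = others[rng.integers(len(others))]
    return "".join(seq_list), labels, False, None


def _seq_error(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0 or not seq:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    seq_list = list(seq)
    for i in rng.choice(len(seq_list), size=n_err, replace=False):
        others = [b for b in "ACGT" if b != seq_list[i]]
        seq_list[i] = others[rng.integers(len(others))]
    return "".join(seq_list)


def _consensus_labels_for(transcript: TRNATranscript, start: int, end: int):
    if transcript.kind != "mature":
        return [None] * (end - start + 1)
    cmap = consensus_map(transcript)
    return [int(cmap[p - 1]) for p in range(start, end + 1)]


def simulate_library(
    out_dir: str | Path,
    samples: list[SampleSpec],
    reference: ReferenceBundle,
    seed: int,
    config: LibraryConfig = LibraryConfig(),
) -> dict:
    """Simulate FASTQ libraries plus ground truth and a true count matrix.

    Per sample, the expected count of each (source, class) cell is the
    profile mixture probability times the read target, modulated by the
    profile's log2 ``effects``; the per-sample total is NB-jittered with the
    profile dispersion and allocated to cells multinomially.  Each read is
    realized from the class spec, passed
    through the RT-stop model and per-base sequencing error, contaminated
    with a 3' adapter prefix with probability ``adapter_contam_prob``, and
    written Phred+33 with constant quality.

    Returns paths: ``{"fastq": {sample: path}, "truth": path, "counts": path,
    "config": path}``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fastq_paths: dict[str, Path] = {}
    truth_rows = []
    counts: dict[tuple, dict[str, int]] = {}

    for s_idx, spec in enumerate(samples):
        rng = np.random.default_rng([int(seed), s_idx])
        profile = spec.profile
        if profile.mixture and sum(c.weight for c in profile.mixture) <= 0:
            raise ValueError(f"zero-weight mixture for sample {spec.sample}")
        fq_path = out_dir / f"{spec.sample}.fastq"
        if fq_path.exists():
            raise FileExistsError(f"output path collision: {fq_path}")
        fastq_paths[spec.sample] = fq_path

        # expected counts per (source, class) cell, NB-jittered
        weights = profile.class_weights
        cells = []
        for cls_spec in profile.mixture:
            sources = _class_sources(cls_spec.class_id, profile, reference)
            if not sources:
                continue
            base = np.array(
                [profile.baseline.get(name, 1.0) for name, _ in sources], dtype=float
            )
            base = base / base.sum()
            for (name, src), b in zip(sources, base):
                mu = spec.n_reads * weights[cls_spec.class_id] * b
                mu *= 2.0 ** profile.effects.get((name, cls_spec.class_id), 0.0)
                cells.append((name, src, cls_spec, mu))
        # NB jitter applies to the per-sample total (library-size variability
        # across replicates); within the sample, reads are allocated to
        # fragment cells multinomially, so ground-truth class fractions
        # converge to the effect-modulated mixture at binomial rate
        mus = np.array([c[3] for c in cells], dtype=float)
        if mus.size and spec.n_reads > 0 and mus.sum() > 0:
            disp = profile.nb_dispersion
            total = int(
                rng.negative_binomial(1.0 / disp, 1.0 / (1.0 + disp * spec.n_reads))
            )
            n_cell = rng.multinomial(total, mus / mus.sum())
        else:
            n_cell = np.zeros(len(cells), dtype=int)

        with open(fq_path, "w") as fq:
            read_no = 0
            for (name, src, cls_spec, _mu), n in zip(cells, n_cell):
                for _ in range(int(n)):
                    read_no += 1
                    read_id = f"{spec.sample}:{read_no}"
                    if isinstance(src, SmallRNA):
                        start, end = 1, len(src.seq)
                        frag = src.seq
                        labels = [None] * len(frag)
                        start_lab, end_lab = "1", str(len(src.seq))
                    else:
                        bounds = None
                        for _try in range(100):
                            bounds = _realize_boundaries(src, cls_spec, rng)
                            if bounds is not None:
                                break
                        if bounds is None:
                            raise RuntimeError(
                                f"class {cls_spec.class_id} unsupported on {name}"
                            )
                        start, end = bounds
                        frag = src.seq[start - 1 : end]
                        labels = _consensus_labels_for(src, start, end)
                        start_lab, end_lab = src.label(start), src.label(end)
                    seq, labels, truncated, trunc_pos = apply_rt_stop(
                        frag, labels, config.mod_model, spec.alkb, rng
                    )
                    if truncated and labels:
                        start_lab = (
                            src.label(start + (end - start + 1) - len(labels))
                            if not isinstance(src, SmallRNA)
                            else start_lab
                        )
                    if len(seq) == 0:
                        continue
                    seq = _seq_error(seq, config.seq_error_rate, rng)
                    if rng.random() < config.adapter_contam_prob:
                        k = int(rng.integers(6, len(config.adapter) + 1))
                        seq = seq + config.adapter[:k]
                    seq = seq[: config.read_length]
                    fq.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
                    truth_rows.append(
                        GroundTruthRead(
                            read_id=read_id,
                            sample=spec.sample,
                            source=name,
                            start_label=str(start_lab),
                            end_label=str(end_lab),
                            class_id=cls_spec.class_id,
                            truncated=truncated,
                            truncation_position=trunc_pos,
                        )
                    )
                    key = (name, str(start_lab), str(end_lab), cls_spec.class_id)
                    counts.setdefault(key, {})[spec.sample] = (
                        counts.get(key, {}).get(spec.sample, 0) + 1
                    )

    truth_df = pd.DataFrame([asdict(r) for r in truth_rows])
    truth_path = out_dir / "ground_truth.tsv"
    truth_df.to_csv(truth_path, sep="\t", index=False)

    sample_names = [s.sample for s in samples]
    count_rows = []
    for (name, start_lab, end_lab, cls), per_sample in sorted(counts.items()):
        row = {"source": name, "start": start_lab, "end": end_lab, "class_id": cls}
        for sn in sample_names:
            row[sn] = per_sample.get(sn, 0)
        count_rows.append(row)
    counts_df = pd.DataFrame(count_rows)
    counts_path = out_dir / "true_counts.tsv"
    counts_df.to_csv(counts_path, sep="\t", index=False)

    config_path = out_dir / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(
            {
                "seed": int(seed),
                "read_length": config.read_length,
                "adapter": config.adapter,
                "seq_error_rate": config.seq_error_rate,
                "adapter_contam_prob": config.adapter_contam_prob,
                "mod_model": {
                    "modified_positions": list(config.mod_model.modified_positions),
                    "read_through_no_alkb": config.mod_model.read_through_no_alkb,
                    "read_through_alkb": config.mod_model.read_through_alkb,
                    "misincorporation_rate": config.mod_model.misincorporation_rate,
                },
                "samples": [
                    {
                        "sample": s.sample,
                        "condition": s.profile.condition,
                        "compartment": s.profile.compartment,
                        "genotype": s.profile.genotype,
                        "n_reads": s.n_reads,
                        "alkb": s.alkb,
                    }
                    for s in samples
                ],
            },
            fh,
        )
    return {
        "fastq": fastq_paths,
        "truth": truth_path,
        "counts": counts_path,
        "config": config_path,
        "truth_df": truth_df,
        "counts_df": counts_df,
    }


# ---------------------------------------------------------------------------
# count-level simulators (feature-level benchmarks for the statistics modules)


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draw parameterized by mean and dispersion: Var = mu + dispersion*mu^2."""
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-8)
    return rng.negative_binomial(1.0 / dispersion, 1.0 / (1.0 + dispersion * mu))


def simulate_nb_counts(
    n_features: int = 1000,
    n_per_group: int = 3,
    frac_de: float = 0.1,
    lfc: float = 2.0,
    dispersion: float = 0.1,
    mean_log: float = 5.0,
    mean_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Two-group NB count matrix with a known differentially abundant subset.

    Returns ``(counts, group_labels, true_lfc)`` where ``true_lfc`` is the
    signed log2 effect (0 for null features).
    """
    rng = np.random.default_rng(seed)
    base = np.exp(rng.normal(mean_log, mean_sd, size=n_features))
    n_de = int(round(frac_de * n_features))
    true_lfc = np.zeros(n_features)
    de_idx = rng.choice(n_features, size=n_de, replace=False)
    true_lfc[de_idx] = lfc * rng.choice([-1.0, 1.0], size=n_de)
    mu_a = np.repeat(base[:, None], n_per_group, axis=1)
    mu_b = np.repeat((base * 2.0**true_lfc)[:, None], n_per_group, axis=1)
    counts = np.concatenate(
        [_nb_sample(rng, mu_a, dispersion), _nb_sample(rng, mu_b, dispersion)], axis=1
    )
    features = [f"f{i}" for i in range(n_features)]
    cols = [f"A{j + 1}" for j in range(n_per_group)] + [f"B{j + 1}" for j in range(n_per_group)]
    df = pd.DataFrame(counts, index=features, columns=cols)
    groups = pd.Series(["A"] * n_per_group + ["B"] * n_per_group, index=cols)
    return df, groups, pd.Series(true_lfc, index=features)


def simulate_ko_design(
    n_induced: int = 50,
    n_depleted: int = 50,
    n_independent: int = 50,
    n_null: int = 350,
    n_per_group: int = 3,
    lfc: float = 2.0,
    dispersion: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """WT/KO x control/stress count matrix with truth-classed features.

    'induced' features respond to stress only in WT (the KO abolishes the
    response), 'depleted' likewise downward, 'independent' respond in both
    genotypes.  Returns ``(counts, sample_table_as_labels, truth_class)``
    with columns named ``<genotype>_<condition>_<rep>``.
    """
    rng = np.random.default_rng(seed)
    n_features = n_induced + n_depleted + n_independent + n_null
    truth = np.array(
        ["induced"] * n_induced
        + ["depleted"] * n_depleted
        + ["independent"] * n_independent
        + ["unchanged"] * n_null
    )
    base = np.exp(rng.normal(5.0, 1.0, size=n_features))
    lfc_wt = np.zeros(n_features)
    lfc_ko = np.zeros(n_features)
    lfc_wt[truth == "induced"] = lfc
    lfc_wt[truth == "depleted"] = -lfc
    sign_ind = rng.choice([-1.0, 1.0], size=(truth == "independent").sum())
    lfc_wt[truth == "independent"] = lfc * sign_ind
    lfc_ko[truth == "independent"] = lfc * sign_ind

    cols, blocks = [], []
    for genotype, eff in (("WT", lfc_wt), ("KO", lfc_ko)):
        for condition, active in (("control", False), ("stress", True)):
            mu = base * (2.0**eff if active else 1.0)
            mu_mat = np.repeat(mu[:, None], n_per_group, axis=1)
            blocks.append(_nb_sample(rng, mu_mat, dispersion))
            cols += [f"{genotype}_{condition}_{r + 1}" for r in range(n_per_group)]
    counts = pd.DataFrame(
        np.concatenate(blocks, axis=1),
        index=[f"f{i}" for i in range(n_features)],
        columns=cols,
    )
    labels = pd.Series({c: "_".join(c.split("_")[:2]) for c in cols})
    return counts, labels, pd.Series(truth, index=counts.index)


def simulate_condition_matrix(
    n_tdr: int = 300,
    n_mirna: int = 100,
    conditions: tuple[str, ...] = ("control", "GSD", "hypoxia", "H2O2"),
    n_per_group: int = 3,
    tdr_lfc: float = 3.0,
    mirna_lfc: float = 0.5,
    frac_responsive: float = 0.3,
    dispersion: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Multi-condition count matrix where tDR effects exceed miRNA effects.

    Each non-control condition perturbs its own random subset of features;
    tDR features receive log2 effects of magnitude ``tdr_lfc``, miRNA
    features ``mirna_lfc``.  Returns ``(counts, condition_labels,
    feature_kind)``.
    """
    rng = np.random.default_rng(seed)
    n_features = n_tdr + n_mirna
    kinds = np.array(["tDR"] * n_tdr + ["miRNA"] * n_mirna)
    base = np.exp(rng.normal(5.0, 1.0, size=n_features))
    cols, blocks, labels = [], [], []
    for cond in conditions:
        eff = np.zeros(n_features)
        if cond != conditions[0]:
            mask = rng.random(n_features) < frac_responsive
            mags = np.where(kinds == "tDR", tdr_lfc, mirna_lfc)
            eff[mask] = (mags * rng.choice([-1.0, 1.0], size=n_features))[mask]
        mu = base * 2.0**eff
        mu_mat = np.repeat(mu[:, None], n_per_group, axis=1)
        blocks.append(_nb_sample(rng, mu_mat, dispersion))
        cols += [f"{cond}_{r + 1}" for r in range(n_per_group)]
        labels += [cond] * n_per_group
    names = [f"tDR-sim-{i}" for i in range(n_tdr)] + [f"mir-sim-{i}" for i in range(n_mirna)]
    counts = pd.DataFrame(np.concatenate(blocks, axis=1), index=names, columns=cols)
    return counts, pd.Series(labels, index=cols), pd.Series(kinds, index=names)
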