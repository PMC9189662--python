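import numpy as np
import pandas as pd
import pytest

from tdrscape.simulate import (
    ConditionProfile,
    FragmentClassSpec,
    LibraryConfig,
    ModificationModel,
    SampleSpec,
    apply_rt_stop,
    cellular_mixture,
    extracellular_mixture,
    sample_fragment,
    simulate_library,
    toy_reference,
)


class TestSampleFragment:
    def test_degenerate_mixture_gives_only_5p_halves(self, reference):
        profile = ConditionProfile(
            mixture=[FragmentClassSpec("five_prime_half", {1: 1.0}, {33: 1.0}, 1.0)]
        )
        rng = np.random.default_rng(0)
        for _ in range(50):
            name, start, end, cls, seq = sample_fragment(profile, reference, rng)
            t = reference.transcript(name)
            assert cls == "five_prime_half"
            assert start == 1
            assert t.seq[start - 1 : end] == seq
            # the end realizes consensus position 33
            from tdrscape.reference import consensus_position

            assert consensus_position(t, end) == 33

    def test_mixture_fractions_within_3se(self, reference):
        """Empirical class fractions converge to the configured 70/20/10
        mixture within 3 binomial SE."""
        profile = ConditionProfile(mixture=extracellular_mixture())
        rng = np.random.default_rng(1)
        n = 20000
        draws = [sample_fragment(profile, reference, rng)[3] for _ in range(n)]
        counts = pd.Series(draws).value_counts(normalize=True)
        for cls, p in [
            ("five_prime_half", 0.7),
            ("three_prime_half_trimmed", 0.2),
            ("mirna", 0.1),
        ]:
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts[cls] - p) < 3 * se

    def test_trailer_class_confined_to_trailer_labels(self, reference):
        spec = FragmentClassSpec(
            "pre_trailer", {"T1": 1.0}, {f"T{i}": 1 / 11 for i in range(20, 31)}, 1.0
        )
        profile = ConditionProfile(mixture=[spec])
        rng = np.random.default_rng(2)
        for _ in range(30):
            name, start, end, cls, seq = sample_fragment(profile, reference, rng)
            t = reference.transcript(name)
            assert t.kind == "precursor"
            assert t.label(start) == "T1"
            assert t.label(end).startswith("T")


class TestRTStop:
    def test_no_readthrough_truncates_exactly_3prime_of_modification(self):
        model = ModificationModel(read_through_no_alkb=0.0)
        rng = np.random.default_rng(0)
        seq, labels, truncated, pos = apply_rt_stop(
            "A" * 76, list(range(1, 77)), model, alkb=False, rng=rng
        )
        assert truncated and pos == 58
        assert labels == list(range(59, 77)) and len(seq) == 18

    def test_fragment_not_covering_modification_unchanged(self):
        model = ModificationModel(read_through_no_alkb=0.0)
        rng = np.random.default_rng(0)
        seq, labels, truncated, pos = apply_rt_stop(
            "C" * 33, list(range(1, 34)), model, alkb=False, rng=rng
        )
        assert not truncated and seq == "C" * 33

    @pytest.mark.parametrize("alkb,p", [(False, 0.3), (True, 0.99)])
    def test_untruncated_fraction_matches_readthrough(self, alkb, p):
        model = ModificationModel(read_through_no_alkb=0.3, read_through_alkb=0.99)
        rng = np.random.default_rng(3)
        n = 10000
        untrunc = sum(
            not apply_rt_stop("G" * 76, list(range(1, 77)), model, alkb, rng)[2]
            for _ in range(n)
        )
        se = np.sqrt(p * (1 - p) / n)
        assert abs(untrunc / n - p) < 3 * se

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            ModificationModel(read_through_no_alkb=0.5, read_through_alkb=0.2)


class TestSimulateLibrary:
    def _spec(self, name, n, alkb=True, mixture=None):
        profile = ConditionProfile(mixture=mixture or extracellular_mixture())
        return SampleSpec(name, profile, n, alkb=alkb)

    def test_same_config_and_seed_byte_identical(self, reference, tmp_path):
        out1 = simulate_library(tmp_path / "a", [self._spec("s", 500)], reference, seed=5)
        out2 = simulate_library(tmp_path / "b", [self._spec("s", 500)], reference, seed=5)
        assert out1["fastq"]["s"].read_bytes() == out2["fastq"]["s"].read_bytes()

    def test_zero_reads_gives_empty_outputs_without_error(self, reference, tmp_path):
        out = simulate_library(tmp_path, [self._spec("empty", 0)], reference, seed=1)
        assert out["fastq"]["empty"].read_text() == ""
        assert len(out["truth_df"]) == 0

    def test_alkb_raises_fraction_spanning_position_58(self, reference, tmp_path):
        """An AlkB-treated library retains far more reads spanning the m1A58
        site than an untreated one (the RT no longer stalls there)."""
        mixture = [
            FragmentClassSpec("three_prime_half_trimmed", {39: 1.0}, {76: 1.0}, 1.0)
        ]
        out = simulate_library(
            tmp_path,
            [
                self._spec("noalkb", 2000, alkb=False, mixture=mixture),
                self._spec("alkb", 2000, alkb=True, mixture=mixture),
            ],
            reference,
            seed=9,
        )
        truth = out["truth_df"]
        frac = truth.groupby("sample")["truncated"].mean()
        assert frac["noalkb"] > 0.8  # default read-through without AlkB is 0.1
        assert frac["alkb"] < 0.05

    def test_reads_are_subsequences_of_source_emission(self, reference, tmp_path):
        """Every emitted read is a (possibly error-mutated) subsequence of its
        source transcript region recorded in the ground truth."""
        config = LibraryConfig(seq_error_rate=0.0, adapter_contam_prob=0.0)
        out = simulate_library(
            tmp_path, [self._spec("s", 800)], reference, seed=13, config=config
        )
        truth = out["truth_df"].set_index("read_id")
        import pysam

        mism_model = config.mod_model.misincorporation_rate
        n_mismatched = 0
        with pysam.FastxFile(str(out["fastq"]["s"])) as fh:
            for entry in fh:
                row = truth.loc[entry.name]
                src = row["source"]
                try:
                    t = reference.transcript(src)
                    start = t.position_of_label(str(row["start_label"]))
                    end = t.position_of_label(str(row["end_label"]))
                    expected = t.seq[start - 1 : end]
                except KeyError:
                    expected = next(
                        s.seq for s in reference.smallrnas if s.name == src
                    )
                if entry.sequence != expected:
                    # only a read-through misincorporation can differ here
                    diffs = sum(a != b for a, b in zip(entry.sequence, expected))
                    assert len(entry.sequence) == len(expected) and diffs == 1
                    n_mismatched += 1
        assert mism_model == 0.3  # misincorporations exist but are bounded
        assert n_mismatched < len(truth) * 0.2

    def test_true_count_marginals_equal_read_totals(self, reference, tmp_path):
        out = simulate_library(
            tmp_path, [self._spec("a", 700), self._spec("b", 300)], reference, seed=21
        )
        counts = out["counts_df"]
        truth = out["truth_df"]
        for sample in ("a", "b"):
            assert counts[sample].sum() == (truth["sample"] == sample).sum()

    def test_output_collision_rejected(self, reference, tmp_path):
        simulate_library(tmp_path, [self._spec("s", 10)], reference, seed=1)
        with pytest.raises(FileExistsError):
            simulate_library(tmp_path, [self._spec("s", 10)], reference, seed=1)
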