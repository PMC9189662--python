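import numpy as np
import pandas as pd
import pytest

from tdrscape.diffexp import (
    SignatureSet,
    ago2_dependent,
    conserved_cross_species,
    de_test,
    ko_dependence,
    overlap_signatures,
    signature,
    size_factors,
    tracking_filter,
)
from tdrscape.simulate import simulate_ko_design, simulate_nb_counts


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        sf = size_factors(counts)
        assert np.allclose(sf, [1.0, 1.0])

    def test_hand_computed_median_of_ratios(self):
        """Rows (100,200),(50,100),(10,20): every ratio pair is
        (1/sqrt(2), sqrt(2)) about the geometric means."""
        counts = pd.DataFrame({"a": [100, 50, 10], "b": [200, 100, 20]})
        sf = size_factors(counts)
        assert sf["a"] == pytest.approx(1 / np.sqrt(2), abs=1e-9)
        assert sf["b"] == pytest.approx(np.sqrt(2), abs=1e-9)

    def test_column_scaling_equivariance(self):
        """Scaling one column by 3 scales its size factor by 3 relative to the
        other samples (the geometric-mean reference rescales all factors by a
        common constant, so equivariance is a between-sample statement)."""
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(5, 500, size=(50, 3)), columns=list("abc"))
        sf = size_factors(counts)
        scaled = counts.copy()
        scaled["b"] = scaled["b"] * 3
        sf2 = size_factors(scaled)
        assert (sf2["b"] / sf2["a"]) / (sf["b"] / sf["a"]) == pytest.approx(3.0, rel=1e-9)
        # normalized matrices are proportional: the scaling is fully removed
        n1 = counts / sf
        n2 = scaled / sf2
        ratio = (n2 / n1).to_numpy()
        assert np.allclose(ratio, ratio[0, 0])

    def test_no_all_positive_row_errors_without_fallback(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="pseudo"):
            size_factors(counts)
        sf = size_factors(counts, allow_pseudo_reference=True)
        assert (sf > 0).all()


class TestDETest:
    def test_constant_feature_is_null(self):
        """A feature with identical normalized counts everywhere has zero
        fold change and a p-value of ~1."""
        counts, groups, _ = simulate_nb_counts(n_features=50, seed=1)
        counts.iloc[0] = 100  # identical in every sample
        sf = pd.Series(1.0, index=counts.columns)
        de = de_test(counts, sf, groups)
        assert de.iloc[0]["log2FoldChange"] == pytest.approx(0.0, abs=1e-12)
        assert de.iloc[0]["pvalue"] > 0.99

    def test_fdr_and_power_on_synthetic_truth(self):
        """Monte-Carlo calibration: on NB counts with 10% true |LFC|=2
        features, FDR at padj<0.05 stays below 0.10 and power above 0.5."""
        fdrs, powers = [], []
        for seed in range(20):
            counts, groups, true_lfc = simulate_nb_counts(seed=seed)
            de = de_test(counts, size_factors(counts), groups)
            called = de.index[de["padj"] < 0.05]
            is_de = true_lfc != 0
            fdrs.append((~is_de[called]).sum() / max(len(called), 1))
            powers.append(is_de[called].sum() / is_de.sum())
        assert np.mean(fdrs) <= 0.10
        assert np.mean(powers) >= 0.5

    def test_permuted_labels_control_discoveries(self):
        counts, groups, _ = simulate_nb_counts(seed=42)
        rng = np.random.default_rng(0)
        perm = pd.Series(rng.permutation(groups.to_numpy()), index=groups.index)
        de = de_test(counts, size_factors(counts), perm)
        frac = (de["padj"] < 0.05).sum() / de["tested"].sum()
        assert frac <= 0.05

    def test_low_count_features_excluded_from_bh_family(self):
        counts, groups, _ = simulate_nb_counts(n_features=30, seed=2)
        counts.iloc[0] = [1, 0, 0, 0, 1, 0]
        de = de_test(counts, size_factors(counts), groups)
        assert not de.iloc[0]["tested"]
        assert np.isnan(de.iloc[0]["padj"])

    def test_single_replicate_group_rejected(self):
        counts, groups, _ = simulate_nb_counts(n_features=20, seed=3)
        bad = groups.copy()
        bad.iloc[0:5] = "A"
        bad.iloc[5] = "B"
        with pytest.raises(ValueError, match="replicates"):
            de_test(counts, size_factors(counts), bad)

    def test_padj_monotone_in_pvalue(self):
        counts, groups, _ = simulate_nb_counts(seed=4)
        de = de_test(counts, size_factors(counts), groups).dropna(subset=["padj"])
        de = de.sort_values("pvalue")
        assert (de["padj"] >= de["pvalue"] - 1e-12).all()
        assert de["padj"].cummax().equals(de["padj"].cummax().sort_values())

    def test_agrees_with_independent_nb_engine(self):
        """Cross-check against an independently developed NB GLM engine on a
        small matrix: fold-change estimates should agree almost exactly."""
        import warnings

        counts, groups, _ = simulate_nb_counts(n_features=100, seed=3)
        de = de_test(counts, size_factors(counts), groups)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from pydeseq2.dds import DeseqDataSet
            from pydeseq2.ds import DeseqStats

            dds = DeseqDataSet(
                counts=counts.T,
                metadata=pd.DataFrame({"condition": groups}),
                design="~condition",
                quiet=True,
            )
            dds.deseq2()
            ds = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
            ds.summary()
        both = de.join(ds.results_df, rsuffix="_ref").dropna(
            subset=["log2FoldChange", "log2FoldChange_ref"]
        )
        r = np.corrcoef(both["log2FoldChange"], both["log2FoldChange_ref"])[0, 1]
        assert r > 0.99


class TestSignatureLogic:
    def _de(self, rows):
        return pd.DataFrame(rows, columns=["padj", "log2FoldChange"]).rename_axis("feature")

    def test_signature_threshold_boundary(self):
        de = pd.DataFrame(
            {"padj": [0.049, 0.051, 0.01], "log2FoldChange": [1.0, 1.0, -2.0]},
            index=["a", "b", "c"],
        )
        s = signature(de, "stress")
        assert s.up == {"a"} and s.down == {"c"}

    def test_signature_counts_match_brute_force_filter(self):
        counts, groups, _ = simulate_nb_counts(seed=7)
        de = de_test(counts, size_factors(counts), groups)
        s = signature(de)
        brute_up = set(de.index[(de["padj"] < 0.05) & (de["log2FoldChange"] > 0)])
        assert s.up == brute_up

    def test_overlap_partition_matches_enumeration(self):
        rng = np.random.default_rng(9)
        universe = [f"f{i}" for i in range(100)]
        sets = [
            SignatureSet(
                condition=c,
                up=set(rng.choice(universe, 30, replace=False)),
                down=set(),
            )
            for c in ("GSD", "hypoxia", "H2O2")
        ]
        table = overlap_signatures(sets)
        up = table[table["direction"] == "up"].set_index("pattern")
        for f in universe:
            member = [s.condition for s in sets if f in s.up]
            if member:
                row = up.loc["&".join(member)]
                assert f in row["features"].split(",")
        # partition: pattern counts sum to the union size
        union = set().union(*(s.up for s in sets))
        assert up["count"].sum() == len(union)

    def test_disjoint_and_identical_sets(self):
        a = SignatureSet("a", up={"x"}, down=set())
        b = SignatureSet("b", up={"y"}, down=set())
        t = overlap_signatures([a, b])
        both = t[(t["direction"] == "up") & (t["pattern"] == "a&b")]
        assert int(both["count"].iloc[0]) == 0
        t2 = overlap_signatures(
            [SignatureSet("a", up={"x"}), SignatureSet("b", up={"x"})]
        )
        full = t2[(t2["direction"] == "up") & (t2["pattern"] == "a&b")]
        assert int(full["count"].iloc[0]) == 1


class TestKODependence:
    def _de(self, padj, lfc):
        return pd.DataFrame({"padj": padj, "log2FoldChange": lfc})

    def test_truth_table_enumeration(self):
        """Exhaustive 25-case table: each (WT state x KO state) combination
        maps to its class, where a state is one of up/down/ns (plus untested
        variants)."""
        states = {
            "up": (0.01, 2.0),
            "down": (0.01, -2.0),
            "ns": (0.8, 0.5),
            "untested": (np.nan, np.nan),
            "ns_down": (0.6, -1.0),
        }

        def expected(wt, ko):
            wt_up = wt == "up"
            wt_down = wt == "down"
            ko_up = ko == "up"
            ko_down = ko == "down"
            if (wt_up and ko_up) or (wt_down and ko_down):
                return "independent"
            if wt_up:
                return "induced"
            if wt_down:
                return "depleted"
            if ko_up or ko_down:
                return "ko_only"
            return "unchanged"

        names = [f"{w}|{k}" for w in states for k in states]
        de_wt = self._de(
            [states[n.split("|")[0]][0] for n in names],
            [states[n.split("|")[0]][1] for n in names],
        ).set_axis(names)
        de_ko = self._de(
            [states[n.split("|")[1]][0] for n in names],
            [states[n.split("|")[1]][1] for n in names],
        ).set_axis(names)
        got = ko_dependence(de_wt, de_ko)
        for n in names:
            wt, ko = n.split("|")
            assert got[n] == expected(wt, ko), n

    def test_classes_partition_features(self):
        counts, labels, truth = simulate_ko_design(seed=0)
        sf = size_factors(counts)
        wt = labels[labels.str.startswith("WT")]
        ko = labels[labels.str.startswith("KO")]
        cls = ko_dependence(
            de_test(counts[wt.index], sf[wt.index], wt),
            de_test(counts[ko.index], sf[ko.index], ko),
        )
        assert set(cls.index) == set(counts.index)
        assert cls.isin(["induced", "depleted", "independent", "ko_only", "unchanged"]).all()

    def test_recovery_of_simulated_truth(self):
        """End-to-end parameter recovery on the WT/KO x control/stress design."""
        recov, mislabel = [], []
        for seed in range(10):
            counts, labels, truth = simulate_ko_design(seed=seed)
            sf = size_factors(counts)
            wt = labels[labels.str.startswith("WT")]
            ko = labels[labels.str.startswith("KO")]
            cls = ko_dependence(
                de_test(counts[wt.index], sf[wt.index], wt),
                de_test(counts[ko.index], sf[ko.index], ko),
            )
            interesting = truth[truth != "unchanged"]
            correct = (cls[interesting.index] == interesting).mean()
            wrong = (
                (cls[interesting.index] != interesting)
                & (cls[interesting.index] != "unchanged")
            ).mean()
            recov.append(correct)
            mislabel.append(wrong)
        assert np.mean(recov) >= 0.80
        assert np.mean(mislabel) <= 0.10


class TestOtherSignatureOps:
    def test_ago2_dependent_is_decreased_and_significant(self):
        de = pd.DataFrame(
            {"padj": [0.01, 0.01, 0.5], "log2FoldChange": [-2.0, 2.0, -2.0]},
            index=["dep", "up", "ns"],
        )
        assert ago2_dependent(de) == {"dep"}
        brute = set(de.index[(de["padj"] < 0.05) & (de["log2FoldChange"] < 0)])
        assert ago2_dependent(de) == brute

    def test_conserved_exact_and_relaxed(self):
        a = {"tDR-1:36-Gly-CCC-1", "tDR-1:33-Pro-AGG-1-M5"}
        b = {"tDR-1:36-Gly-CCC-2", "tDR-1:33-Pro-AGG-1-M5"}
        assert conserved_cross_species(a, b) == {"tDR-1:33-Pro-AGG-1-M5"}
        relaxed = conserved_cross_species(a, b, relaxed=True)
        assert relaxed == a  # Gly-CCC matches across transcript numbers

    def test_conserved_unparseable_name_rejected(self):
        with pytest.raises(Exception, match="garbage"):
            conserved_cross_species({"garbage"}, {"tDR-1:36-Gly-CCC-1"})

    def test_tracking_filter_rules(self):
        counts = pd.DataFrame(
            {
                "c1": [6, 5, 8],
                "c2": [6, 5, 0],
                "c3": [6, 5, 9],
                "t1": [0, 5, 10],
                "t2": [0, 5, 10],
                "t3": [0, 5, 12],
            },
            index=["all_ctrl", "never", "treated_only"],
        )
        groups = pd.Series(
            ["ctrl"] * 3 + ["treat"] * 3, index=counts.columns
        )
        kept = tracking_filter(counts, groups, min_reads=5)
        assert set(kept) == {"all_ctrl", "treated_only"}
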