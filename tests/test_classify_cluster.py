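"""Classification schemes, meta-class matrix, k-means signatures, embedding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rasdyn.classify_cluster import (
    NINE_GROUP_LABELS,
    ClassifierConfig,
    GroupSignature,
    build_metaclass_matrix,
    cross_correlation,
    embed_2d,
    energy_nine_group,
    group_signatures,
    kmeans_groups,
    rmsd_combined_label,
    rmsd_two_way,
    three_way_classify,
)
from rasdyn.synthetic_data import generate_score_table


class TestThreeWay:
    @pytest.mark.parametrize(
        "z,expected",
        [(0.0, "wt-like"), (1.0, "high"), (-1.0, "low"), (0.99, "wt-like"), (-2.3, "low"), (2.5, "high")],
    )
    def test_boundaries_inclusive_to_extremes(self, z, expected):
        assert three_way_classify(10.0 + z * 2.0, 10.0, 2.0) == expected

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            three_way_classify(1.0, 0.0, 0.0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        value=st.floats(-50, 50),
        mu=st.floats(-10, 10),
        sd=st.floats(0.1, 10),
        a=st.floats(0.1, 5),
        b=st.floats(-20, 20),
    )
    def test_affine_equivariance(self, value, mu, sd, a, b):
        """Applying any positive affine map to a metric and its WT stats
        leaves the label unchanged (away from the exact 1-sigma boundary,
        where float rounding can legitimately flip the inclusive edge)."""
        from hypothesis import assume

        z = (value - mu) / sd
        assume(abs(abs(z) - 1.0) > 1e-6)
        assert three_way_classify(value, mu, sd) == three_way_classify(a * value + b, a * mu + b, a * sd)


class TestNineGroup:
    def test_neutral_neutral(self):
        assert energy_nine_group(0.2, 0.5) == ("Neutral", "Neutral")

    def test_gdp_neutral_gtp_unstable_pattern(self):
        # similar GDP energy with a ~3-sigma less stable GTP energy
        assert energy_nine_group(0.3, 2.8) == ("Neutral", "Unstable")

    def test_label_space_has_exactly_nine_members(self):
        seen = {
            energy_nine_group(g, t)
            for g in (-2.0, 0.0, 2.0)
            for t in (-2.0, 0.0, 2.0)
        }
        assert seen == set(NINE_GROUP_LABELS)
        assert len(NINE_GROUP_LABELS) == 9

    def test_stable_is_more_negative_energy(self):
        assert energy_nine_group(-1.5, 0.0)[0] == "Stable"


class TestRmsdTwoWay:
    def test_wt_like_both_states(self):
        assert rmsd_two_way(1.0, 1.0, 0.5) == "closed"
        assert rmsd_combined_label("RMSD NF1", "closed", "closed") == "RMSD NF1 GTP Closed GDP Closed"

    def test_deviated_both(self):
        assert rmsd_two_way(2.0, 1.0, 0.5) == "deviated"

    def test_one_state_deviation_label(self):
        gtp = rmsd_two_way(1.0, 1.0, 0.5)
        gdp = rmsd_two_way(2.0, 1.0, 0.5)
        assert rmsd_combined_label("RMSD NF1", gtp, gdp) == "RMSD NF1 GTP Closed GDP Deviated"


def brute_force_matrix(table, config):
    """Independent elementwise reimplementation of the meta-class matrix."""
    states = table.states
    out = pd.DataFrame(0, index=pd.Index(table.variants, name="variant"),
                       columns=config.column_names(states), dtype=int)
    for variant in table.variants:
        for metric in config.three_way + config.fraction:
            words = ("Above", "Below") if metric in config.three_way else ("Plus SD", "Minus SD")
            for state in states:
                v = table.state_frame(state).loc[variant, metric]
                mu = table.wt_stat(state, metric, "mean")
                sd = table.wt_stat(state, metric, "sd")
                z = (v - mu) / sd
                if z >= config.threshold:
                    out.loc[variant, f"{metric} {words[0]} {state}"] = 1
                elif z <= -config.threshold:
                    out.loc[variant, f"{metric} {words[1]} {state}"] = 1
        if config.energy:
            cats = []
            for state in ("GDP", "GTP"):
                v = table.state_frame(state).loc[variant, config.energy]
                z = (v - table.wt_stat(state, config.energy, "mean")) / table.wt_stat(state, config.energy, "sd")
                cats.append("Stable" if z <= -config.threshold else "Unstable" if z >= config.threshold else "Neutral")
            out.loc[variant, f"{config.energy} GDP {cats[0]} GTP {cats[1]}"] = 1
        for metric in config.rmsd_pairs:
            cats = {}
            for state in ("GTP", "GDP"):
                v = table.state_frame(state).loc[variant, metric]
                z = (v - table.wt_stat(state, metric, "mean")) / table.wt_stat(state, metric, "sd")
                cats[state] = "Deviated" if abs(z) >= config.threshold else "Closed"
            out.loc[variant, f"{metric} GTP {cats['GTP']} GDP {cats['GDP']}"] = 1
    return out


class TestMetaclassMatrix:
    CONFIG = ClassifierConfig(three_way=("m1", "m2"), fraction=("m3",), energy="m4", rmsd_pairs=("m5",))

    def test_wt_identical_variants_have_no_nonneutral_memberships(self):
        table, _ = generate_score_table(n_variants=4, n_metrics=5, planted_groups=1, effect_size=0.0, seed=3)
        table.values.loc[:, :] = 0.0  # everyone exactly at the WT centroid
        mat = build_metaclass_matrix(table, ClassifierConfig(three_way=("m1", "m2"), fraction=("m3",)))
        assert (mat.to_numpy() == 0).all()

    def test_single_shifted_variant_sets_exactly_one_above_column(self):
        table, _ = generate_score_table(n_variants=3, n_metrics=5, planted_groups=1, effect_size=0.0, seed=4)
        table.values.loc[:, :] = 0.0
        table.values.loc[("V001", "GTP"), "m1"] = 2.0
        mat = build_metaclass_matrix(table, ClassifierConfig(three_way=("m1", "m2")))
        assert mat.loc["V001", "m1 Above GTP"] == 1
        assert mat.to_numpy().sum() == 1

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for trial in range(25):
            table, _ = generate_score_table(
                n_variants=6, n_metrics=5, planted_groups=2, effect_size=float(rng.uniform(0, 4)), seed=trial
            )
            mat = build_metaclass_matrix(table, self.CONFIG)
            oracle = brute_force_matrix(table, self.CONFIG)
            pd.testing.assert_frame_equal(mat, oracle)

    def test_column_count_deterministic_from_config(self):
        cols = self.CONFIG.column_names(["GDP", "GTP"])
        # 2 three-way * 2 states * 2 + 1 fraction * 2 * 2 + 9 energy + 4 rmsd
        assert len(cols) == 8 + 4 + 9 + 4
        assert len(set(cols)) == len(cols)

    def test_missing_metric_named_in_error(self):
        table, _ = generate_score_table(n_variants=3, n_metrics=2, planted_groups=1, seed=6)
        with pytest.raises(KeyError, match="m9"):
            build_metaclass_matrix(table, ClassifierConfig(three_way=("m9",)))


class TestKmeans:
    def test_k1_single_group(self):
        table, _ = generate_score_table(n_variants=8, planted_groups=2, seed=7)
        labels = kmeans_groups(table.state_frame("GDP"), k=1, seed=0)
        assert labels.nunique() == 1

    def test_duplicate_rows_k_equals_distinct(self):
        frame = pd.DataFrame([[0.0, 0], [0, 0], [5, 5], [5, 5]], index=list("abcd"))
        labels = kmeans_groups(frame, k=2, seed=0, standardize=False)
        assert labels["a"] == labels["b"]
        assert labels["c"] == labels["d"]
        assert labels["a"] != labels["c"]

    def test_k_exceeding_rows_rejected(self):
        frame = pd.DataFrame(np.eye(3))
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_groups(frame, k=5)

    def test_determinism(self):
        table, _ = generate_score_table(n_variants=20, planted_groups=3, seed=8)
        a = kmeans_groups(table.state_frame("GDP"), k=3, seed=1)
        b = kmeans_groups(table.state_frame("GDP"), k=3, seed=1)
        assert a.equals(b)


class TestSignatures:
    def test_exclusive_metaclass_ranks_first_with_full_occupancy(self):
        groups = pd.Series([0, 0, 1, 1], index=list("abcd"))
        mat = pd.DataFrame(
            {"only_g0": [1, 1, 0, 0], "noise": [1, 0, 1, 0]}, index=list("abcd")
        )
        sigs, retained = group_signatures(groups, mat, top_n=1)
        g0 = next(s for s in sigs if s.group_id == 0)
        assert g0.ranked[0] == ("only_g0", 1.0)

    def test_all_zero_metaclass_never_retained(self):
        groups = pd.Series([0, 0, 1, 1], index=list("abcd"))
        mat = pd.DataFrame(
            {"live1": [1, 1, 0, 0], "live2": [0, 0, 1, 1], "dead": [0, 0, 0, 0]},
            index=list("abcd"),
        )
        _, retained = group_signatures(groups, mat, top_n=2)
        assert "dead" not in retained

    def test_block_structured_matrix_recovers_blocks(self):
        rng = np.random.default_rng(9)
        groups = pd.Series(np.repeat([0, 1, 2], 5), index=[f"v{i}" for i in range(15)])
        mat = pd.DataFrame(0, index=groups.index, columns=[f"mc{j}" for j in range(9)])
        for g in range(3):
            members = groups.index[groups == g]
            mat.loc[members, [f"mc{3 * g + j}" for j in range(3)]] = 1
        _, retained = group_signatures(groups, mat, top_n=3)
        assert retained == [f"mc{j}" for j in range(9)]

    def test_empty_group_rejected(self):
        groups = pd.Series([], dtype=int)
        mat = pd.DataFrame()
        with pytest.raises(ValueError):
            group_signatures(pd.Series([0], index=["a"]), pd.DataFrame(index=["b"]), top_n=1)


class TestCrossCorrelation:
    def test_diagonal_and_negation(self):
        table, _ = generate_score_table(n_variants=30, n_metrics=4, planted_groups=2, seed=10)
        table.values["m_neg"] = -table.values["m1"]
        corr = cross_correlation(table, "GDP")
        assert corr.loc["m1", "m1"] == pytest.approx(1.0)
        assert corr.loc["m1", "m_neg"] == pytest.approx(-1.0)
        assert np.allclose(corr, corr.T)

    def test_independent_metrics_uncorrelated(self):
        table, _ = generate_score_table(n_variants=200, n_metrics=2, planted_groups=1, effect_size=0.0, seed=11)
        corr = cross_correlation(table, "GDP")
        assert abs(corr.loc["m1", "m2"]) < 0.2

    def test_too_few_variants_rejected(self):
        table, _ = generate_score_table(n_variants=1, planted_groups=1, seed=12)
        with pytest.raises(ValueError):
            cross_correlation(table, "GDP")


class TestEmbedding:
    def test_pca_on_rank2_data_preserves_distances(self):
        rng = np.random.default_rng(13)
        latent = rng.normal(size=(30, 2))
        mix = rng.normal(size=(2, 6))
        frame = pd.DataFrame(latent @ mix)
        emb = embed_2d(frame, method="pca")
        from scipy.spatial.distance import pdist

        assert np.allclose(pdist(frame.to_numpy()), pdist(emb.to_numpy()), atol=1e-6)

    def test_row_count_preserved(self):
        frame = pd.DataFrame(np.random.default_rng(14).normal(size=(12, 5)))
        assert len(embed_2d(frame, method="pca")) == 12

    def test_separated_clusters_keep_silhouette(self):
        from sklearn.metrics import silhouette_score

        table, truth = generate_score_table(n_variants=30, planted_groups=2, effect_size=8.0, seed=15)
        frame = table.state_frame("GDP").drop(index="WT")
        labels = [truth.group_labels[v] for v in frame.index]
        emb = embed_2d(frame, method="pca")
        assert silhouette_score(emb.to_numpy(), labels) >= 0.5

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            embed_2d(pd.DataFrame(np.eye(4)), method="tsne-ish")
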