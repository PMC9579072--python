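"""Community pipeline: matrix construction, Bray-Curtis, NMDS, NPMANOVA
(against exhaustive, scikit-bio and vegan oracles) and pairwise Holm tests."""

import itertools
import subprocess

import numpy as np
import pandas as pd
import pytest

from benthme.community import (
    Npmanova,
    bray_curtis,
    build_community_matrix,
    centroids_ci,
    holm_adjust,
    nmds,
    pairwise_permutation,
)
from benthme.design import DesignSpec, ZONES
from benthme.simulate import SimParams, simulate_biomass


@pytest.fixture(scope="module")
def community(survey_table):
    return build_community_matrix(survey_table)


class TestCommunityMatrix:
    def test_transform_then_average_hand_value(self):
        rows = []
        for i, b in enumerate([0.0, 3.0, 6.0], start=1):
            rows.append(
                dict(station_id="S1", zone="North", period="1", design="grid",
                     line="9m", depth_m=9.0, sediment="fine", replicate_index=i,
                     taxon_group="Amphipoda", biomass_wet_g_per_m2=b)
            )
            rows.append(
                dict(station_id="S2", zone="North", period="1", design="grid",
                     line="9m", depth_m=9.0, sediment="fine", replicate_index=i,
                     taxon_group="Amphipoda", biomass_wet_g_per_m2=1.0)
            )
        tab = pd.DataFrame(rows)
        cm = build_community_matrix(tab, min_prevalence=0.0)
        expected = (np.log(1) + np.log(4) + np.log(7)) / 3
        assert cm.values.loc["S1|1", "Amphipoda"] == pytest.approx(expected, abs=1e-4)

    def test_average_then_transform_differs(self, survey_table):
        a = build_community_matrix(survey_table, average="transform-then-average")
        b = build_community_matrix(survey_table, average="average-then-transform")
        assert not np.allclose(a.values.to_numpy(), b.values.to_numpy())

    def test_prevalence_filter(self, survey_table):
        rare = survey_table.copy()
        # make 'other' present at exactly one station visit
        mask = rare["taxon_group"] == "other"
        rare.loc[mask, "biomass_wet_g_per_m2"] = 0.0
        first = rare.index[mask][0]
        rare.loc[first, "biomass_wet_g_per_m2"] = 5.0
        cm = build_community_matrix(rare, min_prevalence=0.05)
        assert "other" in cm.dropped_groups
        cm0 = build_community_matrix(rare, min_prevalence=0.0)
        assert cm0.dropped_groups == ()

    def test_row_per_station_visit(self, community, survey_table):
        grid = survey_table[survey_table["design"] == "grid"]
        visits = grid.groupby(["station_id", "period"], observed=True).ngroups
        assert len(community.values) == visits


class TestBrayCurtis:
    def test_hand_examples(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0], [2.0, 2.0, 1.0], [1.0, 2.0, 3.0]])
        D = bray_curtis(m).to_numpy()
        assert D[0, 1] == pytest.approx(3.0 / 11.0, abs=1e-12)
        assert D[0, 2] == 0.0  # identical rows

    def test_disjoint_support(self):
        D = bray_curtis(pd.DataFrame([[1.0, 0.0], [0.0, 1.0]])).to_numpy()
        assert D[0, 1] == pytest.approx(1.0)

    def test_zero_rows_convention(self):
        with pytest.warns(UserWarning, match="all-zero"):
            D = bray_curtis(pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]]))
        assert D.to_numpy()[0, 1] == 0.0

    def test_invariants_on_survey(self, community):
        D = bray_curtis(community).to_numpy()
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        assert D.min() >= 0.0 and D.max() <= 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(pd.DataFrame([[1.0, -0.1], [0.0, 1.0]]))


class TestNMDS:
    def test_perfect_embedding_low_stress(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        from scipy.spatial.distance import pdist, squareform

        D = bray_curtis(pd.DataFrame(pts + 1.0))  # positive data, 2-D structure
        # build a truly Euclidean-embeddable matrix instead
        from benthme.community import DissimilarityMatrix

        E = squareform(pdist(pts))
        E = E / E.max()
        D = DissimilarityMatrix(pd.DataFrame(E))
        res = nmds(D, k=2, n_starts=10, max_iter=1000, seed=0)
        assert res.stress < 1e-3

    def test_seed_reproducible(self, community):
        D = bray_curtis(community)
        a = nmds(D, n_starts=2, seed=4)
        b = nmds(D, n_starts=2, seed=4)
        assert np.allclose(a.coords.to_numpy(), b.coords.to_numpy())
        assert a.stress == b.stress

    def test_coords_centered(self, community):
        res = nmds(bray_curtis(community), n_starts=2, seed=1)
        assert np.allclose(res.coords.mean(axis=0), 0.0, atol=1e-9)

    def test_stress_decreases_with_dimension(self, community):
        D = bray_curtis(community)
        s2 = nmds(D, k=2, n_starts=4, seed=7).stress
        s3 = nmds(D, k=3, n_starts=4, seed=7).stress
        assert s3 <= s2 + 0.01


class TestCentroids:
    def test_identical_points_zero_width(self):
        from benthme.community import OrdinationResult

        coords = pd.DataFrame(
            {"axis1": [1.0, 1.0, 1.0], "axis2": [2.0, 2.0, 2.0]},
            index=["a", "b", "c"],
        )
        res = OrdinationResult(coords, 0.0, 1, True, None)
        out = centroids_ci(res, pd.Series(["g", "g", "g"], index=coords.index))
        assert out.loc["g", "axis1_halfwidth"] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_pair_centroid_origin(self):
        from benthme.community import OrdinationResult

        coords = pd.DataFrame(
            {"axis1": [-1.0, 1.0], "axis2": [2.0, -2.0]}, index=["a", "b"]
        )
        res = OrdinationResult(coords, 0.0, 1, True, None)
        out = centroids_ci(res, pd.Series(["g", "g"], index=coords.index))
        assert out.loc["g", "axis1_centroid"] == pytest.approx(0.0)
        assert out.loc["g", "axis2_centroid"] == pytest.approx(0.0)

    def test_singleton_flagged(self):
        from benthme.community import OrdinationResult

        coords = pd.DataFrame(
            {"axis1": [0.0, 1.0, 2.0], "axis2": [0.0, 1.0, 2.0]},
            index=["a", "b", "c"],
        )
        res = OrdinationResult(coords, 0.0, 1, True, None)
        out = centroids_ci(res, pd.Series(["g", "g", "solo"], index=coords.index))
        assert not out.loc["solo", "ci_defined"]
        assert np.isnan(out.loc["solo", "axis1_halfwidth"])

    def test_halfwidth_shrinks_with_n(self):
        from benthme.community import OrdinationResult

        rng = np.random.default_rng(2)
        widths = []
        for n in (8, 32, 128):
            coords = pd.DataFrame(
                rng.normal(size=(n, 2)), columns=["axis1", "axis2"]
            )
            res = OrdinationResult(coords, 0.0, 1, True, None)
            out = centroids_ci(res, pd.Series(["g"] * n, index=coords.index))
            widths.append(out.loc["g", "axis1_halfwidth"])
        assert widths[0] > widths[1] > widths[2]


def _tiny_two_group_matrix():
    """6 station visits, two zones, clear but noisy group difference."""
    rng = np.random.default_rng(5)
    vals = np.vstack(
        [
            rng.uniform(1, 2, size=(3, 3)) + np.array([2.0, 0.0, 0.0]),
            rng.uniform(1, 2, size=(3, 3)) + np.array([0.0, 2.0, 0.0]),
        ]
    )
    from benthme.community import CommunityMatrix

    values = pd.DataFrame(
        vals,
        index=[f"s{i}" for i in range(6)],
        columns=["Amphipoda", "Bivalvia", "Polychaeta"],
    )
    meta = pd.DataFrame(
        {
            "station_id": values.index,
            "zone": ["North"] * 3 + ["South"] * 3,
            "period": ["1"] * 6,
            "design": ["grid"] * 6,
            "line": ["9m"] * 6,
            "sediment": ["fine"] * 6,
            "depth_m": [9.0] * 6,
        },
        index=values.index,
    )
    return CommunityMatrix(values, meta, (), "transform-then-average")


class TestNpmanova:
    def test_exhaustive_matches_independent_oracle(self):
        """Exhaustive permutation p equals a brute-force oracle built on
        scikit-bio's one-way PERMANOVA statistic over all relabelings."""
        from skbio.stats.distance import DistanceMatrix, permanova

        cm = _tiny_two_group_matrix()
        res = Npmanova(cm, term_order=("zone",)).fit(n_perm="exhaustive")

        D = bray_curtis(cm).to_numpy()
        dm = DistanceMatrix(D, ids=list(cm.values.index))
        labels = np.array(["A"] * 3 + ["B"] * 3)
        F_obs = permanova(dm, labels, permutations=0)["test statistic"]
        count, total = 0, 0
        for combo in itertools.combinations(range(6), 3):
            lab = np.array(["B"] * 6)
            lab[list(combo)] = "A"
            Fp = permanova(dm, lab, permutations=0)["test statistic"]
            total += 1
            if Fp >= F_obs - 1e-12:
                count += 1
        assert res.table.loc[0, "p"] == pytest.approx(count / total, abs=1e-12)
        assert res.table.loc[0, "pseudo_F"] == pytest.approx(F_obs, rel=1e-9)

    def test_label_swap_invariance(self):
        cm = _tiny_two_group_matrix()
        F1 = Npmanova(cm, ("zone",)).fit(n_perm=99, seed=1).table.loc[0, "pseudo_F"]
        cm2 = _tiny_two_group_matrix()
        cm2.meta["zone"] = cm2.meta["zone"].map({"North": "South", "South": "North"})
        F2 = Npmanova(cm2, ("zone",)).fit(n_perm=99, seed=1).table.loc[0, "pseudo_F"]
        assert F1 == pytest.approx(F2, rel=1e-12)

    def test_ss_decomposition_and_seed(self, community):
        model = Npmanova(community)
        res = model.fit(n_perm=99, seed=3)
        ss = res.table["SS"].to_numpy()
        assert np.sum(ss) == pytest.approx(res.total_ss, rel=1e-10)
        r2 = res.table["R2"].to_numpy()
        assert np.sum(r2) == pytest.approx(1.0, abs=1e-10)
        assert (res.table["p"].dropna() >= 1 / 100).all()
        res2 = model.fit(n_perm=99, seed=3)
        pd.testing.assert_frame_equal(res.table, res2.table)

    def test_term_order_changes_terms_not_total(self, community):
        a = Npmanova(community, ("period", "zone", "sediment", "depth")).fit(
            n_perm=99, seed=1
        )
        b = Npmanova(community, ("zone", "period", "sediment", "depth")).fit(
            n_perm=99, seed=1
        )
        assert a.total_ss == pytest.approx(b.total_ss, rel=1e-12)

    def test_matches_vegan_adonis2(self, tmp_path, community):
        """Sequential SS, pseudo-F and R2 agree with vegan's adonis2."""
        community.values.to_csv(tmp_path / "comm.csv")
        community.meta.to_csv(tmp_path / "meta.csv")
        out = tmp_path / "adonis.csv"
        rscript = f"""
        suppressMessages(library(vegan))
        x <- read.csv("{tmp_path / 'comm.csv'}", row.names=1)
        m <- read.csv("{tmp_path / 'meta.csv'}", row.names=1)
        m$period <- factor(m$period)
        d <- vegdist(x, method="bray")
        a <- adonis2(d ~ period + zone + sediment + line + period:zone,
                     data=m, permutations=99, by="terms")
        write.csv(data.frame(term=rownames(a), Df=a$Df, SS=a$SumOfSqs,
                             F=a$F, R2=a$R2), "{out}", row.names=FALSE)
        """
        subprocess.run(["Rscript", "-e", rscript], check=True, capture_output=True)
        r = pd.read_csv(out).set_index("term")
        res = Npmanova(community).fit(n_perm=99, seed=0)
        mine = res.table.set_index("term")
        for ours, veg in [
            ("period", "period"), ("zone", "zone"), ("sediment", "sediment"),
            ("depth", "line"), ("period:zone", "period:zone"),
        ]:
            assert mine.loc[ours, "SS"] == pytest.approx(r.loc[veg, "SS"], rel=1e-6)
            assert mine.loc[ours, "pseudo_F"] == pytest.approx(r.loc[veg, "F"], rel=1e-6)
            assert mine.loc[ours, "R2"] == pytest.approx(r.loc[veg, "R2"], rel=1e-6)
        assert mine.loc["residual", "SS"] == pytest.approx(
            r.loc["Residual", "SS"], rel=1e-6
        )

    def test_confounded_term_rejected(self):
        cm = _tiny_two_group_matrix()
        cm.meta["dup"] = cm.meta["zone"]
        with pytest.raises(ValueError, match="confounded"):
            Npmanova(cm, ("zone", "dup")).fit(n_perm=99, seed=0)

    def test_null_pvalues_roughly_uniform(self):
        """No group structure => permutation p approximately U(0,1)."""
        from scipy import stats

        rng = np.random.default_rng(11)
        from benthme.community import CommunityMatrix

        ps = []
        for _ in range(200):
            vals = pd.DataFrame(
                rng.uniform(0.5, 3.0, size=(12, 3)),
                index=[f"s{i}" for i in range(12)],
                columns=["a", "b", "c"],
            )
            meta = pd.DataFrame(
                {
                    "station_id": vals.index,
                    "zone": ["North"] * 6 + ["South"] * 6,
                    "period": ["1"] * 12,
                    "design": "grid",
                    "line": "9m",
                    "sediment": "fine",
                    "depth_m": 9.0,
                },
                index=vals.index,
            )
            cm = CommunityMatrix(vals, meta, (), "transform-then-average")
            p = Npmanova(cm, ("zone",)).fit(
                n_perm=199, seed=int(rng.integers(2**31 - 1))
            ).table.loc[0, "p"]
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestPairwiseHolm:
    def test_holm_hand_example(self):
        adj = holm_adjust([0.01, 0.02, 0.04])
        assert adj == pytest.approx([0.03, 0.04, 0.04], abs=1e-12)

    def test_holm_all_ones(self):
        assert holm_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_separated_group_flagged(self):
        """A strongly shifted zone community is significantly different
        from the others after Holm adjustment."""
        p = SimParams.uniform(
            taxa=("Amphipoda", "Bivalvia", "Polychaeta"),
            lnmean=2.0,
            sigma_station=0.2,
            sigma_resid=0.3,
            zone_effects={"North": 2.5, "Middle": 0.0, "South": 0.0},
        )
        spec = DesignSpec.balanced(stations_per_line=12, periods=("1",))
        tab = simulate_biomass(spec, p, 13)
        cm = build_community_matrix(tab, min_prevalence=0.0)
        pairs = pairwise_permutation(
            cm, grouping=cm.meta["zone"], n_perm=199, seed=1
        )
        north = pairs[(pairs["group1"] == "North") | (pairs["group2"] == "North")]
        rest = pairs[(pairs["group1"] != "North") & (pairs["group2"] != "North")]
        assert north["significant"].all()
        assert not rest["significant"].any()

    def test_depth_gradient_on_first_axis(self, calibrated_params):
        """With amphipods shallow/fine and bivalves deep/medium, the first
        NMDS axis separates the two isobath lines (|point-biserial r| > 0.5)."""
        hits = 0
        n_sims = 5
        for seed in range(n_sims):
            tab = simulate_biomass(DesignSpec(), calibrated_params, seed=100 + seed)
            cm = build_community_matrix(tab)
            res = nmds(bray_curtis(cm), n_starts=4, seed=seed)
            is_deep = (cm.meta["line"] == "13m").astype(float).to_numpy()
            r = np.corrcoef(res.coords["axis1"], is_deep)[0, 1]
            if abs(r) > 0.5:
                hits += 1
        assert hits >= int(0.9 * n_sims)
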