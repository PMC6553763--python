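"""Composition summaries, Bray-Curtis similarity and UPGMA clustering."""

import io

import numpy as np
import pandas as pd
import pytest

from fatracer.composition import (
    average_linkage_cluster,
    bray_curtis_similarity,
    class_sums,
    logit_percentages,
    molar_cn_ratio,
    permil_body_carbon,
    profile_matrix,
    relative_composition,
    tfa_filter,
)
from fatracer.isotope import IsotopeKind, IsotopeValue
from fatracer.profiles import SampleGroup, SampleProfile
from fatracer.tables import EXPERIMENTAL_FA, IN_SITU_FA_MASS, fixture_from_tables


def _profile(sid, group, entries, **kw):
    p = SampleProfile(sample_id=sid, group=group, **kw)
    for label, mass in entries:
        p.add(label, mass)
    return p


class TestRelativeComposition:
    def test_diatom_epa_share(self, table_fixture):
        rel = relative_composition(table_fixture.diet[0])
        # EPA dominates the diet at ~22-24 %TFA
        assert rel["20:5(n-3)"] == pytest.approx(22.0, abs=2.0)
        assert sum(rel.values()) == pytest.approx(100.0, abs=1e-9)

    def test_degenerate_profiles(self):
        single = _profile("s", SampleGroup.diet, [("16:0", 5.0)])
        assert relative_composition(single) == {"16:0": 100.0}
        two = _profile("t", SampleGroup.diet, [("16:0", 3.0), ("18:0", 3.0)])
        assert set(relative_composition(two).values()) == {50.0}
        with pytest.raises(ValueError):
            relative_composition(_profile("e", SampleGroup.diet, []))


class TestMolarCN:
    @pytest.mark.parametrize(
        "c, n, expected",
        [
            (577.0, 117.0, 5.8),      # diet culture
            (7668.0, 1929.0, 4.6),    # baseline consumers
            (12.011, 14.007, 1.0),    # equal molar amounts
        ],
    )
    def test_values(self, c, n, expected):
        assert molar_cn_ratio(c, n) == pytest.approx(expected, abs=0.05)

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            molar_cn_ratio(100.0, 0.0)


class TestPermilBodyCarbon:
    def test_experimental_larvae_total(self, table_fixture):
        prof = table_fixture.experimental[0]
        permil = permil_body_carbon(prof)
        # printed whole-pool share is 74 +/- 10 per mil of body C
        assert sum(permil.values()) == pytest.approx(74.0, abs=10.0)

    def test_scale_equivariance_and_zero(self):
        p = _profile("s", SampleGroup.experimental, [("16:0", 50.0), ("14:0", 0.0)],
                     bulk_c=1000.0, mass_kind="carbon")
        one = permil_body_carbon(p)
        assert one["14:0"] == 0.0
        p2 = _profile("s2", SampleGroup.experimental, [("16:0", 50.0)],
                      bulk_c=2000.0, mass_kind="carbon")
        assert permil_body_carbon(p2)["16:0"] == pytest.approx(one["16:0"] / 2)

    def test_missing_bulk_c_rejected(self):
        p = _profile("s", SampleGroup.experimental, [("16:0", 50.0)])
        with pytest.raises(ValueError):
            permil_body_carbon(p)


class TestClassSums:
    def test_diet_pufa_dominates(self, table_fixture):
        sums = class_sums(table_fixture.diet[0])
        # diatom PUFA pool ~92 of ~148 total (printed SD 9)
        assert sums["PUFA"] == pytest.approx(92.0, abs=9.0)
        assert sums["SFA"] + sums["MUFA"] + sums["PUFA"] == pytest.approx(sums["TFA"])

    def test_all_saturated(self):
        sums = class_sums({"16:0": 5.0, "18:0": 2.0})
        assert sums == {"SFA": 7.0, "MUFA": 0.0, "PUFA": 0.0, "TFA": 7.0}

    def test_on_assimilated_carbon(self, table_fixture, baseline):
        from fatracer.assimilation import assimilate_profile

        res = assimilate_profile(table_fixture.experimental[0], baseline)
        per = dict(zip(res.per_fa["label"], res.per_fa["c_assim"]))
        sums = class_sums(per)
        assert sums["PUFA"] == pytest.approx(97.0, abs=11.0)  # printed 97 +/- 11


class TestLogit:
    def test_midpoint_and_monotonicity(self):
        assert logit_percentages(50.0) == pytest.approx(0.0)
        vals = logit_percentages([10.0, 20.0, 80.0])
        assert list(vals) == sorted(vals)

    def test_boundary_policy_is_finite(self):
        out = logit_percentages([0.0, 4.0, 100.0], epsilon=1e-3)
        assert np.all(np.isfinite(out))
        assert out[0] == pytest.approx(np.log(1e-3 / (1 - 1e-3)))

    def test_default_epsilon_half_smallest_nonzero(self):
        out = logit_percentages([0.0, 2.0])  # epsilon = 0.01
        assert out[0] == pytest.approx(np.log(0.01 / 0.99))


class TestBrayCurtis:
    def test_axioms_and_hand_values(self):
        X = pd.DataFrame(
            [[1.0, 1.0, 0.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0]],
            index=["a", "b", "c"],
        )
        S = bray_curtis_similarity(X)
        assert np.allclose(np.diag(S), 100.0)
        assert np.allclose(S, S.T)
        assert S.loc["a", "b"] == pytest.approx(50.0)  # 100*(1 - 2/4)
        assert S.loc["a", "c"] == pytest.approx(100.0)
        disjoint = bray_curtis_similarity(
            pd.DataFrame([[1.0, 0.0], [0.0, 1.0]])
        )
        assert disjoint.iloc[0, 1] == pytest.approx(0.0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.uniform(0, 10, size=(4, 6)))
        S = bray_curtis_similarity(X)
        cols = rng.permutation(6)
        rows = rng.permutation(4)
        S2 = bray_curtis_similarity(X.iloc[rows, cols])
        assert np.allclose(S2.to_numpy(), S.iloc[rows, rows].to_numpy())

    def test_all_zero_pair_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis_similarity(pd.DataFrame([[0.0, 0.0], [0.0, 0.0]]))

    def test_negative_input_shifted(self):
        # logit-transformed compositions are negative; shift restores the
        # domain and similarities stay in [0, 100]
        X = pd.DataFrame([[-3.0, -1.0], [-2.0, -2.0]])
        S = bray_curtis_similarity(X)
        assert ((S.values >= 0) & (S.values <= 100 + 1e-9)).all()


def _brute_force_upgma(sim: pd.DataFrame):
    """Tiny reference UPGMA on a similarity matrix, merging the closest
    pair and averaging similarities over all cross-cluster sample pairs."""
    clusters = {i: (str(lbl),) for i, lbl in enumerate(sim.index)}
    dist = {
        (i, j): 100.0 - sim.iloc[i, j]
        for i in clusters
        for j in clusters
        if i < j
    }
    raw = {
        (str(a), str(b)): 100.0 - sim.loc[a, b] for a in sim.index for b in sim.index
    }
    merges = []
    next_id = len(clusters)
    while len(clusters) > 1:
        (i, j), d = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        merges.append((clusters[i], clusters[j], 100.0 - d))
        merged = clusters[i] + clusters[j]
        del clusters[i], clusters[j]
        dist = {k: v for k, v in dist.items() if i not in k and j not in k}
        for k, members in clusters.items():
            dd = float(
                np.mean([raw[(x, y)] for x in merged for y in members])
            )
            dist[(min(k, next_id), max(k, next_id))] = dd
        clusters[next_id] = merged
        next_id += 1
    return merges


class TestAverageLinkage:
    def test_three_sample_hand_case(self):
        sim = pd.DataFrame(
            [[100.0, 95.0, 80.0], [95.0, 100.0, 80.0], [80.0, 80.0, 100.0]],
            index=["A", "B", "C"],
            columns=["A", "B", "C"],
        )
        tree = average_linkage_cluster(sim)
        first, second = tree.merges
        assert set(first.members) == {"A", "B"}
        assert first.similarity == pytest.approx(95.0)
        assert second.similarity == pytest.approx(80.0)  # mean(80, 80)

    def test_two_samples_single_merge(self):
        sim = pd.DataFrame([[100.0, 42.0], [42.0, 100.0]], index=["x", "y"],
                           columns=["x", "y"])
        tree = average_linkage_cluster(sim)
        assert len(tree.merges) == 1
        assert tree.merges[0].similarity == pytest.approx(42.0)

    def test_identical_samples_merge_at_100(self):
        sim = pd.DataFrame(100.0, index=list("abc"), columns=list("abc"))
        tree = average_linkage_cluster(sim)
        assert all(m.similarity == pytest.approx(100.0) for m in tree.merges)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            average_linkage_cluster(pd.DataFrame([[100.0]]))

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = 5
            d = rng.uniform(5, 60, size=(n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            sim = pd.DataFrame(100.0 - d, index=list("abcde"), columns=list("abcde"))
            tree = average_linkage_cluster(sim)
            expected = _brute_force_upgma(sim)
            got_heights = sorted(m.similarity for m in tree.merges)
            exp_heights = sorted(m[2] for m in expected)
            assert np.allclose(got_heights, exp_heights)
            # partitions agree step by step (heights are distinct a.s.)
            got_sets = sorted(frozenset(m.members) for m in tree.merges)
            exp_sets = sorted(frozenset(a + b) for a, b, _ in expected)
            assert got_sets == exp_sets

    def test_newick_export_is_parseable(self):
        from Bio import Phylo

        sim = pd.DataFrame(
            [[100.0, 95.0, 80.0], [95.0, 100.0, 80.0], [80.0, 80.0, 100.0]],
            index=["s1", "s2", "s3"],
            columns=["s1", "s2", "s3"],
        )
        tree = average_linkage_cluster(sim)
        parsed = Phylo.read(io.StringIO(tree.to_newick()), "newick")
        assert sorted(t.name for t in parsed.get_terminals()) == ["s1", "s2", "s3"]


class TestProfileMatrix:
    def _jittered_fixture(self):
        # six consumer samples shaped on the study means with SD-scale
        # jitter: 3 baseline and 3 fed replicates
        rng = np.random.default_rng(5)
        profs = []
        for g, masses in (
            (SampleGroup.in_situ, IN_SITU_FA_MASS),
            (SampleGroup.experimental, {k: v[0] for k, v in EXPERIMENTAL_FA.items()}),
        ):
            for r in range(3):
                entries = [
                    (label, m * rng.lognormal(0, 0.06)) for label, m in masses.items()
                ]
                profs.append(
                    _profile(f"{g.value}_{r}", g, entries, mass_kind="carbon")
                )
        return profs

    def test_tfa_filter_keeps_fa_passing_in_any_group(self):
        a = _profile("a", SampleGroup.diet, [("16:0", 99.0), ("14:0", 1.0)])
        b = _profile("b", SampleGroup.in_situ, [("16:0", 50.0), ("14:0", 50.0)])
        keep = tfa_filter([a, b], threshold_percent=1.0)
        assert keep == ["14:0", "16:0"]  # 14:0 passes via group b
        keep_strict = tfa_filter([a], threshold_percent=1.0)
        assert keep_strict == ["16:0"]

    def test_matrix_percent_rows_sum_to_100_without_filter(self):
        profs = self._jittered_fixture()
        mat = profile_matrix(profs, value="percent", threshold_percent=None)
        assert np.allclose(mat.sum(axis=1), 100.0)

    def test_groups_separate_in_dendrogram(self):
        # replicate-level clustering mirrors the study qualitatively:
        # baseline and fed samples form two high-similarity groups
        profs = self._jittered_fixture()
        mat = profile_matrix(profs, value="mass", threshold_percent=1.0)
        sim = bray_curtis_similarity(mat)
        tree = average_linkage_cluster(sim)
        top = tree.merges[-1]
        sides = [set(top.left), set(top.right)]
        groups = [
            {p.sample_id for p in profs if p.group is SampleGroup.in_situ},
            {p.sample_id for p in profs if p.group is SampleGroup.experimental},
        ]
        assert sides in (groups, groups[::-1])
        assert top.similarity > 50.0

    def test_logit_matrix_clusters_and_runs_end_to_end(self):
        profs = self._jittered_fixture()
        mat = profile_matrix(profs, value="percent", threshold_percent=1.0, logit=True)
        sim = bray_curtis_similarity(mat)
        tree = average_linkage_cluster(sim)
        assert len(tree.merges) == len(profs) - 1
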