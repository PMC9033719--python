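"""Marker filtering/clustering/pruning, combos, and diversity oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from haplocharter.cohort import CohortConfig, generate_cohort
from haplocharter import haplotypes as hp
from haplocharter.variants import MISSING, filter_sites

from conftest import make_matrix


def brute_force_pi(hap_matrix, n_invariant):
    """Oracle: average pairwise per-site differences over all haplotype pairs.

    ``hap_matrix`` is (n_sites, n_haplotypes) allele indices without missing.
    """
    S, H = hap_matrix.shape
    num = 0
    den = 0
    for i, j in itertools.combinations(range(H), 2):
        num += int(np.sum(hap_matrix[:, i] != hap_matrix[:, j]))
        den += S + n_invariant
    return num / den if den else float("nan")


class TestFilterMarkers:
    def test_het_heavy_site_removed(self):
        het = [(0, 1)] * 4 + [(0, 0)] * 3 + [(1, 1)] * 3  # 40% het
        ok = [(0, 0)] * 5 + [(1, 1)] * 5
        m = make_matrix([(100, "A", ["G"], het), (200, "A", ["G"], ok)])
        kept = hp.filter_markers(m)
        assert [s.pos for s in kept.sites] == [200]

    def test_low_alt_count_removed(self):
        # after het masking: 2 alt alleles (< min_allele_count=4) -> dropped;
        # 4 alt alleles -> kept
        gts = [(1, 1), (1, 1)] + [(0, 0)] * 148
        bad = [(1, 1), (0, 1)] + [(0, 0)] * 148
        m = make_matrix([(100, "A", ["G"], bad), (200, "A", ["G"], gts)])
        kept = hp.filter_markers(m)
        assert [s.pos for s in kept.sites] == [200]

    def test_passing_site_kept_with_hets_masked(self):
        gts = [(0, 1)] + [(1, 1)] * 3 + [(0, 0)] * 8
        m = make_matrix([(100, "A", ["G"], gts)])
        kept = hp.filter_markers(m)
        assert kept.n_sites == 1
        np.testing.assert_array_equal(kept.genotypes[0, 0], [MISSING, MISSING])
        np.testing.assert_array_equal(kept.genotypes[0, 1], [1, 1])

    def test_high_missingness_removed(self):
        gts = [(-1, -1)] * 7 + [(1, 1)] * 2 + [(0, 0)] * 1  # 70% missing
        m = make_matrix([(100, "A", ["G"], gts)])
        assert hp.filter_markers(m).n_sites == 0


class TestClusterMarkers:
    def test_planted_partition_recovered_without_leak(self):
        res = generate_cohort(CohortConfig(
            seed=6, ld_leak=0.0, missing_rate=0.0, background_snp_count=0,
            n_wild=40, n_landrace=150, n_old_cultivar=10, n_modern_cultivar=30,
        ))
        snp_idx = [i for i, lab in enumerate(res.truth.site_labels)
                   if lab.startswith("G")]
        markers = hp.filter_markers(res.matrix.take_sites(snp_idx))
        groups = hp.cluster_markers(markers, res.phenotypes)
        found = {g.member_positions for g in groups}
        truth: dict = {}
        for site, lab in zip(res.matrix.sites, res.truth.site_labels):
            if lab.startswith("G"):
                truth.setdefault(lab, []).append(site.pos)
        expected = {tuple(sorted(v)) for v in truth.values()}
        assert found == expected

    def test_top_group_is_most_protein_associated(self):
        res = generate_cohort(CohortConfig(seed=8))
        m = filter_sites(res.matrix)
        markers = hp.filter_markers(m)
        groups = hp.cluster_markers(markers, res.phenotypes)
        contrasts = [abs(g.protein_contrast) for g in groups]
        assert contrasts[0] == max(contrasts)
        focal_group = {
            s.pos for s, lab in zip(res.matrix.sites, res.truth.site_labels)
            if lab == "G01"
        }
        assert set(groups[0].member_positions) <= focal_group | {
            res.config.repeat_locus, res.config.deletion_start - 1
        }

    def test_stricter_threshold_never_merges(self):
        res = generate_cohort(CohortConfig(
            seed=9, n_wild=20, n_landrace=80, n_old_cultivar=5,
            n_modern_cultivar=15, background_snp_count=20,
        ))
        markers = hp.filter_markers(filter_sites(res.matrix))
        n_09 = len(hp.cluster_markers(markers, independence_r2=0.9))
        n_10 = len(hp.cluster_markers(markers, independence_r2=1.0))
        assert n_10 >= n_09

    def test_independent_plants_share_no_edges(self):
        res = generate_cohort(CohortConfig(
            seed=10, group_layout="independent", ld_leak=0.0,
            missing_rate=0.0, background_snp_count=0,
            n_wild=40, n_landrace=150, n_old_cultivar=10, n_modern_cultivar=30,
        ))
        snp_idx = [i for i, lab in enumerate(res.truth.site_labels)
                   if lab.startswith("G")]
        markers = hp.filter_markers(res.matrix.take_sites(snp_idx))
        groups = hp.cluster_markers(markers, res.phenotypes)
        assert len(groups) == res.config.n_marker_groups


class TestPruneGroups:
    def _mk(self, gid, members, rep=None, contrast=1.0):
        members = tuple(members)
        return hp.MarkerGroup(
            group_id=gid, representative_pos=rep or members[0],
            member_positions=members, protein_contrast=contrast,
        )

    def _combo(self, states):
        return hp.HaplotypeCombo(label="A", state_vector=tuple(states),
                                 members=("s1",))

    def test_duplicate_state_vectors_keep_largest(self):
        g1 = self._mk("M01", range(100, 110))
        g2 = self._mk("M02", range(200, 220))
        combos = [self._combo(["ALT", "ALT"]), self._combo(["REF", "REF"])]
        kept = hp.prune_groups([g1, g2], combos)
        assert [g.member_positions for g in kept] == [g2.member_positions]

    def test_small_groups_dropped_at_six_member_boundary(self):
        g5 = self._mk("M01", range(100, 105))   # 5 SNPs: dropped
        g6 = self._mk("M02", range(200, 206))   # 6 SNPs: kept
        combos = [self._combo(["ALT", "REF"]), self._combo(["REF", "ALT"])]
        kept = hp.prune_groups([g5, g6], combos)
        assert len(kept) == 1
        assert kept[0].member_positions == g6.member_positions

    def test_one_snp_difference_drops_smaller(self):
        g1 = self._mk("M01", range(100, 110))
        g2 = self._mk("M02", list(range(100, 110)) + [250])
        combos = [self._combo(["ALT", "REF"]), self._combo(["REF", "ALT"])]
        kept = hp.prune_groups([g1, g2], combos)
        assert [g.member_positions for g in kept] == [g2.member_positions]

    def test_all_pruned_raises_actionable_error(self):
        g = self._mk("M01", range(100, 103))
        with pytest.raises(ValueError, match="pruned"):
            hp.prune_groups([g], [self._combo(["ALT"])])

    def test_relabelling_is_sequential(self):
        g1 = self._mk("M01", range(100, 105))
        g2 = self._mk("M02", range(200, 210))
        g3 = self._mk("M03", range(300, 310))
        combos = [self._combo(["ALT", "REF", "ALT"]),
                  self._combo(["REF", "ALT", "HET"])]
        kept = hp.prune_groups([g1, g2, g3], combos)
        assert [g.group_id for g in kept] == ["M01", "M02"]
        assert kept[0].member_positions == g2.member_positions


class TestAssignCombos:
    def test_all_ref_sample_gets_all_ref_vector(self):
        m = make_matrix([
            (100, "A", ["G"], [(0, 0), (1, 1)]),
            (200, "A", ["G"], [(0, 0), (1, 1)]),
        ])
        groups = [
            hp.MarkerGroup("M01", 100, (100,), 1.0),
            hp.MarkerGroup("M02", 200, (200,), 0.5),
        ]
        combos, unassigned = hp.assign_combos(groups, m)
        assert unassigned == []
        vecs = {c.state_vector for c in combos}
        assert ("REF", "REF") in vecs and ("ALT", "ALT") in vecs

    def test_miss_state_sets_sample_aside(self):
        m = make_matrix([(100, "A", ["G"], [(-1, -1), (0, 1), (0, -1)])])
        groups = [hp.MarkerGroup("M01", 100, (100,), 1.0)]
        combos, unassigned = hp.assign_combos(groups, m)
        assert unassigned == ["S1"]
        states = {c.state_vector[0] for c in combos}
        assert states == {"HET", "HETMISS"}

    def test_default_cohort_yields_at_least_seven_combos(self, default_cohort):
        assert len(default_cohort.truth.combo_vectors()) >= 7
        m = filter_sites(default_cohort.matrix)
        markers = hp.filter_markers(m)
        prov = hp.cluster_markers(markers, default_cohort.phenotypes)
        pc, _ = hp.assign_combos(prov, m)
        groups = hp.prune_groups(prov, pc)
        combos, _ = hp.assign_combos(groups, m)
        assert len(combos) >= 7

    def test_single_sample_forms_single_combo(self):
        m = make_matrix([(100, "A", ["G"], [(1, 1)])])
        groups = [hp.MarkerGroup("M01", 100, (100,), 1.0)]
        combos, unassigned = hp.assign_combos(groups, m)
        assert len(combos) == 1 and combos[0].members == ("S1",)

    def test_partition_property(self, default_cohort):
        m = filter_sites(default_cohort.matrix)
        markers = hp.filter_markers(m)
        prov = hp.cluster_markers(markers, default_cohort.phenotypes)
        pc, _ = hp.assign_combos(prov, m)
        groups = hp.prune_groups(prov, pc)
        combos, unassigned = hp.assign_combos(groups, m)
        seen: list = []
        for c in combos:
            seen.extend(c.members)
        assert len(seen) == len(set(seen))
        assert sorted(seen + unassigned) == sorted(m.samples)


class TestPiDxy:
    def test_hand_enumerated_single_site(self):
        # 4 haplotypes, one 2/2 split site, 9 invariant sites:
        # pi = (2*2) / (6 + 9*6) = 0.0667
        m = make_matrix([(100, "A", ["G"], [(0, 0), (1, 1)])])
        stat = hp.pi_dxy(m, {"g": [0, 1]}, region_length=10)
        assert stat.pi["g"] == pytest.approx(4 / 60)

    def test_identical_haplotypes_have_zero_pi(self):
        m = make_matrix([(100, "A", ["G"], [(1, 1), (1, 1)])])
        stat = hp.pi_dxy(m, {"g": [0, 1]}, region_length=50)
        assert stat.pi["g"] == 0.0

    def test_fixed_difference_dxy(self):
        # two groups fixed for opposite alleles at the only variant site,
        # region length 10 -> dxy = 0.1, within-group pi = 0
        m = make_matrix([(100, "A", ["G"], [(0, 0), (0, 0), (1, 1), (1, 1)])])
        stat = hp.pi_dxy(m, {"a": [0, 1], "b": [2, 3]}, region_length=10)
        assert stat.dxy[frozenset(("a", "b"))] == pytest.approx(0.1)
        assert stat.pi["a"] == 0.0 and stat.pi["b"] == 0.0

    @given(st.integers(0, 2**32 - 1))
    def test_matches_brute_force_pairwise_average(self, seed):
        rng = np.random.default_rng(seed)
        n_samples = int(rng.integers(2, 5))          # <= 8 haplotypes
        n_sites = int(rng.integers(1, 6))
        n_invariant = int(rng.integers(0, 10))
        gt = rng.integers(0, 2, size=(n_sites, n_samples, 2))
        recs = [(100 + i, "A", ["G"], [tuple(g) for g in gt[i]])
                for i in range(n_sites)]
        m = make_matrix(recs)
        stat = hp.pi_dxy(m, {"g": list(range(n_samples))},
                         n_invariant=n_invariant)
        haps = gt.reshape(n_sites, -1)
        assert stat.pi["g"] == pytest.approx(
            brute_force_pi(haps, n_invariant), abs=1e-12
        )

    def test_adding_invariant_sites_shrinks_pi(self):
        m = make_matrix([(100, "A", ["G"], [(0, 0), (1, 1)])])
        small = hp.pi_dxy(m, {"g": [0, 1]}, n_invariant=5).pi["g"]
        large = hp.pi_dxy(m, {"g": [0, 1]}, n_invariant=50).pi["g"]
        assert large < small


class TestGroupPhenotypeSummary:
    def test_noise_free_landrace_contrast_is_exact(self):
        res = generate_cohort(CohortConfig(
            seed=12, noise_sd_protein=0.0, noise_sd_oil=0.0,
            n_wild=30, n_landrace=300, n_old_cultivar=5, n_modern_cultivar=15,
        ))
        m = filter_sites(res.matrix)
        markers = hp.filter_markers(m)
        prov = hp.cluster_markers(markers, res.phenotypes)
        pc, _ = hp.assign_combos(prov, m)
        groups = hp.prune_groups(prov, pc)
        combos, _ = hp.assign_combos(groups, m)
        table, _tests = hp.group_phenotype_summary(
            combos, groups, m, res.phenotypes
        )
        sel = table[(table.scope == "group") & (table.name == "M01")
                    & (table.dclass == "landrace") & (table.trait == "protein")]
        alt = sel[sel.state == "ALT"]["mean"].iloc[0]
        ref = sel[sel.state == "REF"]["mean"].iloc[0]
        assert alt - ref == pytest.approx(3.32)

    def test_permuted_phenotype_kills_contrast(self):
        res = generate_cohort(CohortConfig(seed=13, n_wild=30, n_landrace=300,
                                           n_old_cultivar=5,
                                           n_modern_cultivar=15))
        rng = np.random.default_rng(0)
        perm = res.phenotypes.copy()
        perm["protein"] = rng.permutation(perm["protein"].to_numpy())
        m = filter_sites(res.matrix)
        markers = hp.filter_markers(m)
        prov = hp.cluster_markers(markers, res.phenotypes)
        pc, _ = hp.assign_combos(prov, m)
        groups = hp.prune_groups(prov, pc)
        combos, _ = hp.assign_combos(groups, m)
        _table, tests = hp.group_phenotype_summary(combos, groups, m, perm)
        key = ("M01", "protein", "all")
        assert abs(tests[key].diff) < 0.8
        assert tests[key].p_value > 1e-4

    def test_pruning_never_removes_top_contrast_group(self):
        for seed in (1, 2, 3, 4, 5):
            res = generate_cohort(CohortConfig(
                seed=seed, n_wild=30, n_landrace=200,
                n_old_cultivar=5, n_modern_cultivar=25,
                background_snp_count=30,
            ))
            m = filter_sites(res.matrix)
            markers = hp.filter_markers(m)
            prov = hp.cluster_markers(markers, res.phenotypes)
            pc, _ = hp.assign_combos(prov, m)
            groups = hp.prune_groups(prov, pc)
            assert prov[0].representative_pos == groups[0].representative_pos
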