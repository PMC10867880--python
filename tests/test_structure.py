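"""Homophily, motif censuses vs brute force, null models, z-scores."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_web, random_layered_web
from webcva.core import FoodWeb, Group, SpeciesNode
from webcva.structure import (
    _web_tally_fast,
    census_apparent_competition,
    census_tritrophic,
    coleman_homophily,
    driving_position_tally,
    erdos_renyi_null,
    motif_zscores,
)


def random_directed_web(rng, n, p=0.15) -> FoodWeb:
    """Arbitrary random directed group-labeled graph (no validity claims)."""
    groups = ["bird", "mammal", "reptile", "invertebrate", "plant"]
    nodes = [
        SpeciesNode(id=f"n{k}", group=Group(groups[int(rng.integers(5))]))
        for k in range(n)
    ]
    edges = [
        (f"n{i}", f"n{j}")
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < p
    ]
    return FoodWeb(nodes, edges)


class TestHomophily:
    def test_all_links_within_gives_plus_one(self):
        web = make_web(
            {"a": "bird", "b": "bird", "c": "mammal", "d": "mammal"},
            [("a", "b"), ("c", "d")],
        )
        h = coleman_homophily(web)
        assert h.loc["bird", "H"] == 1.0
        assert h.loc["mammal", "H"] == 1.0

    def test_no_links_within_gives_minus_one(self):
        web = make_web(
            {"a": "bird", "b": "bird", "c": "mammal"}, [("a", "c"), ("b", "c")]
        )
        assert coleman_homophily(web).loc["bird", "H"] == -1.0

    def test_balanced_case_gives_zero(self):
        web = make_web(
            {"a": "bird", "b": "bird", "c": "mammal", "d": "mammal"},
            [("a", "b"), ("a", "c")],
        )
        h = coleman_homophily(web)
        assert h.loc["bird", "w"] == 0.5
        assert h.loc["bird", "p"] == 0.5
        assert h.loc["bird", "H"] == 0.0

    def test_invert_flag_equals_manual_reversal(self, mojave_synth):
        from webcva.core import invert_links

        web = mojave_synth.web
        a = coleman_homophily(web, invert=True)
        b = coleman_homophily(invert_links(web), invert=False)
        assert np.allclose(a["H"], b["H"], equal_nan=True)

    def test_plants_on_inverted_web_score_minus_one(self, mojave_synth):
        h = coleman_homophily(mojave_synth.web, invert=True)
        assert h.loc["plant", "H"] == -1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_bounded_in_unit_interval(self, seed):
        web = random_directed_web(np.random.default_rng(seed), 25)
        h = coleman_homophily(web)["H"].dropna()
        assert ((h >= -1) & (h <= 1)).all()

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        n=st.integers(2, 10),
        groups=st.lists(st.sampled_from(["bird", "mammal", "plant"]),
                        min_size=10, max_size=10),
        seed=st.integers(0, 2**16),
    )
    def test_bounds_and_inversion_duality_hold_generally(self, n, groups, seed):
        rng = np.random.default_rng(seed)
        gmap = {f"n{k}": groups[k] for k in range(n)}
        edges = [
            (f"n{i}", f"n{j}")
            for i in range(n)
            for j in range(n)
            if i != j and rng.random() < 0.3
        ]
        web = make_web(gmap, edges)
        if not edges:
            return
        from webcva.core import invert_links

        h = coleman_homophily(web)["H"].dropna()
        assert ((h >= -1) & (h <= 1)).all()
        a = coleman_homophily(web, invert=True)["H"]
        b = coleman_homophily(invert_links(web))["H"]
        assert np.allclose(a, b, equal_nan=True)

    def test_group_with_no_out_links_undefined(self):
        web = make_web({"a": "bird", "p": "plant"}, [("a", "p")])
        assert np.isnan(coleman_homophily(web).loc["plant", "H"])

    def test_empty_web_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            coleman_homophily(FoodWeb([], []))


def brute_force_ac(web: FoodWeb, induced=True):
    """O(n^3) reference enumeration of apparent-competition motifs."""
    out = set()
    ids = web.ids
    for p, a, b in itertools.permutations(ids, 3):
        if a > b:
            continue
        if a in web.resources_of(p) and b in web.resources_of(p):
            if induced and (
                a in web.resources_of(b) or b in web.resources_of(a)
            ):
                continue
            out.add((p, a, b))
    return out


def brute_force_tt(web: FoodWeb):
    out = set()
    for x, m, b in itertools.permutations(web.ids, 3):
        if (
            m in web.resources_of(x)
            and b in web.resources_of(m)
            and b not in web.resources_of(x)
        ):
            out.add((x, m, b))
    return out


class TestCensuses:
    def test_three_unlinked_prey_give_three_pairs(self):
        web = make_web(
            {"P": "bird", "A": "plant", "B": "plant", "C": "plant"},
            [("P", "A"), ("P", "B"), ("P", "C")],
        )
        assert census_apparent_competition(web).count == 3

    def test_linked_prey_pair_excluded_when_induced(self):
        web = make_web(
            {"P": "bird", "A": "mammal", "B": "plant"},
            [("P", "A"), ("P", "B"), ("A", "B")],
        )
        assert census_apparent_competition(web).count == 0
        assert census_apparent_competition(web, induced=False).count == 1

    def test_empty_edge_set(self):
        web = make_web({"a": "bird"}, [])
        assert census_apparent_competition(web).count == 0
        assert census_tritrophic(web).count == 0

    def test_chain_is_one_tritrophic_motif(self):
        web = make_web(
            {"C": "bird", "H": "mammal", "P": "plant"}, [("C", "H"), ("H", "P")]
        )
        assert census_tritrophic(web).count == 1

    def test_omnivory_link_excludes_chain(self):
        web = make_web(
            {"C": "bird", "H": "mammal", "P": "plant"},
            [("C", "H"), ("H", "P"), ("C", "P")],
        )
        assert census_tritrophic(web).count == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_censuses_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        web = random_directed_web(rng, int(rng.integers(8, 26)))
        ac = census_apparent_competition(web)
        assert set(ac.occurrences) == brute_force_ac(web)
        tt = census_tritrophic(web)
        assert set(tt.occurrences) == brute_force_tt(web)

    @pytest.mark.parametrize("seed", range(8))
    def test_fast_tally_equals_census_tally(self, seed):
        rng = np.random.default_rng(50 + seed)
        web = random_directed_web(rng, 20)
        slow = driving_position_tally(
            web, census_apparent_competition(web), census_tritrophic(web)
        )
        fast = _web_tally_fast(web)
        assert (slow.sort_index() == fast.sort_index()).all().all()


class TestDrivingTally:
    def test_mixed_and_same_group_prey_cells(self):
        web = make_web(
            {"P": "reptile", "b1": "bird", "b2": "bird", "m": "mammal"},
            [("P", "b1"), ("P", "b2"), ("P", "m")],
        )
        tally = driving_position_tally(web, census_apparent_competition(web))
        assert tally.loc["bird", "ac_both"] == 1  # {b1, b2}
        assert tally.loc["bird", "ac_one"] == 2  # {b1,m}, {b2,m}
        assert tally.loc["mammal", "ac_one"] == 2
        assert tally.loc["mammal", "ac_both"] == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_counting_identity(self, seed):
        # each occurrence contributes one 'both' or two 'one' increments
        web = random_directed_web(np.random.default_rng(seed), 18)
        ac = census_apparent_competition(web)
        tally = driving_position_tally(web, ac)
        assert (
            tally["ac_both"].sum() + tally["ac_one"].sum() / 2 == ac.count
        )


class TestNullModel:
    def test_exact_node_and_edge_counts_groups_in_place(self, mojave_synth):
        web = mojave_synth.web
        null = erdos_renyi_null(web, seed=5)
        assert len(null) == len(web)
        assert null.n_edges == web.n_edges
        assert all(
            null.nodes[i].group is web.nodes[i].group for i in web.ids
        )

    def test_seed_determinism(self, mojave_synth):
        web = mojave_synth.web
        assert erdos_renyi_null(web, seed=1) == erdos_renyi_null(web, seed=1)
        assert erdos_renyi_null(web, seed=1) != erdos_renyi_null(web, seed=2)

    def test_within_group_edge_expectation(self):
        rng = np.random.default_rng(0)
        groups = {f"b{k}": "bird" for k in range(20)}
        groups.update({f"m{k}": "mammal" for k in range(30)})
        edges = [("b0", f"m{k}") for k in range(10)] + [
            (f"m{k}", f"m{k+1}") for k in range(29)
        ]
        web = make_web(groups, edges)
        m, n = web.n_edges, len(web)
        expect = m * (20 * 19) / (n * (n - 1))
        counts = []
        for k in range(300):
            null = erdos_renyi_null(web, seed=k)
            counts.append(
                sum(
                    1
                    for u, v in null.edges
                    if u.startswith("b") and v.startswith("b")
                )
            )
        # se of the mean ~ sqrt(var/300) < 0.15; allow 5 se
        assert np.mean(counts) == pytest.approx(expect, abs=0.75)

    def test_gnp_variant_matches_edge_count_in_expectation(self, mojave_synth):
        web = mojave_synth.web
        ms = [erdos_renyi_null(web, seed=k, model="gnp").n_edges for k in range(20)]
        assert np.mean(ms) == pytest.approx(web.n_edges, rel=0.05)


@pytest.fixture(scope="module")
def small_result():
    web = random_directed_web(np.random.default_rng(7), 30, p=0.12)
    return motif_zscores(web, n_null=30, seed=3)


class TestZScores:
    def test_z_formula_consistency(self, small_result):
        df = small_result[~small_result.degenerate]
        z = (df.observed - df.null_mean) / df.null_sd
        assert np.allclose(df.z, z)
        assert ((df.p > 0) & (df.p < 1)).all()

    def test_reproducible_per_seed(self):
        web = random_directed_web(np.random.default_rng(8), 25, p=0.12)
        a = motif_zscores(web, n_null=10, seed=4)
        b = motif_zscores(web, n_null=10, seed=4)
        assert a.equals(b)

    def test_degenerate_cell_flagged_not_zero(self):
        web = make_web({"a": "bird", "p": "plant"}, [("a", "p")])
        df = motif_zscores(web, n_null=5, seed=0)
        assert df.degenerate.all()  # a 2-node web can hold no 3-node motif
        assert df.z.isna().all()

    def test_empirical_p_option(self):
        web = random_directed_web(np.random.default_rng(9), 25, p=0.12)
        df = motif_zscores(web, n_null=20, seed=5, p_method="empirical")
        ok = df[~df.degenerate]
        assert ((ok.p >= 1 / 21) & (ok.p <= 1.0)).all()

    def test_bird_subweb_depresses_cross_group_shared_prey(self):
        """A strongly within-group bird block should show negative ac_one z."""
        from webcva.synthetic import generate_web, mojave_like_config

        syn = generate_web(mojave_like_config(seed=7))
        df = motif_zscores(syn.web, n_null=25, seed=6)
        row = df[(df.group == "bird") & (df.cell == "ac_one")].iloc[0]
        assert row.z < -3
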