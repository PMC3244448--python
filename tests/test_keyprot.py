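import pytest
from hypothesis import given, settings, strategies as st

import networkx as nx

from spanet.data_model import interactome_from_edges
from spanet.errors import ParameterError
from spanet.keyprot import (
    assemble_heart,
    decompose,
    global_importants,
    stepwise_keys,
)
from spanet.paths import enumerate_paths
from spanet.synthetic import corridor_fixture

from _oracles import all_simple_paths


def worked_example_frequencies():
    """40 proteins whose histogram is m=[30,6,1,1,1,1] over 6 bins.

    f_max = 60 so the equal-width bins are (0,10], (10,20], ..., (50,60].
    The hand computation gives M = [75, 90, 92.5, 95, 97.5, 100],
    D = [75, 15, 2.5, 2.5, 2.5, 2.5] and F = [5, 6, 1, 1, 1]; the largest
    fold change sits at bin 2 and exactly 4 proteins (10% of 40) lie above
    its upper edge, so those 4 are the key set.
    """
    freqs = {f"low{i:02d}": 5.0 for i in range(30)}
    freqs.update({f"mid{i}": 15.0 for i in range(6)})
    freqs.update({"hi1": 25.0, "hi2": 35.0, "hi3": 45.0, "hi4": 60.0})
    return freqs


class TestDecompose:
    def test_worked_example(self):
        dec = decompose(worked_example_frequencies())
        assert dec.n == 40 and dec.k == 6
        assert dec.m == (30, 6, 1, 1, 1, 1)
        assert dec.M == pytest.approx((75.0, 90.0, 92.5, 95.0, 97.5, 100.0))
        assert dec.F == pytest.approx((5.0, 6.0, 1.0, 1.0, 1.0))
        assert dec.threshold_bin == 2
        assert dec.key_set == {"hi1", "hi2", "hi3", "hi4"}
        assert not dec.fallback

    def test_cumulative_curve_well_formed(self):
        dec = decompose(worked_example_frequencies())
        assert sum(dec.m) == dec.n
        assert list(dec.M) == sorted(dec.M)
        assert dec.M[-1] == pytest.approx(100.0)

    def test_small_n_takes_empty_fallback(self):
        # n=4, k=2: bins (0,20], (20,40]; tail of bin 1 is 25% > 10%,
        # so no bin qualifies and floor(0.1*4)=0 keys are returned
        dec = decompose({"a": 10.0, "b": 10.0, "c": 10.0, "d": 40.0})
        assert dec.F == pytest.approx((3.0,))
        assert dec.fallback and dec.key_set == frozenset()

    def test_uniform_frequencies_degenerate_fallback(self):
        dec = decompose({f"p{i}": 50.0 for i in range(20)})
        assert dec.fallback
        assert dec.m[-1] == 20  # single occupied bin

    def test_rejects_empty_and_out_of_range(self):
        with pytest.raises(ParameterError):
            decompose({})
        with pytest.raises(ParameterError):
            decompose({"a": 0.0})
        with pytest.raises(ParameterError):
            decompose({"a": 101.0})

    def test_reciprocal_fold_mode_differs(self):
        dec = decompose(worked_example_frequencies(), fold="reciprocal")
        # reciprocal reading peaks where the curve steepens instead
        assert dec.F == pytest.approx((0.2, 1 / 6, 1.0, 1.0, 1.0))

    @settings(max_examples=50, deadline=None)
    @given(
        st.dictionaries(
            st.text(alphabet="abcdefgh", min_size=1, max_size=4),
            st.integers(min_value=1, max_value=100),
            min_size=1,
            max_size=60,
        ),
        st.sampled_from([0.5, 0.25]),
    )
    def test_scale_invariance(self, int_freqs, c):
        # the key set depends only on the rank-and-bin structure: an exact
        # rescaling of all frequencies preserves it
        freqs = {p: float(v) for p, v in int_freqs.items()}
        scaled = {p: v * c for p, v in freqs.items()}
        assert decompose(freqs).key_set == decompose(scaled).key_set

    @settings(max_examples=50, deadline=None)
    @given(
        st.dictionaries(
            st.text(alphabet="abcdefgh", min_size=1, max_size=4),
            st.floats(min_value=0.01, max_value=100.0),
            min_size=1,
            max_size=60,
        )
    )
    def test_ten_percent_bound_unless_fallback(self, freqs):
        dec = decompose(freqs)
        if not dec.fallback:
            import math

            assert len(dec.key_set) <= math.ceil(0.10 * dec.n)


class TestStepwiseKeys:
    @pytest.mark.parametrize("width,seed", [(2, 0), (2, 1), (3, 0)])
    def test_recovers_planted_backbone(self, width, seed):
        g, rec = corridor_fixture(corridor_width=width, seed=seed)
        spec = enumerate_paths(g, "INPUT", "OUTPUT", 6)
        res = stepwise_keys(spec)
        for i, b in enumerate(rec.backbone):
            assert b in res.steps[i].keys

    def test_single_path_degenerate_trail(self):
        g = nx.path_graph(["a", "b", "c", "d", "e", "f"])
        spec = enumerate_paths(g, "a", "f", 6)
        res = stepwise_keys(spec)
        assert [r.subset_size for r in res.steps] == [1, 1, 1, 1]
        assert all(r.decomposition.fallback for r in res.steps)

    def test_subset_sizes_nonincreasing(self):
        g, _ = corridor_fixture(corridor_width=3, seed=7)
        spec = enumerate_paths(g, "INPUT", "OUTPUT", 6)
        res = stepwise_keys(spec)
        sizes = [r.subset_size for r in res.steps]
        assert sizes == sorted(sizes, reverse=True)

    def test_empty_spectrum_rejected(self):
        g = interactome_from_edges([("a", "b")])
        g.add_node("z")
        spec = enumerate_paths(g, "a", "z", 6)
        with pytest.raises(ParameterError):
            stepwise_keys(spec)


class TestGlobalImportants:
    def test_backbone_among_importants(self):
        g, rec = corridor_fixture(corridor_width=2, seed=3)
        spec = enumerate_paths(g, "INPUT", "OUTPUT", 6)
        imp = global_importants(spec)
        assert set(rec.backbone) <= imp

    def test_endpoints_never_returned(self):
        g, _ = corridor_fixture(corridor_width=2, seed=3)
        spec = enumerate_paths(g, "INPUT", "OUTPUT", 6)
        for method in ("histogram", "top-fraction"):
            imp = global_importants(spec, method=method)
            assert "INPUT" not in imp and "OUTPUT" not in imp

    def test_uniform_spectrum_flagged_empty(self):
        g = nx.path_graph(["a", "b", "c", "d", "e", "f"])
        spec = enumerate_paths(g, "a", "f", 6)
        assert global_importants(spec) == frozenset()


class TestAssembleHeart:
    def _branch(self, width=2, seed=0):
        g, rec = corridor_fixture(corridor_width=width, seed=seed)
        spec = enumerate_paths(g, "INPUT", "OUTPUT", 6)
        return g, rec, spec, stepwise_keys(spec)

    def test_full_membership_covers_everything(self):
        g, _, spec, res = self._branch()
        # force the member set to the whole network via branches' keys
        class Full:
            def all_keys(self):
                return frozenset(g.nodes)

        heart = assemble_heart(
            {("INPUT", "OUTPUT"): Full()}, ["INPUT"], ["OUTPUT"], g,
            spectra={("INPUT", "OUTPUT"): spec},
        )
        assert heart.coverage[("INPUT", "OUTPUT")] == pytest.approx(100.0)

    def test_no_keys_means_no_covered_paths(self):
        g, _, spec, _ = self._branch()

        class Empty:
            def all_keys(self):
                return frozenset()

        heart = assemble_heart(
            {("INPUT", "OUTPUT"): Empty()}, ["INPUT"], ["OUTPUT"], g,
            spectra={("INPUT", "OUTPUT"): spec},
        )
        assert heart.members == {"INPUT", "OUTPUT"}
        assert heart.coverage[("INPUT", "OUTPUT")] == 0.0

    def test_coverage_matches_bruteforce_classification(self):
        g, rec, spec, res = self._branch(width=2, seed=5)
        heart = assemble_heart(
            {("INPUT", "OUTPUT"): res}, ["INPUT"], ["OUTPUT"], g,
            spectra={("INPUT", "OUTPUT"): spec},
        )
        adj = {v: set(g.neighbors(v)) for v in g.nodes}
        oracle_paths = all_simple_paths(adj, "INPUT", "OUTPUT", 6)
        members = heart.members
        inside = sum(
            1 for p in oracle_paths if all(v in members for v in p[1:-1])
        )
        assert heart.coverage[("INPUT", "OUTPUT")] == pytest.approx(
            100.0 * inside / len(oracle_paths)
        )
        assert heart.graph.number_of_nodes() == len(members)
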