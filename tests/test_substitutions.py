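import numpy as np
import pytest

from convloss import synthetic
from convloss import substitutions as sub
from convloss.errors import InvalidArgumentError
from convloss.mk import MarginalPosteriors
from convloss.trees import Phylogeny
from oracles import enumerate_aa_marginal_4tip


class TestMarginalASR:
    def test_invariant_column_confident_everywhere(self):
        t = synthetic.simulate_tree(12, seed=1, depth=0.2)
        msa = {n: "AAAA" for n in t.tip_names}
        post = sub.marginal_asr_aa(t, msa, sub.PoissonAAModel())
        a_idx = sub.AA_ALPHABET.index("A")
        assert np.all(post.probs[:, :, a_idx] > 0.99)

    def test_all_gap_column_uninformative(self):
        t = synthetic.simulate_tree(6, seed=2)
        msa = {n: "-" for n in t.tip_names}
        post = sub.marginal_asr_aa(t, msa, sub.PoissonAAModel())
        assert np.allclose(post.probs, 0.05, atol=1e-12)

    def test_matches_enumeration_on_4tip_instances(self, balanced_4tip):
        rng = np.random.default_rng(5)
        maxerr = 0.0
        for rep in range(10):
            bl = balanced_4tip.blen.copy()
            bl[1:] = rng.uniform(0.05, 0.8, size=6)
            t = Phylogeny(balanced_4tip.names, balanced_4tip.parent, bl)
            msa = {n: "".join(rng.choice(list(sub.AA_ALPHABET), 10))
                   for n in ["a", "b", "c", "d"]}
            model = sub.PoissonAAModel()
            post = sub.marginal_asr_aa(t, msa, model)
            brute = enumerate_aa_marginal_4tip(t, msa, model, sub.AA_ALPHABET)
            for node, expected in brute.items():
                got = post.probs[t.names.index(node)]
                maxerr = max(maxerr, np.abs(got - expected).max())
        assert maxerr < 1e-8

    def test_posteriors_sum_to_one(self):
        t = synthetic.simulate_tree(8, seed=3)
        rng = np.random.default_rng(0)
        msa = {n: "".join(rng.choice(list(sub.AA_ALPHABET), 20)) for n in t.tip_names}
        post = sub.marginal_asr_aa(t, msa)
        assert np.allclose(post.probs.sum(axis=2), 1.0, atol=1e-9)


class TestCallStates:
    def _posteriors(self, pvals):
        probs = np.zeros((1, len(pvals), 20))
        for i, p in enumerate(pvals):
            probs[0, i, 0] = p
            probs[0, i, 1:] = (1 - p) / 19
        return MarginalPosteriors(["n"], probs)

    def test_strict_threshold(self):
        calls = sub.call_states(self._posteriors([0.51, 0.50, 0.40]), threshold=0.5)
        assert calls.get("n", 1) == "A"
        assert calls.get("n", 2) == sub.UNCERTAIN
        assert calls.get("n", 3) == sub.UNCERTAIN

    def test_lower_threshold_never_uncalls(self):
        post = self._posteriors(np.linspace(0.2, 0.9, 15))
        high = sub.call_states(post, threshold=0.9)
        low = sub.call_states(post, threshold=0.5)
        assert low.n_called >= high.n_called


class TestMapSubstitutions:
    def _tiny(self):
        t = Phylogeny(["R", "x", "a", "b"], [-1, 0, 1, 1], [0, 0.1, 0.1, 0.1])
        return t

    def _calls(self, seqs):
        arr = np.array([list(s) for s in seqs])
        return sub.AncestralCalls(["R", "x"], arr, 0.5)

    def test_no_event_when_equal(self):
        t = self._tiny()
        calls = self._calls(["A", "A"])
        events, diag = sub.map_substitutions(t, calls, {"a": "A", "b": "A"})
        assert events == [] and diag["skipped_uncertain"] == 0

    def test_event_emitted_with_direction(self):
        t = self._tiny()
        calls = self._calls(["A", "A"])
        events, _ = sub.map_substitutions(t, calls, {"a": "V", "b": "A"})
        assert len(events) == 1
        ev = events[0]
        assert (ev.parent, ev.child, ev.site, ev.from_aa, ev.to_aa) == ("x", "a", 1, "A", "V")

    def test_uncertain_endpoint_skipped_and_counted(self):
        t = self._tiny()
        calls = self._calls(["A", "?"])
        events, diag = sub.map_substitutions(t, calls, {"a": "V", "b": "A"})
        # branches x->a and x->b and R->x all touch the uncertain node
        assert events == []
        assert diag["skipped_uncertain"] == 3

    def test_gap_tip_skipped(self):
        t = self._tiny()
        calls = self._calls(["A", "A"])
        events, diag = sub.map_substitutions(t, calls, {"a": "-", "b": "V"})
        assert len(events) == 1 and diag["skipped_gap"] == 1

    def test_event_total_equals_site_sums(self):
        sc = synthetic.simulate_two_clade_tree(n_clade_a=6, n_clade_f=6, seed=8)
        dm = synthetic.simulate_domain_msa(sc.tree, 60, 40, [sc.clade_a_tips], (5,), 3.0, seed=9)
        msa = {k: v[:60] for k, v in dm.alignment.items()}
        post = sub.marginal_asr_aa(sc.tree, msa)
        calls = sub.call_states(post)
        events, _ = sub.map_substitutions(sc.tree, calls, msa)
        enr = sub.site_fragment_ratio(events, set(), min_events=1)
        assert sum(e.total for e in enr) == len(events)


class TestEnrichment:
    def test_ratio_and_min_events_rule(self):
        evs = [sub.SubstitutionEvent("p", "c1", 7, "A", "V")] * 0
        mk_ev = lambda child, site: sub.SubstitutionEvent("p", child, site, "A", "V")
        frag = {("p", "f")}
        events = [mk_ev("f", 1)] * 4 + [mk_ev("o", 1)] * 1 + [mk_ev("o", 2)] * 4
        enr = sub.site_fragment_ratio(events, frag, min_events=5)
        assert len(enr) == 1
        assert enr[0].site == 1 and enr[0].total == 5 and np.isclose(enr[0].ratio, 0.8)

    def test_all_background_site_has_zero_ratio(self):
        mk_ev = lambda site: sub.SubstitutionEvent("p", "o", site, "A", "V")
        enr = sub.site_fragment_ratio([mk_ev(3)] * 6, {("p", "f")}, min_events=5)
        assert enr[0].ratio == 0.0

    def test_top_sites_ordering_and_ties(self):
        e = [
            sub.SiteEnrichment(1, 10, 8),   # 0.8, count 8
            sub.SiteEnrichment(2, 5, 4),    # 0.8, count 4
            sub.SiteEnrichment(3, 10, 9),   # 0.9
            sub.SiteEnrichment(4, 10, 2),   # 0.2
        ]
        assert sub.top_sites(e, k=3) == [3, 1, 2]
        assert sub.top_sites(e, k=15) == [3, 1, 2, 4]

    def test_fragment_branch_labelling_includes_stem(self):
        t = Phylogeny.from_newick("((f1:1,f2:1)fc:1,(o1:1,o2:1)oc:1)r;")
        fb = sub.fragment_branch_set(t, {"f1", "f2"})
        assert fb == {("r", "fc"), ("fc", "f1"), ("fc", "f2")}

    def test_group_enrichment_skips_small_groups(self):
        e = [sub.SiteEnrichment(i, 10, i % 5) for i in range(1, 12)]
        groups = {1: "tiny"}
        with pytest.warns(UserWarning):
            table = sub.group_enrichment(e, groups)
        assert table.empty or "tiny" not in set(table.group1) | set(table.group2)

    def test_planted_interface_recovery_single_seed(self):
        sc = synthetic.simulate_two_clade_tree(
            n_clade_a=16, n_clade_f=16, path_a_len=3, path_f_len=3, seed=0, clade_depth=0.7
        )
        interface = (10, 40, 70, 100, 130)
        dm = synthetic.simulate_domain_msa(
            sc.tree, 150, 100, [sc.clade_a_tips, sc.clade_f_tips],
            interface, 10.0, seed=100, base_rate=0.3,
        )
        msa = {k: v[:150] for k, v in dm.alignment.items()}
        post = sub.marginal_asr_aa(sc.tree, msa)
        calls = sub.call_states(post)
        events, _ = sub.map_substitutions(sc.tree, calls, msa)
        fb = sub.fragment_branch_set(sc.tree, sc.clade_a_tips | sc.clade_f_tips)
        enr = sub.site_fragment_ratio(events, fb, min_events=5)
        top = sub.top_sites(enr, k=15)
        assert all(s in top for s in interface)

    def test_null_configuration_indistinguishable(self):
        from convloss import stats as st

        sc = synthetic.simulate_two_clade_tree(n_clade_a=16, n_clade_f=16, seed=2,
                                               clade_depth=0.7)
        dm = synthetic.simulate_domain_msa(
            sc.tree, 200, 100, [sc.clade_a_tips, sc.clade_f_tips],
            tuple(range(1, 51)), 1.0, seed=9, base_rate=0.3,
        )
        msa = {k: v[:200] for k, v in dm.alignment.items()}
        post = sub.marginal_asr_aa(sc.tree, msa)
        calls = sub.call_states(post)
        events, _ = sub.map_substitutions(sc.tree, calls, msa)
        fb = sub.fragment_branch_set(sc.tree, sc.clade_a_tips | sc.clade_f_tips)
        enr = sub.site_fragment_ratio(events, fb, min_events=1)
        iface = [e.ratio for e in enr if e.site <= 50]
        other = [e.ratio for e in enr if e.site > 50]
        _, p = st.mann_whitney(iface, other)
        assert p > 0.01
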