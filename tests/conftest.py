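import numpy as np
import pytest

import clockdrift as cd


@pytest.fixture(scope="session")
def hky2():
    """HKY with equal frequencies and transition/transversion event ratio 2."""
    return cd.make_hky(ts_tv_ratio=2.0)


@pytest.fixture(scope="session")
def jc():
    return cd.make_jc()


@pytest.fixture
def two_taxon_tree():
    """Factory: two tips joined at the root, branch lengths (la, lb), root age in Myr."""

    def make(la, lb, root_age=1.0):
        return cd.DatedTree(
            [2, 2, -1], ["a", "b", None], ages=[0.0, 0.0, root_age],
            lengths=[la, lb, np.nan],
        )

    return make


@pytest.fixture
def four_taxon_tree():
    """Balanced 4-taxon ultrametric tree, every branch `length` subs/site over 1 Myr."""

    def make(length=0.1):
        tree = cd.DatedTree(
            [4, 4, 5, 5, 6, 6, -1],
            ["a", "b", "c", "d", None, None, None],
            ages=[0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 2.0],
            lengths=[length] * 6 + [np.nan],
        )
        tree._tag_root_clades()
        return tree

    return make


def enumeration_loglik(aln, tree, model):
    """Brute-force likelihood: sum over all ancestral state assignments."""
    tips = tree.tips
    internals = [n for n in range(tree.n_nodes) if tree.children[n]]
    pi = model.base_frequencies
    Ps = {
        n: model.transition_probabilities(tree.lengths[n])
        for n in range(tree.n_nodes)
        if tree.parent[n] >= 0
    }
    tip_rows = {n: aln.sites[aln.taxa.index(tree.labels[n])] for n in tips}
    total = 0.0
    for site in range(aln.n_sites):
        site_lik = 0.0
        for assign in np.ndindex(*(4,) * len(internals)):
            states = dict(zip(internals, assign))
            states.update({n: tip_rows[n][site] for n in tips})
            term = pi[states[tree.root]]
            for n in range(tree.n_nodes):
                if tree.parent[n] >= 0:
                    term *= Ps[n][states[tree.parent[n]], states[n]]
            site_lik += term
        total += np.log(site_lik)
    return total
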