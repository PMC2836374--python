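"""Clock-like sequence simulation along a dated tree.

Two samplers are provided. :func:`simulate_alignment` is the workhorse: it
draws the root sequence from the stationary frequencies and evolves each
branch site-wise through the finite-time transition matrix P(t), exactly as
Seq-Gen does. :func:`simulate_alignment_gillespie` is an exact event-level
simulation of the underlying continuous-time Markov chain; it is slower but
exposes the *realised* number of substitutions on every branch, which the
P(t) sampler integrates out. The two agree in distribution at the tips.
"""

from __future__ import annotations

import numpy as np

from .alignment import Alignment
from .substmodel import SubstitutionModel
from .trees import DatedTree

_MAX_EXPECTED_EVENTS = 1e8


def _sample_children(P_rows: np.ndarray, rng) -> np.ndarray:
    """Draw one categorical sample per row of an (n, 4) probability array."""
    cum = np.cumsum(P_rows, axis=1)
    u = rng.random(P_rows.shape[0]) * cum[:, -1]
    return (u[:, None] >= cum).sum(axis=1).astype(np.int8)


def simulate_alignment(
    tree: DatedTree,
    model: SubstitutionModel,
    n_sites: int,
    rng_seed,
    keep_ancestors: bool = False,
):
    """Simulate an alignment under the model along ``tree``.

    Deterministic given ``rng_seed``. Returns the tip alignment, or
    ``(alignment, ancestors)`` with per-node sequences when
    ``keep_ancestors`` is true.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be > 0")
    if tree.lengths is None:
        raise ValueError("tree has no branch lengths")
    rng = np.random.default_rng(rng_seed)
    mult = model.site_rate_multipliers(n_sites, rng)
    seqs = {tree.root: rng.choice(4, size=n_sites, p=model.base_frequencies).astype(np.int8)}
    uniform_rates = not model.has_site_rate_variation()
    for node in tree.preorder():
        if node == tree.root:
            continue
        parent_seq = seqs[tree.parent[node]]
        L = tree.lengths[node]
        child = np.empty(n_sites, dtype=np.int8)
        if uniform_rates:
            P = model.transition_probabilities(L)
            for s in range(4):
                mask = parent_seq == s
                n = int(mask.sum())
                if n:
                    child[mask] = rng.choice(4, size=n, p=P[s]).astype(np.int8)
        else:
            # per-site branch lengths; chunk to bound the (n,4,4) temporary
            for lo in range(0, n_sites, 100_000):
                hi = min(lo + 100_000, n_sites)
                P = model.transition_probabilities(L * mult[lo:hi])
                rows = P[np.arange(hi - lo), parent_seq[lo:hi]]
                child[lo:hi] = _sample_children(rows, rng)
        seqs[node] = child
    tips = tree.tips
    aln = Alignment(
        [tree.labels[t] for t in tips],
        np.vstack([seqs[t] for t in tips]),
        site_multipliers=mult,
    )
    if keep_ancestors:
        return aln, seqs
    return aln


def simulate_alignment_gillespie(
    tree: DatedTree,
    model: SubstitutionModel,
    n_sites: int,
    rng_seed,
):
    """Exact CTMC simulation; returns ``(alignment, per_branch_event_counts)``.

    ``per_branch_event_counts`` maps each non-root node to the realised
    number of substitution events on the branch above it (summed over
    sites). Under a clock these counts are Poisson with mean
    ``branch_length * n_sites``.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be > 0")
    if tree.lengths is None:
        raise ValueError("tree has no branch lengths")
    total_expected = np.nansum(tree.lengths) * n_sites
    if total_expected > _MAX_EXPECTED_EVENTS:
        raise ResourceWarning(
            f"~{total_expected:.2g} expected events exceeds the {_MAX_EXPECTED_EVENTS:.0g} guard"
        )
    rng = np.random.default_rng(rng_seed)
    Q = model.rate_matrix
    exit_rate = -np.diag(Q)
    jump = Q / exit_rate[:, None]
    np.fill_diagonal(jump, 0.0)
    jump_cum = np.cumsum(jump, axis=1)
    mult = model.site_rate_multipliers(n_sites, rng)

    seqs = {tree.root: rng.choice(4, size=n_sites, p=model.base_frequencies).astype(np.int8)}
    counts: dict[int, int] = {}
    for node in tree.preorder():
        if node == tree.root:
            continue
        state = seqs[tree.parent[node]].copy()
        remaining = tree.lengths[node] * mult  # per-site rate-scaled duration
        active = np.flatnonzero(remaining > 0)
        n_events = 0
        while active.size:
            waits = rng.exponential(1.0 / exit_rate[state[active]])
            jumped = waits < remaining[active]
            idx = active[jumped]
            n_events += idx.size
            if idx.size:
                u = rng.random(idx.size)
                state[idx] = (u[:, None] >= jump_cum[state[idx]]).sum(axis=1).astype(np.int8)
            remaining[active] -= waits
            active = idx
        seqs[node] = state
        counts[node] = n_events
    tips = tree.tips
    aln = Alignment(
        [tree.labels[t] for t in tips],
        np.vstack([seqs[t] for t in tips]),
        site_multipliers=mult,
    )
    return aln, counts
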