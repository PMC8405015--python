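"""Hypothesis strategies: random valid species networks."""

import string

import numpy as np
from hypothesis import strategies as st

from xenorisk.network import PhyloNetwork


def build_random_network(n_leaves: int, n_reticulations: int, seed: int,
                         with_theta: bool = False) -> PhyloNetwork:
    """A random ultrametric tree with up to ``n_reticulations`` horizontal
    transfer edges inserted at random times (fewer if no placement exists)."""
    rng = np.random.default_rng(seed)
    net = PhyloNetwork()
    active = [net.add_node(label=string.ascii_uppercase[i], age=0.0)
              for i in range(n_leaves)]
    t = 0.0
    while len(active) > 1:
        t += float(rng.exponential(0.7)) + 0.05
        i, j = rng.choice(len(active), size=2, replace=False)
        parent = net.add_node(age=t)
        for k in sorted((int(i), int(j)), reverse=True):
            net.add_edge(active[k], parent)
            del active[k]
        active.append(parent)
    net.root_id = active[0].id
    net.validate()
    for _ in range(n_reticulations):
        tr = float(rng.uniform(0.0, net.root.age))
        spanning = [e for e in net.edges()
                    if net.nodes[e.child].age < tr - 1e-3
                    and net.nodes[e.parent].age > tr + 1e-3]
        if len(spanning) < 2:
            continue
        di, si = rng.choice(len(spanning), size=2, replace=False)
        dest, src = spanning[int(di)], spanning[int(si)]
        gamma = float(rng.uniform(0.05, 0.95))
        ret = net.add_node(age=tr, tag=f"H{len(net.reticulations()) + 1}")
        mid = net.add_node(age=tr)
        for e, node in ((dest, ret), (src, mid)):
            child, parent = net.nodes[e.child], net.nodes[e.parent]
            net.remove_edge(e)
            # keep any inheritance probability on the segment entering the
            # original child (it may itself be a reticulation node)
            net.add_edge(child, node, gamma=e.gamma, secondary=e.secondary)
            net.add_edge(node, parent)
        net.add_edge(ret, mid, 0.0, gamma=gamma, secondary=True)
        ret.parent_edges[0].gamma = 1.0 - gamma
        net.validate()
    if with_theta:
        for e in net.edges():
            if rng.random() < 0.4:
                e.theta = float(rng.uniform(0.001, 0.05))
    return net


@st.composite
def random_networks(draw, max_leaves=5, max_reticulations=2,
                    with_theta=False):
    n = draw(st.integers(2, max_leaves))
    r = draw(st.integers(0, max_reticulations))
    seed = draw(st.integers(0, 10 ** 6))
    return build_random_network(n, r, seed, with_theta=with_theta)
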