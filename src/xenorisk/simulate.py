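"""Genealogy, trait and sequence simulation under the multispecies (network)
coalescent.

Time is measured in coalescent units of 2N generations throughout: within any
population (network edge) each pair of lineages coalesces at rate 1 per unit,
lineages arriving at a reticulation node choose a parent edge independently
with the edge's inheritance probability, and lineages that reach the network
root keep coalescing in the root population until a single ancestor remains.
Traits and sequences then evolve down the sampled genealogy: the binary trait
as a two-state chain with instantaneous rates ``theta*u`` (0->1) and
``theta*v`` (1->0), sequences under a GTR model whose per-unit-time scale
multiplies genealogy branch lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.linalg import expm

from .network import PhyloNetwork, NetworkError

__all__ = [
    "Genealogy",
    "SampleScheme",
    "GTRParams",
    "sample_genealogy",
    "sample_genealogies",
    "simulate_trait_on_genealogy",
    "simulate_sequences",
    "simulate_multilocus",
]

RngLike = Union[int, np.random.Generator, None]


def as_rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SampleScheme:
    """Number of sampled individuals per leaf species (each >= 1)."""

    counts: dict

    def __post_init__(self):
        for sp, k in self.counts.items():
            if int(k) < 1:
                raise ValueError(f"sample count for {sp!r} must be >= 1")

    @classmethod
    def from_spec(cls, spec) -> "SampleScheme":
        """Accept a dict, an existing scheme, or ``"A=1,B=10,C=1"``."""
        if isinstance(spec, SampleScheme):
            return spec
        if isinstance(spec, str):
            out = {}
            for part in spec.split(","):
                sp, _, k = part.partition("=")
                out[sp.strip()] = int(k) if k else 1
            return cls(out)
        return cls(dict(spec))

    def total(self) -> int:
        return int(sum(self.counts.values()))


class Genealogy:
    """Rooted binary gene tree over sampled individuals.

    Leaves are numbered ``0..n-1`` (grouped by species in sorted species
    order); internal nodes ``n..2n-2`` are the coalescences in age order, the
    last being the root.  ``leaf_labels[i]`` is a ``(species, index)`` pair.
    """

    def __init__(self, leaf_labels, coal_ages, children, theta=None):
        self.leaf_labels = list(leaf_labels)
        self.coal_ages = np.asarray(coal_ages, dtype=float)
        self.children = np.asarray(children, dtype=np.int64)
        self.theta = theta
        n = len(self.leaf_labels)
        if self.coal_ages.shape != (n - 1,) or self.children.shape != (n - 1, 2):
            raise ValueError("inconsistent genealogy arrays")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    def node_age(self, i: int) -> float:
        n = self.n_leaves
        return 0.0 if i < n else float(self.coal_ages[i - n])

    def branch_length(self, child: int) -> float:
        """Length of the branch above node ``child``."""
        n = self.n_leaves
        parents = self.parent_map()
        return self.node_age(parents[child]) - self.node_age(child)

    def parent_map(self) -> np.ndarray:
        n = self.n_leaves
        par = np.full(self.n_nodes, -1, dtype=np.int64)
        for j in range(n - 1):
            par[self.children[j, 0]] = n + j
            par[self.children[j, 1]] = n + j
        return par

    def leaves_under(self, i: int) -> frozenset:
        n = self.n_leaves
        if i < n:
            return frozenset([i])
        j = i - n
        return self.leaves_under(int(self.children[j, 0])) | \
            self.leaves_under(int(self.children[j, 1]))

    def newick(self) -> str:
        n = self.n_leaves

        def render(i):
            if i < n:
                sp, idx = self.leaf_labels[i]
                return f"{sp}_{idx}", 0.0
            j = i - n
            parts = []
            for c in self.children[j]:
                s, age = render(int(c))
                parts.append(f"{s}:{self.coal_ages[j] - age:.10g}")
            return "(" + ",".join(parts) + ")", float(self.coal_ages[j])

        s, _ = render(self.n_nodes - 1)
        return s + ";"

    def topology_key(self) -> tuple:
        """Canonical label-based topology (ignores branch lengths)."""
        n = self.n_leaves

        def key(i):
            if i < n:
                sp, idx = self.leaf_labels[i]
                return (f"{sp}_{idx}",)
            j = i - n
            return tuple(sorted((key(int(self.children[j, 0])),
                                 key(int(self.children[j, 1])))))

        return key(self.n_nodes - 1)

    def __repr__(self):
        return f"Genealogy({self.newick()})"


class _Draws:
    """Blocked RNG draws to amortize Generator call overhead."""

    def __init__(self, rng: np.random.Generator, block=8192):
        self.rng = rng
        self.block = block
        self._exp = rng.exponential(size=block)
        self._uni = rng.random(size=block)
        self._ei = 0
        self._ui = 0

    def exp(self) -> float:
        if self._ei >= self.block:
            self._exp = self.rng.exponential(size=self.block)
            self._ei = 0
        v = self._exp[self._ei]
        self._ei += 1
        return v

    def unif(self) -> float:
        if self._ui >= self.block:
            self._uni = self.rng.random(size=self.block)
            self._ui = 0
        v = self._uni[self._ui]
        self._ui += 1
        return v


class _NetIndex:
    """Preprocessed event schedule for repeated genealogy sampling."""

    def __init__(self, net: PhyloNetwork, scheme: SampleScheme):
        net = net.copy()
        net.validate()
        self.net = net
        species = net.leaf_labels()
        missing = set(scheme.counts) - set(species)
        if missing:
            raise NetworkError(f"species in scheme absent from network: "
                               f"{sorted(missing)}")
        absent = set(species) - set(scheme.counts)
        if absent:
            raise NetworkError(f"scheme does not cover species: {sorted(absent)}")
        # leaves grouped by species in sorted order
        self.leaf_labels = []
        self.leaf_range = {}
        for sp in sorted(species):
            k = int(scheme.counts[sp])
            start = len(self.leaf_labels)
            self.leaf_labels += [(sp, i) for i in range(k)]
            self.leaf_range[sp] = (start, start + k)
        self.n = len(self.leaf_labels)
        # topological order (children before parents), stably sorted by age
        order, indeg = [], {}
        for node in net.nodes.values():
            indeg[node.id] = len(node.child_edges)
        stack = [nid for nid, d in indeg.items() if d == 0]
        while stack:
            nid = stack.pop()
            order.append(nid)
            for e in net.nodes[nid].parent_edges:
                indeg[e.parent] -= 1
                if indeg[e.parent] == 0:
                    stack.append(e.parent)
        order.sort(key=lambda nid: net.nodes[nid].age)  # stable
        self.schedule = [net.nodes[nid] for nid in order]


def _coalesce(lst, t, t1, k, n, coal_ages, children, draws):
    """Coalesce lineages in ``lst`` from time ``t`` to ``t1``; returns new k."""
    kk = len(lst)
    while kk >= 2:
        t += draws.exp() * 2.0 / (kk * (kk - 1))
        if t >= t1:
            break
        i = int(draws.unif() * kk)
        j = int(draws.unif() * (kk - 1))
        if j >= i:
            j += 1
        coal_ages[k] = t
        children[k, 0] = lst[i]
        children[k, 1] = lst[j]
        lst[i] = n + k
        lst[j] = lst[kk - 1]
        del lst[kk - 1]
        kk -= 1
        k += 1
    return k


def _sample_one(idx: _NetIndex, coal_ages, children, draws):
    net, n = idx.net, idx.n
    pop: dict[int, list] = {}
    k = 0
    for node in idx.schedule:
        if node.is_leaf:
            lo, hi = idx.leaf_range[node.label]
            lineages = list(range(lo, hi))
        else:
            lineages = []
            for e in node.child_edges:
                lst = pop.pop(e.id, [])
                if len(lst) >= 2:
                    k = _coalesce(lst, net.nodes[e.child].age, node.age,
                                  k, n, coal_ages, children, draws)
                lineages.extend(lst)
        if not node.parent_edges:  # network root
            k = _coalesce(lineages, node.age, math.inf, k, n,
                          coal_ages, children, draws)
        elif len(node.parent_edges) == 2:
            e1, e2 = node.parent_edges
            g = e1.gamma
            for lin in lineages:
                target = e1 if draws.unif() < g else e2
                pop.setdefault(target.id, []).append(lin)
        else:
            pop[node.parent_edges[0].id] = lineages
    return k


def sample_genealogies(net: PhyloNetwork, scheme, n_genealogies: int,
                       rng_seed: RngLike = None):
    """Sample raw genealogy arrays: ``(leaf_labels, coal_ages, children)``.

    ``coal_ages`` has shape ``(m, n-1)`` (sorted increasing per row, the last
    column being the root age) and ``children`` shape ``(m, n-1, 2)``.
    """
    scheme = SampleScheme.from_spec(scheme)
    idx = _NetIndex(net, scheme)
    rng = as_rng(rng_seed)
    draws = _Draws(rng)
    m, n = int(n_genealogies), idx.n
    coal_ages = np.empty((m, n - 1), dtype=float)
    children = np.empty((m, n - 1, 2), dtype=np.int64)
    for r in range(m):
        k = _sample_one(idx, coal_ages[r], children[r], draws)
        assert k == n - 1
    return idx.leaf_labels, coal_ages, children


def sample_genealogy(net: PhyloNetwork, scheme, theta_default=None,
                     rng_seed: RngLike = None) -> Genealogy:
    """Sample one genealogy of the individuals in ``scheme`` under the
    multispecies (network) coalescent on ``net``."""
    labels, ages, children = sample_genealogies(net, scheme, 1, rng_seed)
    return Genealogy(labels, ages[0], children[0], theta=theta_default)


# ---------------------------------------------------------------------------
# trait simulation
# ---------------------------------------------------------------------------

def simulate_trait_on_genealogy(gen: Genealogy, model, rng_seed: RngLike = None,
                                theta=None, root_state=None) -> np.ndarray:
    """Evolve a binary trait down a genealogy; returns one state per leaf.

    The root state is drawn from the stationary distribution
    ``(pi0, pi1) = (v, u)/(u+v)`` unless ``root_state`` is forced; along each
    branch of length t the state flips by the two-state chain with rates
    ``theta*u`` (0->1) and ``theta*v`` (1->0).
    """
    from .likelihood import transition_matrix  # local import, no cycle at runtime

    rng = as_rng(rng_seed)
    th = theta if theta is not None else model.theta
    if th is None:
        raise ValueError("theta must be given (argument or model default)")
    n = gen.n_leaves
    states = np.empty(gen.n_nodes, dtype=np.int8)
    pi = model.stationary()
    states[-1] = root_state if root_state is not None \
        else int(rng.random() < pi[1])
    for j in range(n - 2, -1, -1):
        node = n + j
        for c in gen.children[j]:
            c = int(c)
            t = gen.coal_ages[j] - gen.node_age(c)
            p = transition_matrix(model, t, th)
            states[c] = int(rng.random() < p[states[node], 1])
    return states[:n].copy()


# ---------------------------------------------------------------------------
# sequence simulation
# ---------------------------------------------------------------------------

_BASES = "ACGT"


@dataclass(frozen=True)
class GTRParams:
    """GTR substitution model: base frequencies (A,C,G,T), six exchangeability
    rates (AC, AG, AT, CG, CT, GT) and a per-coalescent-unit branch scale."""

    freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    rates: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    scale: float = 1.0

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        if f.shape != (4,) or abs(f.sum() - 1.0) > 1e-10:
            raise ValueError("base frequencies must be 4 values summing to 1")
        if r.shape != (6,) or np.any(r <= 0) or np.any(f <= 0) or self.scale < 0:
            raise ValueError("GTR rates/frequencies must be positive")

    def rate_matrix(self) -> np.ndarray:
        """Instantaneous rate matrix normalized to one expected substitution
        per unit time at stationarity."""
        f = np.asarray(self.freqs, dtype=float)
        ac, ag, at, cg, ct, gt = self.rates
        s = np.array([[0, ac, ag, at],
                      [ac, 0, cg, ct],
                      [ag, cg, 0, gt],
                      [at, ct, gt, 0]], dtype=float)
        q = s * f[None, :]
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(f * np.diag(q)).sum()
        return q / mu


def simulate_sequences(gen: Genealogy, gtr: GTRParams, length: int,
                       rng_seed: RngLike = None) -> MultipleSeqAlignment:
    """Simulate an alignment of i.i.d. sites under GTR along a genealogy.

    Branch lengths (coalescent units) are multiplied by ``gtr.scale`` to give
    expected substitutions per site.
    """
    if length <= 0:
        raise ValueError("alignment length must be positive")
    rng = as_rng(rng_seed)
    q = gtr.rate_matrix()
    f = np.asarray(gtr.freqs, dtype=float)
    n = gen.n_leaves
    seqs = [None] * gen.n_nodes
    seqs[-1] = rng.choice(4, size=length, p=f)
    for j in range(n - 2, -1, -1):
        parent_seq = seqs[n + j]
        for c in gen.children[j]:
            c = int(c)
            t = (gen.coal_ages[j] - gen.node_age(c)) * gtr.scale
            if t == 0:
                seqs[c] = parent_seq.copy()
                continue
            p = expm(q * t)
            cdf = np.cumsum(p, axis=1)
            u = rng.random(length)
            seqs[c] = (u[:, None] > cdf[parent_seq]).sum(axis=1)
    records = []
    for i, (sp, idx) in enumerate(gen.leaf_labels):
        s = "".join(_BASES[b] for b in seqs[i])
        records.append(SeqRecord(Seq(s), id=f"{sp}_{idx}", description=""))
    return MultipleSeqAlignment(records)


def simulate_multilocus(net: PhyloNetwork, loci: int, scheme, theta,
                        gtr: GTRParams, length: int,
                        rng_seed: RngLike = None):
    """Sample ``loci`` genealogies and one GTR alignment per genealogy.

    Returns a list of ``(Genealogy, MultipleSeqAlignment)`` pairs.  Per-locus
    RNG substreams are spawned deterministically from ``rng_seed`` so a fixed
    seed reproduces the output byte for byte.
    """
    if loci < 0:
        raise ValueError("loci must be >= 0")
    base = rng_seed if isinstance(rng_seed, (int, np.integer)) or rng_seed is None \
        else int(as_rng(rng_seed).integers(2 ** 31))
    ss = np.random.SeedSequence(base)
    out = []
    for child in ss.spawn(int(loci)):
        rng = np.random.default_rng(child)
        gen = sample_genealogy(net, scheme, theta_default=theta, rng_seed=rng)
        aln = simulate_sequences(gen, gtr, length, rng_seed=rng)
        out.append((gen, aln))
    return out
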