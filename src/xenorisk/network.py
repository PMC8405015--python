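"""Rooted phylogenetic networks with node ages in coalescent units.

A :class:`PhyloNetwork` is a rooted, binary, time-consistent network: every
node carries an age (leaves at age 0, in units of 2N generations), every edge
a non-negative length equal to the parent/child age difference, and each
reticulation node has two parent edges whose inheritance probabilities
(``gamma``) sum to one.  A network with no reticulations is an ordinary
ultrametric species tree, and all operations degenerate accordingly.

I/O uses the rich-Newick dialect in which a reticulation node is tagged
``#H<k>`` at exactly two places in the string, and the inheritance probability
is the third colon-separated field on a reticulation edge
(``name:length:support:gamma``; the support field is ignored).  An optional
per-edge population mutation rate may be attached as a ``[&theta=x]`` comment
after the branch fields.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Optional

__all__ = [
    "PhyloNetwork",
    "NetworkError",
    "Edge",
    "Node",
    "DisplayedTree",
    "parse_extended_newick",
    "write_extended_newick",
    "displayed_trees",
    "major_tree",
    "backbone_tree",
    "network_signature",
]

_AGE_TOL = 1e-8


class NetworkError(ValueError):
    """Raised for malformed Newick strings or invalid network structure."""


class Edge:
    """Directed child -> parent edge; ``gamma`` is set on reticulation edges only."""

    __slots__ = ("id", "child", "parent", "length", "gamma", "theta", "secondary")

    def __init__(self, eid, child, parent, length, gamma=None, theta=None,
                 secondary=False):
        self.id = eid
        self.child = child
        self.parent = parent
        self.length = length
        self.gamma = gamma
        self.theta = theta
        # True for the edge written as a bare #H reference in source text;
        # used only as the deterministic tie-break when gamma == 0.5.
        self.secondary = secondary

    def __repr__(self):  # pragma: no cover - debugging aid
        g = f", gamma={self.gamma}" if self.gamma is not None else ""
        return f"Edge({self.child}->{self.parent}, len={self.length:g}{g})"


class Node:
    __slots__ = ("id", "label", "age", "child_edges", "parent_edges", "tag")

    def __init__(self, nid, label=None, age=None, tag=None):
        self.id = nid
        self.label = label
        self.age = age
        self.child_edges: list[Edge] = []
        self.parent_edges: list[Edge] = []
        self.tag = tag  # '#H' tag for reticulation nodes

    @property
    def is_leaf(self):
        return not self.child_edges

    @property
    def is_reticulation(self):
        return len(self.parent_edges) == 2

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Node({self.id}, label={self.label!r}, age={self.age})"


class PhyloNetwork:
    """Mutable rooted network; see module docstring for invariants."""

    def __init__(self):
        self.nodes: dict[int, Node] = {}
        self.root_id: Optional[int] = None
        self._next_node = 0
        self._next_edge = 0

    # -- construction -----------------------------------------------------
    def add_node(self, label=None, age=None, tag=None) -> Node:
        n = Node(self._next_node, label=label, age=age, tag=tag)
        self.nodes[n.id] = n
        self._next_node += 1
        return n

    def add_edge(self, child: Node, parent: Node, length=None, gamma=None,
                 theta=None, secondary=False) -> Edge:
        if length is None:
            if child.age is None or parent.age is None:
                raise NetworkError("edge needs a length or both node ages")
            length = parent.age - child.age
        e = Edge(self._next_edge, child.id, parent.id, float(length),
                 gamma=gamma, theta=theta, secondary=secondary)
        self._next_edge += 1
        child.parent_edges.append(e)
        parent.child_edges.append(e)
        return e

    def remove_edge(self, e: Edge):
        self.nodes[e.child].parent_edges.remove(e)
        self.nodes[e.parent].child_edges.remove(e)

    # -- views ------------------------------------------------------------
    @property
    def root(self) -> Node:
        return self.nodes[self.root_id]

    def leaves(self) -> list[Node]:
        return sorted((n for n in self.nodes.values() if n.is_leaf),
                      key=lambda n: (n.label is None, n.label))

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def reticulations(self) -> list[Node]:
        out = [n for n in self.nodes.values() if n.is_reticulation]
        out.sort(key=lambda n: (n.age, n.tag or "", n.id))
        return out

    def edges(self) -> Iterator[Edge]:
        for n in self.nodes.values():
            yield from n.child_edges

    @property
    def is_tree(self) -> bool:
        return not any(n.is_reticulation for n in self.nodes.values())

    def node_by_label(self, label) -> Node:
        for n in self.nodes.values():
            if n.label == label:
                return n
        raise KeyError(label)

    def leaves_below(self, node: Node) -> frozenset:
        """Set of leaf labels reachable leafward from ``node``."""
        seen, stack, out = set(), [node.id], []
        while stack:
            nid = stack.pop()
            if nid in seen:
                continue
            seen.add(nid)
            n = self.nodes[nid]
            if n.is_leaf:
                out.append(n.label)
            stack.extend(e.child for e in n.child_edges)
        return frozenset(out)

    # -- validation -------------------------------------------------------
    def validate(self):
        roots = [n for n in self.nodes.values() if not n.parent_edges]
        if len(roots) != 1:
            raise NetworkError(f"expected exactly one root, found {len(roots)}")
        self.root_id = roots[0].id
        labels = [n.label for n in self.nodes.values() if n.is_leaf]
        if any(l is None for l in labels):
            raise NetworkError("every leaf must carry a label")
        if len(set(labels)) != len(labels):
            raise NetworkError("duplicate leaf labels")
        for n in self.nodes.values():
            np_ = len(n.parent_edges)
            if n.id != self.root_id and np_ not in (1, 2):
                raise NetworkError(f"node {n.id} has {np_} parents")
            if np_ == 2:
                gammas = [e.gamma for e in n.parent_edges]
                if any(g is None for g in gammas):
                    raise NetworkError(
                        "reticulation edges must carry inheritance probabilities")
                if not all(-1e-12 <= g <= 1 + 1e-12 for g in gammas):
                    raise NetworkError("inheritance probability outside [0, 1]")
                if abs(sum(gammas) - 1.0) > 1e-8:
                    raise NetworkError(
                        f"inheritance probabilities sum to {sum(gammas)}, not 1")
        for e in self.edges():
            if e.length < -1e-12:
                raise NetworkError("negative branch length")
            pa = self.nodes[e.parent].age
            ca = self.nodes[e.child].age
            if pa is not None and ca is not None:
                if pa < ca - _AGE_TOL:
                    raise NetworkError("parent younger than child")
                if abs((pa - ca) - e.length) > _AGE_TOL * max(1.0, abs(pa)):
                    raise NetworkError(
                        "edge length inconsistent with node ages "
                        f"({e.length} vs {pa - ca})")
        return self

    def assign_ages(self):
        """Compute node ages bottom-up from edge lengths (leaves at age 0)."""
        for n in self.nodes.values():
            n.age = 0.0 if n.is_leaf else None
        pending = True
        while pending:
            pending = False
            progressed = False
            for n in self.nodes.values():
                if n.age is not None:
                    continue
                ages = []
                ok = True
                for e in n.child_edges:
                    c = self.nodes[e.child]
                    if c.age is None:
                        ok = False
                        break
                    ages.append(c.age + e.length)
                if not ok:
                    pending = True
                    continue
                if max(ages) - min(ages) > _AGE_TOL * max(1.0, max(ages)):
                    raise NetworkError(
                        "branch lengths are not time-consistent "
                        f"(node age candidates {ages})")
                n.age = ages[0]
                progressed = True
            if pending and not progressed:
                raise NetworkError("cycle detected while assigning ages")
        return self

    # -- copying ----------------------------------------------------------
    def copy(self) -> "PhyloNetwork":
        out = PhyloNetwork()
        mapping = {}
        for nid in sorted(self.nodes):
            n = self.nodes[nid]
            mapping[nid] = out.add_node(label=n.label, age=n.age, tag=n.tag)
        for e in sorted(self.edges(), key=lambda e: e.id):
            out.add_edge(mapping[e.child], mapping[e.parent], e.length,
                         gamma=e.gamma, theta=e.theta, secondary=e.secondary)
        out.root_id = mapping[self.root_id].id if self.root_id is not None else None
        return out

    def __repr__(self):
        try:
            return f"PhyloNetwork({write_extended_newick(self)})"
        except Exception:  # pragma: no cover
            return f"PhyloNetwork(<{len(self.nodes)} nodes>)"


@dataclass
class DisplayedTree:
    """One tree displayed by a network, with its mixture weight.

    ``choices`` maps each reticulation tag (or node id) of the source network
    to the edge id of the retained parent edge.
    """

    tree: PhyloNetwork
    weight: float
    choices: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# rich Newick parsing
# ---------------------------------------------------------------------------

def _tokenize(text: str):
    specials = "(),;"
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
        elif c in specials or c == ":":
            yield c
            i += 1
        elif c == "[":
            j = text.find("]", i)
            if j < 0:
                raise NetworkError("unterminated [] comment")
            yield text[i:j + 1]
            i = j + 1
        else:
            j = i
            while j < n and text[j] not in specials + ":[" and not text[j].isspace():
                j += 1
            yield text[i:j]
            i = j


class _Parser:
    def __init__(self, text):
        self.tokens = list(_tokenize(text))
        self.pos = 0
        self.net = PhyloNetwork()
        self.hybrids: dict[str, list] = {}

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self):
        t = self.peek()
        if t is None:
            raise NetworkError("unexpected end of Newick string")
        self.pos += 1
        return t

    def parse(self) -> PhyloNetwork:
        top = self.parse_clade()
        if self.peek() == ";":
            self.take()
        if self.pos != len(self.tokens):
            raise NetworkError(f"trailing tokens after ';': {self.tokens[self.pos:]}")
        node, fields = top
        if fields["length"] is not None:
            raise NetworkError("root must not carry a branch length")
        self._resolve_hybrids()
        self.net.root_id = node.id
        self.net.assign_ages()
        return self.net.validate()

    def parse_clade(self):
        children = []
        if self.peek() == "(":
            self.take()
            children.append(self.parse_clade())
            while self.peek() == ",":
                self.take()
                children.append(self.parse_clade())
            if self.take() != ")":
                raise NetworkError("expected ')'")
        name, tag = self._parse_name()
        fields = self._parse_fields()
        if tag is not None:
            entry = {"name": name, "children": children, "fields": fields,
                     "parents": []}
            self.hybrids.setdefault(tag, []).append(entry)
            return ("#", entry), fields
        if not children and name is None:
            raise NetworkError("unlabeled leaf")
        node = self.net.add_node(label=name if not children else None)
        if children and name is not None:
            # interior labels are allowed but not structural; keep as tag-less
            pass
        self._attach(node, children)
        return node, fields

    def _attach(self, node, children):
        for child, cf in children:
            if isinstance(child, tuple) and child[0] == "#":
                # hybrid occurrence: edge added later in _resolve_hybrids
                child[1]["parents"].append((node, cf))
                continue
            self._add_edge(child, node, cf)

    def _add_edge(self, child, parent, fields, secondary=False):
        if fields["length"] is None:
            raise NetworkError(
                f"missing branch length on edge above node {child.label or child.id}")
        if fields["length"] < 0:
            raise NetworkError("negative branch length")
        g = fields["gamma"]
        if g is not None and not (0.0 <= g <= 1.0):
            raise NetworkError(f"inheritance probability {g} outside [0, 1]")
        self.net.add_edge(child, parent, fields["length"], gamma=g,
                          theta=fields["theta"], secondary=secondary)

    def _parse_name(self):
        t = self.peek()
        if t is None or t in "(),;:" or t.startswith("["):
            return None, None
        self.take()
        if "#" in t:
            base, _, tag = t.partition("#")
            if not tag:
                raise NetworkError(f"empty hybrid tag in {t!r}")
            return (base or None), tag
        return t, None

    def _parse_fields(self):
        out = {"length": None, "support": None, "gamma": None, "theta": None}
        slots = ["length", "support", "gamma"]
        i = 0
        while self.peek() == ":":
            self.take()
            if i >= len(slots):
                raise NetworkError("too many ':' fields")
            t = self.peek()
            if t is not None and not t.startswith("[") and t not in "(),;:":
                self.take()
                try:
                    out[slots[i]] = float(t)
                except ValueError as exc:
                    raise NetworkError(f"bad numeric field {t!r}") from exc
            i += 1
        t = self.peek()
        if t is not None and t.startswith("[&"):
            self.take()
            body = t[2:-1]
            for part in body.split(","):
                k, _, v = part.partition("=")
                if k.strip() == "theta":
                    try:
                        out["theta"] = float(v)
                    except ValueError as exc:
                        raise NetworkError(f"bad theta comment {t!r}") from exc
        return out

    def _resolve_hybrids(self):
        plan = []
        for tag, occ in self.hybrids.items():
            if len(occ) != 2:
                raise NetworkError(
                    f"hybrid tag #{tag} appears {len(occ)} times, expected 2")
            defs = [o for o in occ if o["children"]]
            if len(defs) > 1:
                raise NetworkError(f"hybrid tag #{tag} defined twice")
            definition = defs[0] if defs else occ[0]
            node = self.net.add_node(tag=tag)
            plan.append((tag, occ, definition, node))
        # attach children first: this may register parents on *other* hybrids,
        # so parent edges are added only afterwards
        for tag, occ, definition, node in plan:
            self._attach(node, definition["children"])
        for tag, occ, definition, node in plan:
            gammas, edges = [], []
            for o in occ:
                for parent, fields in o["parents"]:
                    self._add_edge(node, parent, fields,
                                   secondary=not o["children"])
                    edges.append(node.parent_edges[-1])
                    gammas.append(fields["gamma"])
            if len(edges) != 2:
                raise NetworkError(f"hybrid #{tag} must have exactly 2 parents")
            given = [g for g in gammas if g is not None]
            if not given:
                raise NetworkError(
                    f"no inheritance probability given for hybrid #{tag}")
            if len(given) == 1:
                for e in edges:
                    if e.gamma is None:
                        e.gamma = 1.0 - given[0]


def parse_extended_newick(text: str) -> PhyloNetwork:
    """Parse a (rich) Newick string into a validated :class:`PhyloNetwork`.

    Plain Newick trees are accepted; single-node inputs like ``"A;"`` yield a
    one-leaf network (useful as a single panmictic population).
    """
    text = text.strip()
    if not text:
        raise NetworkError("empty Newick string")
    return _Parser(text).parse()


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def write_extended_newick(net: PhyloNetwork) -> str:
    """Serialize a network to rich Newick (round-trips through the parser)."""
    tags = {}
    for i, r in enumerate(net.reticulations(), start=1):
        tags[r.id] = r.tag or f"H{i}"

    def fields(e: Edge) -> str:
        s = f":{_fmt(e.length)}"
        if e.gamma is not None:
            s += f"::{_fmt(e.gamma)}"
        if e.theta is not None:
            s += f"[&theta={_fmt(e.theta)}]"
        return s

    def embed_edge(node: Node) -> Edge:
        """Pick the parent edge under which a reticulation node is written out."""
        prim = [e for e in node.parent_edges if not e.secondary]
        return prim[0] if prim else node.parent_edges[0]

    def render(node: Node, via: Optional[Edge]) -> str:
        if node.id in tags and via is not None and via is not embed_edge(node):
            return f"#{tags[node.id]}{fields(via)}"
        parts = []
        for e in sorted(node.child_edges, key=lambda e: e.id):
            parts.append(render(net.nodes[e.child], e))
        if parts:
            body = "(" + ",".join(parts) + ")"
        else:
            body = node.label or ""
        if node.id in tags:
            body += f"#{tags[node.id]}"
        if via is not None:
            body += fields(via)
        return body

    return render(net.root, None) + ";"


# ---------------------------------------------------------------------------
# displayed trees / major tree / backbone
# ---------------------------------------------------------------------------

def _cleanup(net: PhyloNetwork) -> PhyloNetwork:
    """Prune childless interior nodes, suppress degree-2 nodes, trim the root."""
    changed = True
    while changed:
        changed = False
        for n in list(net.nodes.values()):
            if n.id not in net.nodes:
                continue
            if n.is_leaf and n.label is None:
                for e in list(n.parent_edges):
                    net.remove_edge(e)
                del net.nodes[n.id]
                changed = True
            elif len(n.child_edges) == 1 and len(n.parent_edges) == 1:
                ce, pe = n.child_edges[0], n.parent_edges[0]
                child, parent = net.nodes[ce.child], net.nodes[pe.parent]
                net.remove_edge(ce)
                net.remove_edge(pe)
                theta = None
                if ce.theta is not None or pe.theta is not None:
                    tl = (ce.theta or 0.0) * ce.length + (pe.theta or 0.0) * pe.length
                    tot = ce.length + pe.length
                    theta = tl / tot if tot > 0 else (ce.theta
                                                      if ce.theta is not None
                                                      else pe.theta)
                net.add_edge(child, parent, ce.length + pe.length,
                             gamma=pe.gamma, theta=theta, secondary=pe.secondary)
                del net.nodes[n.id]
                changed = True
            elif len(n.child_edges) == 1 and not n.parent_edges:
                # root left with a single child: the child becomes the root
                ce = n.child_edges[0]
                net.remove_edge(ce)
                del net.nodes[n.id]
                net.root_id = ce.child
                changed = True
    roots = [n for n in net.nodes.values() if not n.parent_edges]
    net.root_id = roots[0].id
    return net


def displayed_trees(net: PhyloNetwork) -> list[DisplayedTree]:
    """All ``2^r`` trees displayed by a network, with gamma-product weights.

    Each entry corresponds to one choice of retained parent edge per
    reticulation; degree-2 nodes created by the deletion are suppressed with
    lengths merged additively.  Weights sum to one.
    """
    net = net.copy()
    net.validate()
    rets = net.reticulations()
    if not rets:
        return [DisplayedTree(net.copy(), 1.0, {})]
    out = []
    for keep in itertools.product(*[r.parent_edges for r in rets]):
        t = net.copy()
        weight = 1.0
        choices = {}
        for r, e in zip(rets, keep):
            weight *= e.gamma
            choices[r.tag or r.id] = e.id
            node = t.nodes[r.id]
            for pe in list(node.parent_edges):
                if pe.id != e.id:
                    t.remove_edge(pe)
            node.parent_edges[0].gamma = None
        _cleanup(t)
        t.validate()
        out.append(DisplayedTree(t, weight, choices))
    return out


def _select_edges(net: PhyloNetwork, choice) -> dict:
    """Resolve a backbone selector into {ret node id: kept parent edge}."""
    kept = {}
    for r in net.reticulations():
        e1, e2 = r.parent_edges
        if choice == "major":
            if abs(e1.gamma - e2.gamma) < 1e-12:
                pick = e1 if not e1.secondary else e2
            else:
                pick = e1 if e1.gamma > e2.gamma else e2
        elif choice == "minor":
            if abs(e1.gamma - e2.gamma) < 1e-12:
                pick = e1 if e1.secondary else e2
            else:
                pick = e1 if e1.gamma < e2.gamma else e2
        elif choice == "primary":
            pick = e1 if not e1.secondary else e2
        elif choice == "secondary":
            pick = e1 if e1.secondary else e2
        elif isinstance(choice, dict):
            key = r.tag if r.tag in choice else r.id
            if key not in choice:
                raise NetworkError(f"selector missing reticulation {r.tag or r.id}")
            sel = choice[key]
            if sel in ("major", "minor", "primary", "secondary"):
                kept.update(_select_edges_single(r, sel))
                continue
            matches = [e for e in r.parent_edges if e.id == sel]
            if not matches:
                raise NetworkError(f"selector names edge {sel!r} not entering "
                                   f"reticulation {r.tag or r.id}")
            pick = matches[0]
        else:
            raise NetworkError(f"unknown backbone selector {choice!r}")
        kept[r.id] = pick
    return kept


def _select_edges_single(r: Node, choice: str) -> dict:
    e1, e2 = r.parent_edges
    if choice == "major":
        pick = (e1 if not e1.secondary else e2) if abs(e1.gamma - e2.gamma) < 1e-12 \
            else (e1 if e1.gamma > e2.gamma else e2)
    elif choice == "minor":
        pick = (e1 if e1.secondary else e2) if abs(e1.gamma - e2.gamma) < 1e-12 \
            else (e1 if e1.gamma < e2.gamma else e2)
    elif choice == "primary":
        pick = e1 if not e1.secondary else e2
    else:
        pick = e1 if e1.secondary else e2
    return {r.id: pick}


def backbone_tree(net: PhyloNetwork, choice="major") -> PhyloNetwork:
    """Extract one displayed tree as the gene-flow-free backbone.

    ``choice`` is ``"major"`` (default: keep the higher-gamma edge at every
    reticulation, ties broken by removing the secondary/#H-referenced edge),
    ``"primary"``/``"secondary"``/``"minor"``, or a dict mapping reticulation
    tags (or node ids) to retained edge ids or per-reticulation keywords.
    """
    t = net.copy()
    t.validate()
    kept = _select_edges(t, choice)
    for rid, e in kept.items():
        node = t.nodes[rid]
        for pe in list(node.parent_edges):
            if pe.id != e.id:
                t.remove_edge(pe)
        node.parent_edges[0].gamma = None
    _cleanup(t)
    return t.validate()


def major_tree(net: PhyloNetwork) -> PhyloNetwork:
    """The displayed tree keeping, at each reticulation, the edge with the
    larger inheritance probability (the network's major tree)."""
    return backbone_tree(net, "major")


# ---------------------------------------------------------------------------
# structural comparison (used heavily in tests)
# ---------------------------------------------------------------------------

def network_signature(net: PhyloNetwork, ndigits: int = 8):
    """A hashable invariant of (topology, lengths, gamma, theta).

    Equal signatures imply isomorphic networks for the time-consistent,
    uniquely-leaf-labelled class handled here.
    """
    memo = {}

    def rnd(x):
        return None if x is None else round(float(x), ndigits)

    def sig(nid):
        if nid in memo:
            return memo[nid]
        n = net.nodes[nid]
        if n.is_leaf:
            s = ("leaf", n.label)
        else:
            parts = sorted(
                (sig(e.child), rnd(e.length), rnd(e.gamma), rnd(e.theta))
                for e in n.child_edges)
            s = ("node", tuple(parts))
        memo[nid] = s
        return s

    return sig(net.root_id)
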