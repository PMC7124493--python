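"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles (hand-rolled
DFS path enumeration, per-path blocking rules, full subset search) and never
calls the library code it is used to verify.
"""

from __future__ import annotations

import itertools


def directed_paths_exist(edges: set[tuple[str, str]], start: str, goal: str) -> bool:
    """DFS over directed edges only; no library calls."""
    adjacency: dict[str, list[str]] = {}
    for u, v in edges:
        adjacency.setdefault(u, []).append(v)
    stack, seen = [start], set()
    while stack:
        node = stack.pop()
        if node == goal:
            return True
        if node in seen:
            continue
        seen.add(node)
        stack.extend(adjacency.get(node, ()))
    return False


def has_cycle(edges: set[tuple[str, str]]) -> bool:
    """A directed cycle exists iff some edge (u, v) admits a path v -> u."""
    return any(directed_paths_exist(edges, v, u) for u, v in edges)


def all_undirected_simple_paths(edges, x, y):
    """Enumerate acyclic x..y paths ignoring arrow direction; yields node
    sequences annotated with the true arrow at each step."""
    neighbours: dict[str, set[str]] = {}
    for u, v in edges:
        neighbours.setdefault(u, set()).add(v)
        neighbours.setdefault(v, set()).add(u)
    edge_set = set(edges)
    paths = []

    def walk(node, path):
        if node == y:
            arrows = [
                "->" if (path[i], path[i + 1]) in edge_set else "<-"
                for i in range(len(path) - 1)
            ]
            paths.append((tuple(path), tuple(arrows)))
            return
        for nxt in neighbours.get(node, ()):
            if nxt not in path:
                walk(nxt, path + [nxt])

    if x in neighbours and y in neighbours:
        walk(x, [x])
    return paths


def descendants_of(edges, node):
    out = set()
    frontier = [node]
    while frontier:
        cur = frontier.pop()
        for u, v in edges:
            if u == cur and v not in out:
                out.add(v)
                frontier.append(v)
    return out


def path_is_open(edges, nodes, arrows, Z) -> bool:
    """Per-path d-separation blocking rules applied literally."""
    Z = set(Z)
    for i in range(1, len(nodes) - 1):
        into = arrows[i - 1] == "->"
        out_of = arrows[i] == "->"
        mid = nodes[i]
        if into and not out_of:  # collider
            if not ((descendants_of(edges, mid) | {mid}) & Z):
                return False
        else:  # chain or fork
            if mid in Z:
                return False
    return True


def brute_d_separated(edges, x, y, Z) -> bool:
    return not any(
        path_is_open(edges, nodes, arrows, Z)
        for nodes, arrows in all_undirected_simple_paths(edges, x, y)
    )


def brute_backdoor_valid(edges, nodes, x, y, Z) -> bool:
    """Classic backdoor criterion checked literally: Z holds no descendant of
    x and blocks every path whose first arrow points into x."""
    Z = set(Z)
    if Z & descendants_of(edges, x):
        return False
    for path_nodes, arrows in all_undirected_simple_paths(edges, x, y):
        if arrows[0] == "<-" and path_is_open(edges, path_nodes, arrows, Z):
            return False
    return True


def brute_minimal_adjustment_sets(edges, nodes, x, y, measured) -> set[frozenset]:
    candidates = sorted(
        (measured - {x, y}) - descendants_of(edges, x)
    )
    valid = [
        frozenset(c)
        for r in range(len(candidates) + 1)
        for c in itertools.combinations(candidates, r)
        if brute_backdoor_valid(edges, nodes, x, y, set(c))
    ]
    return {
        Z for Z in valid if not any(other < Z for other in valid)
    }
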