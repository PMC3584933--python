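"""Independent brute-force reference implementations used only by tests.

Everything here is written with explicit loops and set arithmetic,
sharing no code with the package, so that agreement between the two is
a meaningful check rather than a tautology.
"""

from __future__ import annotations


def brute_ancestors(parents: dict[str, frozenset[str]], term: str) -> set[str]:
    """Closure of term under the parent relation, including term itself."""
    out = {term}
    changed = True
    while changed:
        changed = False
        for t in list(out):
            for p in parents[t]:
                if p not in out:
                    out.add(p)
                    changed = True
    return out


def brute_similarity(parents: dict[str, frozenset[str]], g1: str, g2: str) -> float:
    r1 = brute_ancestors(parents, g1)
    r2 = brute_ancestors(parents, g2)
    return len(r1 & r2) / max(len(r1), len(r2))


def brute_root_paths(parents: dict[str, frozenset[str]], term: str) -> list[list[str]]:
    """All paths from term to a parentless node, as node lists."""
    if not parents[term]:
        return [[term]]
    paths = []
    for p in parents[term]:
        for sub in brute_root_paths(parents, p):
            paths.append([term] + sub)
    return paths


def brute_depth(parents: dict[str, frozenset[str]], term: str,
                convention: str = "shortest") -> int:
    lengths = [len(p) for p in brute_root_paths(parents, term)]
    return min(lengths) if convention == "shortest" else max(lengths)


def brute_neighbor_set(edges: set[frozenset[str]], nodes: set[str],
                       centers: set[str], radius: int) -> set[str]:
    """Plain frontier-by-frontier BFS from every center."""
    adjacency = {n: set() for n in nodes}
    for e in edges:
        u, v = tuple(e)
        adjacency[u].add(v)
        adjacency[v].add(u)
    reached = set(centers)
    frontier = set(centers)
    for _ in range(radius):
        frontier = {m for n in frontier for m in adjacency[n]} - reached
        reached |= frontier
    return reached - centers


def brute_ranks(scores: list[float]) -> list[float]:
    """Average ranks by explicit position counting."""
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    position = {}
    for rank_minus_1, i in enumerate(order):
        position[i] = rank_minus_1 + 1
    ranks = []
    for i, s in enumerate(scores):
        tied_positions = [position[j] for j in range(len(scores)) if scores[j] == s]
        ranks.append(sum(tied_positions) / len(tied_positions))
    return ranks


def brute_pr(parents, predicted: set[str], true: set[str]) -> tuple[float, float]:
    if not predicted:
        return 0.0, 0.0
    prop_pred = set()
    for t in predicted:
        prop_pred |= brute_ancestors(parents, t)
    prop_true = set()
    for t in true:
        prop_true |= brute_ancestors(parents, t)
    correct = len(prop_pred & prop_true)
    return correct / len(prop_pred), correct / len(prop_true)


def brute_topn_terms(entry: list[tuple[str, float]], n: int) -> set[str]:
    """entry: (go_term, confidence) sorted descending. Whole tie groups."""
    seen_scores: list[float] = []
    out = set()
    for go, conf in entry:
        if conf not in seen_scores:
            if len(seen_scores) == n:
                break
            seen_scores.append(conf)
        out.add(go)
    return out


def brute_topn_curve(parents, entries: dict[str, list[tuple[str, float]]],
                     truth: dict[str, set[str]], n_values) -> list[tuple[float, float]]:
    points = []
    for n in n_values:
        ps, rs = [], []
        for targ in sorted(truth):
            if not truth[targ]:
                continue
            selected = brute_topn_terms(entries.get(targ, []), n)
            p, r = brute_pr(parents, selected, truth[targ])
            ps.append(p)
            rs.append(r)
        points.append((sum(ps) / len(ps), sum(rs) / len(rs)))
    return points


def brute_threshold_curve(parents, entries, truth, t_values):
    points = []
    for t in t_values:
        ps, rs = [], []
        for targ in sorted(truth):
            if not truth[targ]:
                continue
            selected = {go for go, conf in entries.get(targ, []) if conf >= t}
            p, r = brute_pr(parents, selected, truth[targ])
            ps.append(p)
            rs.append(r)
        points.append((sum(ps) / len(ps), sum(rs) / len(rs)))
    return points


def brute_break_even(t_values, curve: list[tuple[float, float]]):
    """Same contract as the package: exclude vacuous all-zero points."""
    best = None
    for t, (p, r) in zip(t_values, curve):
        if (p, r) == (0.0, 0.0):
            continue
        key = (abs(p - r), -t)
        if best is None or key < best[0]:
            best = (key, t, p, r)
    if best is None:
        t, (p, r) = max(zip(t_values, curve), key=lambda x: x[0])
        return t, p, r
    return best[1], best[2], best[3]


def brute_similarity_curves(parents, entries, truth, k_values):
    avg_curve, best_curve = [], []
    for k in k_values:
        avgs, bests = [], []
        for targ in sorted(truth):
            if not truth[targ]:
                continue
            selected = brute_topn_terms(entries.get(targ, []), k)
            if not selected:
                avgs.append(0.0)
                bests.append(0.0)
                continue
            per_term = []
            for g in selected:
                best = 0.0
                for t in truth[targ]:
                    s = brute_similarity(parents, g, t)
                    if s > best:
                        best = s
                per_term.append(best)
            avgs.append(sum(per_term) / len(per_term))
            bests.append(max(per_term))
        avg_curve.append(sum(avgs) / len(avgs))
        best_curve.append(sum(bests) / len(bests))
    return avg_curve, best_curve
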