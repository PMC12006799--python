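"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the package's code paths: the Markov-cluster
oracle is a plain-Python dense-matrix transcription of the documented
algorithm, and the chaining oracle is a direct, unoptimized transcription
of the documented chaining rule.
"""

from __future__ import annotations


def mcl_oracle(graph, inflation=1.5, expansion=2, max_iter=200, tol=1e-6,
               prune=1e-5):
    """Dense-matrix Markov clustering with plain Python loops."""
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        return []
    idx = {v: i for i, v in enumerate(nodes)}
    M = [[0.0] * n for _ in range(n)]
    for u, v, d in graph.edges(data=True):
        w = float(d.get("weight", 1.0))
        M[idx[u]][idx[v]] = w
        M[idx[v]][idx[u]] = w
    for j in range(n):
        col_max = max(M[i][j] for i in range(n))
        M[j][j] = col_max if col_max > 0 else 1.0

    def _normalize(mat):
        for j in range(n):
            s = sum(mat[i][j] for i in range(n))
            if s == 0:
                mat[j][j] = 1.0
                s = 1.0
            for i in range(n):
                mat[i][j] /= s

    _normalize(M)
    for _ in range(max_iter):
        prev = [row[:] for row in M]
        # expansion: matrix power
        P = M
        for _ in range(expansion - 1):
            N = [[0.0] * n for _ in range(n)]
            for i in range(n):
                for k in range(n):
                    if P[i][k]:
                        for j in range(n):
                            N[i][j] += P[i][k] * M[k][j]
            P = N
        M = P
        # inflation + prune + renormalize
        for i in range(n):
            for j in range(n):
                M[i][j] = M[i][j] ** inflation
                if M[i][j] < prune:
                    M[i][j] = 0.0
        _normalize(M)
        delta = max(
            abs(M[i][j] - prev[i][j]) for i in range(n) for j in range(n)
        )
        if delta < tol:
            break

    # interpretation: attractors have diagonal mass; attractors sharing
    # support form one system; each node joins the system with most mass
    attractors = [i for i in range(n) if M[i][i] > prune]
    if not attractors:
        attractors = sorted({
            max(range(n), key=lambda i: M[i][j]) for j in range(n)
        })
    parent = {i: i for i in attractors}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in attractors:
        for k in attractors:
            if i < k and (M[i][k] > prune or M[k][i] > prune):
                parent[find(i)] = find(k)
    systems: dict[int, list[int]] = {}
    for i in attractors:
        systems.setdefault(find(i), []).append(i)
    sys_list = sorted((sorted(s) for s in systems.values()),
                      key=lambda s: nodes[s[0]])
    clusters: dict[int, set] = {}
    for j in range(n):
        masses = [sum(M[i][j] for i in s) for s in sys_list]
        best = max(masses)
        if best <= 0:
            i = max(range(n), key=lambda i: M[i][j])
            choice = next(
                (si for si, s in enumerate(sys_list) if i in s), 0
            )
        else:
            tied = [si for si, m in enumerate(masses) if m == best]
            choice = min(tied, key=lambda si: nodes[sys_list[si][0]])
        clusters.setdefault(choice, set()).add(nodes[j])
    return sorted(clusters.values(), key=lambda c: sorted(c))


def chain_oracle(points, min_block=5, max_gap=25):
    """Direct transcription of the chaining rule over (x, y, id) points.

    Returns the chains (as id tuples) with at least ``min_block`` points.
    """
    chains = []  # dicts: pts, dir, open
    for x, y, pid in sorted(points):
        for ch in chains:
            if ch["open"] and x - ch["pts"][-1][0] > max_gap:
                ch["open"] = False
        best, best_key = None, None
        for ch in chains:
            if not ch["open"]:
                continue
            lx, ly, _ = ch["pts"][-1]
            dx, dy = x - lx, y - ly
            if dx <= 0 or dx > max_gap or dy == 0 or abs(dy) > max_gap:
                continue
            if ch["dir"] != 0 and (1 if dy > 0 else -1) != ch["dir"]:
                continue
            key = (dx + abs(dy), abs(dy), ly)
            if best_key is None or key < best_key:
                best, best_key = ch, key
        if best is None:
            chains.append({"pts": [(x, y, pid)], "dir": 0, "open": True})
        else:
            ly = best["pts"][-1][1]
            best["pts"].append((x, y, pid))
            if best["dir"] == 0:
                best["dir"] = 1 if y > ly else -1
    return [
        tuple(pid for _, _, pid in ch["pts"])
        for ch in chains
        if len(ch["pts"]) >= min_block
    ]
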