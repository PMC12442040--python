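"""Independent all-pairs chaining oracle shared by the test modules."""


def brute_force_components(mzs, step, ppm, k_max):
    """Connected components of the step-multiple graph, by BFS.

    Edge between i and j when |mz_j - mz_i| is within ``ppm`` (of the
    heavier member) of k*step for some integer k in [1, k_max].
    """
    n = len(mzs)
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            delta = abs(mzs[j] - mzs[i])
            k = round(delta / step)
            if 1 <= k <= k_max and abs(delta - k * step) / max(mzs[i], mzs[j]) * 1e6 <= ppm:
                adj[i].add(j)
                adj[j].add(i)
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(adj[u] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)
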