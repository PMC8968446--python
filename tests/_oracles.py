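"""Independent brute-force oracles used by the test suite.

Pure-Python implementations (no scipy.ndimage, no package internals) so
they stand apart from the code paths they check.
"""

import math


def threshold_components_oracle(delta, mask, k, min_volume, voxel_volume):
    """Reference for candidate extraction: z-threshold + 26-neighbor flood fill.

    Returns a set of frozensets of (i, j, k) voxel tuples.
    """
    ni, nj, nk = delta.shape
    inside = [
        (i, j, kk)
        for i in range(ni)
        for j in range(nj)
        for kk in range(nk)
        if mask[i, j, kk]
    ]
    vals = [float(delta[p]) for p in inside]
    n = len(vals)
    mu = sum(vals) / n
    sigma = math.sqrt(sum((v - mu) ** 2 for v in vals) / n)
    if sigma == 0.0:
        return set()
    thr = mu + k * sigma
    supra = {p for p, v in zip(inside, vals) if v > thr}

    components = []
    unvisited = set(supra)
    while unvisited:
        seed = unvisited.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            ci, cj, ck = frontier.pop()
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for dk in (-1, 0, 1):
                        if di == dj == dk == 0:
                            continue
                        q = (ci + di, cj + dj, ck + dk)
                        if q in unvisited:
                            unvisited.remove(q)
                            comp.add(q)
                            frontier.append(q)
        components.append(comp)
    return {
        frozenset(c) for c in components if len(c) * voxel_volume >= min_volume
    }


def decision_metrics_oracle(records):
    """Reference decision metrics computed by direct counting loops."""
    tp = sum(1 for g, t in records if g and t)
    fp = sum(1 for g, t in records if g and not t)
    fn = sum(1 for g, t in records if not g and t)
    tn = sum(1 for g, t in records if not g and not t)

    def ratio(a, b):
        return None if b == 0 else a / b

    sens = ratio(tp, tp + fn)
    ppv = ratio(tp, tp + fp)
    return {
        "sensitivity": sens,
        "specificity": ratio(tn, fp + tn),
        "ppv": ppv,
        "npv": ratio(tn, fn + tn),
        "accuracy": ratio(tp + tn, tp + fp + fn + tn),
        "f1": (
            None
            if sens is None or ppv is None or (sens + ppv) == 0
            else 2 * sens * ppv / (sens + ppv)
        ),
    }


def gbca_rule_oracle(statuses):
    """Truth table for the injection decision: recommend iff any new lesion."""
    return any(s == "new_lesion" for s in statuses)
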