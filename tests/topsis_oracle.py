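"""Independent brute-force TOPSIS implementation used as a test oracle.

Deliberately written with plain Python loops and ``math``, sharing no code
with ``vesselmorph.fuzzy_eval``.
"""

import math


def topsis_oracle(values, directions, weights, scheme):
    """Return (d_plus, d_minus, closeness, dense_ranks) lists.

    values: list of rows (one per group); directions: 'cost'/'benefit' per
    criterion; weights: positive reals; scheme: 'vector'|'minmax'|'none'.
    """
    n_groups = len(values)
    n_crit = len(values[0])
    total_w = sum(weights)
    w = [wi / total_w for wi in weights]
    dirs = list(directions)

    norm = [[0.0] * n_crit for _ in range(n_groups)]
    if scheme == "vector":
        for j in range(n_crit):
            nrm = math.sqrt(sum(values[i][j] ** 2 for i in range(n_groups)))
            for i in range(n_groups):
                norm[i][j] = values[i][j] / nrm
    elif scheme == "minmax":
        for j in range(n_crit):
            col = [values[i][j] for i in range(n_groups)]
            lo, hi = min(col), max(col)
            for i in range(n_groups):
                if hi == lo:
                    norm[i][j] = 0.0
                elif dirs[j] == "benefit":
                    norm[i][j] = (values[i][j] - lo) / (hi - lo)
                else:
                    norm[i][j] = (hi - values[i][j]) / (hi - lo)
        dirs = ["benefit"] * n_crit
    elif scheme == "none":
        for j in range(n_crit):
            for i in range(n_groups):
                norm[i][j] = values[i][j]
    else:
        raise ValueError(scheme)

    weighted = [[norm[i][j] * w[j] for j in range(n_crit)] for i in range(n_groups)]
    ideal, anti = [], []
    for j in range(n_crit):
        col = [weighted[i][j] for i in range(n_groups)]
        if dirs[j] == "cost":
            ideal.append(min(col))
            anti.append(max(col))
        else:
            ideal.append(max(col))
            anti.append(min(col))

    d_plus, d_minus, closeness = [], [], []
    for i in range(n_groups):
        dp = math.sqrt(sum((weighted[i][j] - ideal[j]) ** 2 for j in range(n_crit)))
        dm = math.sqrt(sum((weighted[i][j] - anti[j]) ** 2 for j in range(n_crit)))
        d_plus.append(dp)
        d_minus.append(dm)
        closeness.append(dm / (dp + dm) if dp + dm > 0 else 1.0)

    distinct = sorted(set(closeness), reverse=True)
    rank_of = {c: r + 1 for r, c in enumerate(distinct)}
    ranks = [rank_of[c] for c in closeness]
    return d_plus, d_minus, closeness, ranks
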