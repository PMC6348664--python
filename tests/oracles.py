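"""Independent brute-force reimplementations of the stability statistics.

Written with plain Python loops and the stdlib ``statistics`` module so that
they share no code path with the package: every pair is enumerated
explicitly and every formula is applied directly to scalars.
"""

from __future__ import annotations

import math
import statistics


def delta_ct_oracle(ct: list[list[float]]) -> list[float]:
    """Mean over partners of the sample SD of pairwise Ct differences."""
    G, S = len(ct), len(ct[0])
    out = []
    for j in range(G):
        sds = []
        for k in range(G):
            if k == j:
                continue
            diffs = [ct[j][s] - ct[k][s] for s in range(S)]
            sds.append(statistics.stdev(diffs))
        out.append(sum(sds) / len(sds))
    return out


def genorm_m_oracle(q: list[list[float]]) -> list[float]:
    """Mean over partners of the SD of pairwise log2 quantity ratios."""
    G, S = len(q), len(q[0])
    out = []
    for j in range(G):
        sds = []
        for k in range(G):
            if k == j:
                continue
            ratios = [math.log2(q[j][s] / q[k][s]) for s in range(S)]
            sds.append(statistics.stdev(ratios))
        out.append(sum(sds) / len(sds))
    return out


def genorm_elimination_oracle(q: list[list[float]], genes: list[str]) -> list[str]:
    """Elimination order (first removed first), recomputing M from scratch at
    every step; ties remove the later gene in input order."""
    alive = list(range(len(genes)))
    order = []
    while len(alive) > 2:
        sub = [q[i] for i in alive]
        m_vals = genorm_m_oracle(sub)
        worst_pos = 0
        for p in range(1, len(alive)):
            if m_vals[p] >= m_vals[worst_pos]:  # >= keeps the later gene on ties
                worst_pos = p
        order.append(genes[alive[worst_pos]])
        alive.pop(worst_pos)
    return order


def normfinder_oracle(q: list[list[float]]) -> list[float]:
    """Ungrouped NormFinder SVs, from the variance-decomposition formulas."""
    G, S = len(q), len(q[0])
    y = [[math.log2(v) for v in row] for row in q]
    gene_mean = [sum(row) / S for row in y]
    samp_mean = [sum(y[g][s] for g in range(G)) / G for s in range(S)]
    grand = sum(gene_mean) / G
    ms = []
    for g in range(G):
        ss = sum(
            (y[g][s] - gene_mean[g] - samp_mean[s] + grand) ** 2 for s in range(S)
        )
        ms.append(ss / (S - 1))
    total = sum(ms)
    out = []
    for g in range(G):
        var = G / (G - 2) * (ms[g] - total / (G * (G - 1)))
        out.append(math.sqrt(max(var, 0.0)))
    return out


def bestkeeper_oracle(ct: list[list[float]]) -> dict[str, list[float]]:
    """Per-gene SD, CV%, geometric mean, and Pearson r against the per-sample
    geometric-mean index."""
    G, S = len(ct), len(ct[0])
    index = [
        math.exp(sum(math.log(ct[g][s]) for g in range(G)) / G) for s in range(S)
    ]

    def pearson(x, y):
        mx, my = sum(x) / len(x), sum(y) / len(y)
        num = sum((a - mx) * (b - my) for a, b in zip(x, y))
        den = math.sqrt(
            sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)
        )
        return num / den if den else float("nan")

    sd = [statistics.stdev(row) for row in ct]
    mean = [sum(row) / S for row in ct]
    return {
        "sd_ct": sd,
        "cv_pct": [100.0 * s / m for s, m in zip(sd, mean)],
        "geo_mean_ct": [
            math.exp(sum(math.log(v) for v in row) / S) for row in ct
        ],
        "r_vs_index": [pearson(row, index) for row in ct],
        "index": index,
    }


def normfinder_grouped_oracle(
    q: list[list[float]], labels: list[str]
) -> list[float]:
    """Grouped NormFinder SVs via the empirical-Bayes decomposition, applied
    group by group with explicit loops."""
    G = len(q)
    y = [[math.log2(v) for v in row] for row in q]
    groups = list(dict.fromkeys(labels))
    J = len(groups)
    cols = {lab: [i for i, l in enumerate(labels) if l == lab] for lab in groups}

    var_gj = [[0.0] * J for _ in range(G)]
    mean_gj = [[0.0] * J for _ in range(G)]
    for jx, lab in enumerate(groups):
        block = [[y[g][s] for s in cols[lab]] for g in range(G)]
        n = len(cols[lab])
        gm = [sum(r) / n for r in block]
        sm = [sum(block[g][i] for g in range(G)) / G for i in range(n)]
        grand = sum(gm) / G
        ms = [
            sum((block[g][i] - gm[g] - sm[i] + grand) ** 2 for i in range(n)) / (n - 1)
            for g in range(G)
        ]
        tot = sum(ms)
        for g in range(G):
            var_gj[g][jx] = max(0.0, G / (G - 2) * (ms[g] - tot / (G * (G - 1))))
            mean_gj[g][jx] = gm[g]

    row_m = [sum(r) / J for r in mean_gj]
    col_m = [sum(mean_gj[g][j] for g in range(G)) / G for j in range(J)]
    grand = sum(row_m) / G
    d = [
        [mean_gj[g][j] - row_m[g] - col_m[j] + grand for j in range(J)]
        for g in range(G)
    ]
    n_j = [len(cols[lab]) for lab in groups]
    noise = [[var_gj[g][j] / n_j[j] for j in range(J)] for g in range(G)]
    gamma2 = max(
        0.0,
        sum(v**2 for row in d for v in row) / ((G - 1) * (J - 1))
        - sum(v for row in noise for v in row) / (G * J),
    )
    out = []
    for g in range(G):
        acc = 0.0
        for j in range(J):
            den = gamma2 + noise[g][j]
            shrink = gamma2 / den if den > 0 else 0.0
            acc += abs(d[g][j] * shrink) + math.sqrt(noise[g][j] * shrink)
        out.append(acc / J)
    return out
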