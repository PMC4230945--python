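"""Independent brute-force implementations used as test oracles.

Deliberately written with plain Python loops and the statistics module —
no numpy vectorization, no code shared with the package — so that agreement
with the library is a genuine cross-check of the algorithms, not of one
code path against itself.
"""

import math
import statistics


def pairwise_v(q: dict, j: str, k: str) -> float:
    """SD over samples of log2(Q_j / Q_k)."""
    ratios = [math.log2(a / b) for a, b in zip(q[j], q[k])]
    return statistics.stdev(ratios)


def m_value(q: dict, j: str, active: list) -> float:
    others = [k for k in active if k != j]
    return sum(pairwise_v(q, j, k) for k in others) / len(others)


def geometric_mean(values: list) -> float:
    return math.exp(sum(math.log(v) for v in values) / len(values))


def normalization_factor(q: dict, genes: list) -> list:
    n_samples = len(next(iter(q.values())))
    return [
        geometric_mean([q[g][s] for g in genes]) for s in range(n_samples)
    ]


def genorm_full(q: dict) -> dict:
    """Full stepwise geNorm: exclusion order, M records, stability order, V series.

    q maps gene -> list of relative quantities (one per sample), insertion
    order = input order. Ties on M exclude the later gene in input order.
    """
    genes = list(q)
    active = list(genes)
    exclusion = []
    m_records = {}
    while len(active) > 2:
        ms = {g: m_value(q, g, active) for g in active}
        worst = None
        for g in active:
            if worst is None or ms[g] >= ms[worst]:
                worst = g
        exclusion.append((worst, ms[worst]))
        m_records[worst] = ms[worst]
        active.remove(worst)
    pair_m = pairwise_v(q, active[0], active[1])
    for g in active:
        m_records[g] = pair_m
    stability_order = active + [g for g, _ in reversed(exclusion)]
    v_series = []
    for n in range(2, len(genes)):
        nf_n = normalization_factor(q, stability_order[:n])
        nf_n1 = normalization_factor(q, stability_order[: n + 1])
        logs = [math.log2(a / b) for a, b in zip(nf_n, nf_n1)]
        v_series.append((n, statistics.stdev(logs)))
    return {
        "exclusion": exclusion,
        "m": m_records,
        "order": stability_order,
        "v_series": v_series,
    }


def pearson_r(x: list, y: list) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    return cov / (sx * sy)
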