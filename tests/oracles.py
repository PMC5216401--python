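"""Independent direct-formula oracles used to cross-check the package.

Everything here is written from the definitions, in plain loops where
possible, deliberately not sharing code with the implementation.
"""

import math


def oracle_regression_stats(y, p):
    """All regression-report statistics from first principles."""
    n = len(y)
    my = sum(y) / n
    mp = sum(p) / n
    # Pearson r^2
    num = sum((y[i] - my) * (p[i] - mp) for i in range(n))
    den = math.sqrt(sum((v - my) ** 2 for v in y) * sum((v - mp) ** 2 for v in p))
    r2 = (num / den) ** 2
    resid = [y[i] - p[i] for i in range(n)]
    press = sum(e * e for e in resid)
    ss = sum((v - my) ** 2 for v in y)
    q2_f1 = 1 - press / ss
    mae = sum(abs(e) for e in resid) / n
    rmse = math.sqrt(press / n)
    mr = sum(resid) / n
    s = math.sqrt(sum((e - mr) ** 2 for e in resid) / (n - 1))
    delta_max = max(abs(e) for e in resid)
    k = sum(y[i] * p[i] for i in range(n)) / sum(v * v for v in p)
    k_prime = sum(y[i] * p[i] for i in range(n)) / sum(v * v for v in y)
    r0_2 = 1 - sum((y[i] - k * p[i]) ** 2 for i in range(n)) / ss
    ssp = sum((v - mp) ** 2 for v in p)
    r0_prime_2 = 1 - sum((p[i] - k_prime * y[i]) ** 2 for i in range(n)) / ssp
    rm2 = r2 * (1 - math.sqrt(abs(r2 - r0_2)))
    rm2_prime = r2 * (1 - math.sqrt(abs(r2 - r0_prime_2)))
    cov = sum((y[i] - my) * (p[i] - mp) for i in range(n)) / n
    var_y = sum((v - my) ** 2 for v in y) / n
    var_p = sum((v - mp) ** 2 for v in p) / n
    ccc = 2 * cov / (var_y + var_p + (my - mp) ** 2)
    return {
        "r2": r2, "q2": r2, "q2_f1": q2_f1, "mae": mae, "rmse": rmse,
        "s": s, "delta_max": delta_max, "k": k, "k_prime": k_prime,
        "r0_2": r0_2, "r0_prime_2": r0_prime_2, "rm2": rm2,
        "rm2_prime": rm2_prime, "rm2_avg": (rm2 + rm2_prime) / 2,
        "rm2_delta": abs(rm2 - rm2_prime), "ccc": ccc,
    }


def oracle_rankings(scores_by_term, directions, keys):
    """Brute-force single/consensus rankings for one candidate group.

    ``scores_by_term``: dict term -> list of scores (index = candidate).
    ``directions``: dict term -> 'higher' | 'lower'.
    ``keys``: sortable tie-break key per candidate.
    Returns dict method -> list of ranks (1 = best) per candidate.
    """
    m = len(keys)
    terms = list(scores_by_term)
    aligned = {
        t: [(-v if directions[t] == "lower" else v) for v in scores_by_term[t]]
        for t in terms
    }

    def order_to_ranks(score_of):
        idx = sorted(range(m), key=lambda i: (-score_of[i], keys[i]))
        ranks = [0] * m
        for pos, i in enumerate(idx):
            ranks[i] = pos + 1
        return ranks

    out = {}
    # rank-by-number: mean of z-standardized aligned scores (sample sd,
    # pooled over the group because the oracle sees one group)
    zmeans = []
    zs = {}
    for t in terms:
        vals = aligned[t]
        mu = sum(vals) / m
        sd = math.sqrt(sum((v - mu) ** 2 for v in vals) / (m - 1))
        zs[t] = [(v - mu) / sd for v in vals]
    for i in range(m):
        zmeans.append(sum(zs[t][i] for t in terms) / len(terms))
    out["rank_by_number"] = order_to_ranks(zmeans)

    # average rank per term, ties share the average rank
    def avg_ranks(vals):
        ranks = []
        for i in range(m):
            less = sum(1 for j in range(m) if vals[j] > vals[i])
            eq = sum(1 for j in range(m) if vals[j] == vals[i])
            ranks.append(less + (eq + 1) / 2)
        return ranks

    mean_rank = [sum(avg_ranks(aligned[t])[i] for t in terms) / len(terms)
                 for i in range(m)]
    out["rank_by_rank"] = order_to_ranks([-r for r in mean_rank])

    # votes: each term votes for its top ceil(m/3) candidates, strict
    # ordering with key tie-break; final order by votes, then mean rank,
    # then key
    cutoff = math.ceil(m / 3)
    votes = [0] * m
    for t in terms:
        idx = sorted(range(m), key=lambda i: (-aligned[t][i], keys[i]))
        for i in idx[:cutoff]:
            votes[i] += 1
    idx = sorted(range(m), key=lambda i: (-votes[i], mean_rank[i], keys[i]))
    ranks = [0] * m
    for pos, i in enumerate(idx):
        ranks[i] = pos + 1
    out["rank_by_vote"] = ranks
    return out
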