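"""Brute-force reference implementations used only as test oracles.

Deliberately written as plain loops over pairs, independent of the package
internals, so agreement is evidence rather than tautology.
"""

import math


def bf_pearson(x, y):
    """Pearson r by direct loops; None when undefined (<3 pairs / no variance)."""
    pairs = [
        (a, b)
        for a, b in zip(x, y)
        if not (math.isnan(a) or math.isnan(b))
    ]
    n = len(pairs)
    if n < 3:
        return None
    mx = sum(a for a, _ in pairs) / n
    my = sum(b for _, b in pairs) / n
    sxx = sum((a - mx) ** 2 for a, _ in pairs)
    syy = sum((b - my) ** 2 for _, b in pairs)
    sxy = sum((a - mx) * (b - my) for a, b in pairs)
    if sxx <= 0 or syy <= 0:
        return None
    return sxy / math.sqrt(sxx * syy)


def bf_ranks(v):
    """Mid-ranks with ties averaged, by enumeration."""
    out = []
    for a in v:
        less = sum(1 for b in v if b < a)
        equal = sum(1 for b in v if b == a)
        out.append(less + (equal + 1) / 2.0)
    return out


def bf_spearman(x, y):
    pairs = [
        (a, b)
        for a, b in zip(x, y)
        if not (math.isnan(a) or math.isnan(b))
    ]
    if len(pairs) < 3:
        return None
    return bf_pearson(bf_ranks([a for a, _ in pairs]), bf_ranks([b for _, b in pairs]))


def bf_alpha(rows):
    """Cronbach's alpha over complete-case rows, sample variances, by loops."""
    rows = [r for r in rows if not any(math.isnan(v) for v in r)]
    n = len(rows)
    if n < 2:
        return None
    k = len(rows[0])

    def var(vs):
        m = sum(vs) / len(vs)
        return sum((v - m) ** 2 for v in vs) / (len(vs) - 1)

    total = var([sum(r) for r in rows])
    if total <= 0:
        return None
    items = sum(var([r[i] for r in rows]) for i in range(k))
    return k / (k - 1) * (1 - items / total)


def bf_fisher_mean(rs, total, min_prop=0.8, clip=0.999):
    """Availability-gated Fisher-z mean of a list of r's (None = undefined)."""
    defined = [r for r in rs if r is not None]
    if len(defined) / total < min_prop:
        return None
    zs = [math.atanh(max(-clip, min(clip, r))) for r in defined]
    mz = sum(zs) / len(zs)
    return mz, math.tanh(mz)


def bf_profile_scores(ratings, criteria, mode, min_prop=0.8, clip=0.999):
    """Per-judge profile accuracy by direct loops.

    ``ratings``: judge x target x trait nested lists (nan = missing);
    ``criteria``: target x trait.  Returns list of back-transformed totals
    (None where missing).
    """
    J = len(ratings)
    T = len(criteria)
    A = len(criteria[0])
    if mode == "distinctive":
        rat_mean = []
        for a in range(A):
            vals = [
                ratings[j][t][a]
                for j in range(J)
                for t in range(T)
                if not math.isnan(ratings[j][t][a])
            ]
            rat_mean.append(sum(vals) / len(vals))
        crit_mean = [sum(criteria[t][a] for t in range(T)) / T for a in range(A)]
    else:
        rat_mean = [0.0] * A
        crit_mean = [0.0] * A
    totals = []
    for j in range(J):
        rs = []
        for t in range(T):
            x = [ratings[j][t][a] - rat_mean[a] for a in range(A)]
            y = [criteria[t][a] - crit_mean[a] for a in range(A)]
            rs.append(bf_pearson(x, y))
        agg = bf_fisher_mean(rs, T, min_prop, clip)
        totals.append(None if agg is None else agg[1])
    return totals
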