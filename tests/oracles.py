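"""Independent brute-force oracles used to cross-check the package's
statistics.  These deliberately follow the textbook formulas step by step
and share no code with the implementation paths they verify."""

from __future__ import annotations

import numpy as np
from scipy.stats import t as t_dist
from scipy.stats import chi2 as chi2_dist


def pooled_t_oracle(a, b):
    """Two-sample pooled-variance Student's t and two-tailed p."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    sa2 = ((a - a.mean()) ** 2).sum() / (na - 1)
    sb2 = ((b - b.mean()) ** 2).sum() / (nb - 1)
    sp2 = ((na - 1) * sa2 + (nb - 1) * sb2) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * t_dist.sf(abs(t), na + nb - 2)
    return t, p


def paired_t_oracle(a, b):
    d = np.asarray(a, float) - np.asarray(b, float)
    n = len(d)
    sd = np.sqrt(((d - d.mean()) ** 2).sum() / (n - 1))
    t = d.mean() / (sd / np.sqrt(n))
    return t, 2 * t_dist.sf(abs(t), n - 1)


def _midranks(x):
    x = np.asarray(x, float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    i = 0
    sorted_x = x[order]
    while i < len(x):
        j = i
        while j + 1 < len(x) and sorted_x[j + 1] == sorted_x[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """Rank (average ranks for ties) then plain Pearson on the ranks."""
    rx, ry = _midranks(x), _midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def chi2_oracle(table):
    """Pearson chi-square from the expected-count table, no correction."""
    table = np.asarray(table, float)
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    stat = float(((table - expected) ** 2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return stat, float(chi2_dist.sf(stat, df)), df


def chi2_2x2_closed_form(table):
    """n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) for a 2x2 table."""
    (a, b), (c, d) = np.asarray(table, float)
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def km_oracle(times, events):
    """Product-limit estimate as {event_time: S(t)}."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out = {}
    s = 1.0
    for t in sorted(set(times[events == 1])):
        n_at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1 - d / n_at_risk
        out[float(t)] = s
    return out


def logrank_oracle(times_a, events_a, times_b, events_b):
    """Two-group log-rank chi-square from the O/E/hypergeometric-V table."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    t_all = np.concatenate([ta, tb])
    e_all = np.concatenate([ea, eb])
    grp_a = np.concatenate([np.ones(len(ta), bool), np.zeros(len(tb), bool)])
    o = e = v = 0.0
    for t in sorted(set(t_all[e_all == 1])):
        at_risk = t_all >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & grp_a).sum())
        d = int(((t_all == t) & (e_all == 1)).sum())
        d_a = int(((t_all == t) & (e_all == 1) & grp_a).sum())
        o += d_a
        e += d * n_a / n
        if n > 1:
            v += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return (o - e) ** 2 / v


def mean_of_z_oracle(values):
    """Signature score by explicit spreadsheet-style z-scoring.

    ``values``: genes x samples array; returns per-sample mean of per-gene
    (x - mean) / population-sd.
    """
    values = np.asarray(values, float)
    z = np.empty_like(values)
    for i, row in enumerate(values):
        z[i] = (row - row.mean()) / row.std()
    return z.mean(axis=0)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """ARI from the pair-counting contingency formula."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    cats_a = {c: i for i, c in enumerate(dict.fromkeys(labels_a.tolist()))}
    cats_b = {c: i for i, c in enumerate(dict.fromkeys(labels_b.tolist()))}
    m = np.zeros((len(cats_a), len(cats_b)))
    for a, b in zip(labels_a, labels_b):
        m[cats_a[a], cats_b[b]] += 1

    def comb2(x):
        return x * (x - 1) / 2

    sum_ij = comb2(m).sum()
    sum_a = comb2(m.sum(axis=1)).sum()
    sum_b = comb2(m.sum(axis=0)).sum()
    n = comb2(m.sum())
    expected = sum_a * sum_b / n
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
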