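"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most literal method available
(per-sample scans, naive sums-of-squares loops, exhaustive enumeration) and
is kept free of the package's own vectorized implementations.
"""

from itertools import combinations

import numpy as np

from rotarena.arena_geometry import in_sector, to_polar


def max_time_avoided_scan(track, sector) -> float:
    """Per-sample scan: walk the samples, accumulating the current run of
    time outside the sector sample-and-hold, tracking the maximum."""
    state = to_polar(track)
    inside = in_sector(state.theta_room_deg, sector)
    n = len(inside)
    best = 0.0
    current = 0.0
    for i in range(n):
        if i < n - 1:
            hold = track.t_s[i + 1] - track.t_s[i]
        else:
            hold = max(track.session_duration_s - track.t_s[i], 0.0)
        if inside[i]:
            current = 0.0
        else:
            current += hold
            if current > best:
                best = current
    return best


def shock_events_scan(t_s, inside) -> list:
    """Literal event simulation of the shock cycle: shock at entrance,
    repeat 2.0 s after the previous shock while still inside."""
    events = []
    was_inside = False
    last_shock = None
    for t, is_in in zip(t_s, inside):
        if is_in:
            if not was_inside:
                events.append(t)
                last_shock = t
            elif t >= last_shock + 2.0 - 1e-9:
                events.append(t)
                last_shock = t
        was_inside = is_in
    return events


def mixed_anova_naive(y, groups):
    """Naive loop-based sums-of-squares decomposition for one between
    (2 groups) x one within (2 levels) design.  Returns dict of
    (F, df1, df2, ges) per effect."""
    y = np.asarray(y, dtype=float)
    groups = list(groups)
    labels = sorted(set(groups))
    n, b = y.shape
    grand = y.sum() / y.size

    ss_group = 0.0
    for g in labels:
        cells = [y[i] for i in range(n) if groups[i] == g]
        mean_g = np.sum(cells) / (len(cells) * b)
        ss_group += len(cells) * b * (mean_g - grand) ** 2

    ss_subj_total = 0.0
    for i in range(n):
        ss_subj_total += b * (y[i].mean() - grand) ** 2
    ss_subj_within = ss_subj_total - ss_group

    ss_phase = 0.0
    for j in range(b):
        ss_phase += n * (y[:, j].mean() - grand) ** 2

    ss_int = 0.0
    for g in labels:
        idx = [i for i in range(n) if groups[i] == g]
        mean_g = y[idx].mean()
        for j in range(b):
            cell = y[idx][:, j].mean()
            ss_int += len(idx) * (cell - mean_g - y[:, j].mean() + grand) ** 2

    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_subj_total - ss_phase - ss_int
    a = len(labels)
    df = {
        "group": (a - 1, n - a),
        "phase": (b - 1, (n - a) * (b - 1)),
        "interaction": ((a - 1) * (b - 1), (n - a) * (b - 1)),
    }
    ss = {"group": ss_group, "phase": ss_phase, "interaction": ss_int}
    err = {"group": ss_subj_within, "phase": ss_err, "interaction": ss_err}
    out = {}
    for effect in ss:
        df1, df2 = df[effect]
        F = (ss[effect] / df1) / (err[effect] / df2)
        ges = ss[effect] / (ss[effect] + ss_subj_within + ss_err)
        out[effect] = (F, df1, df2, ges)
    return out


def mann_whitney_exact_enumeration(x, y):
    """U statistic and exact two-sided p by enumerating all rank
    assignments of the pooled sample (no ties assumed)."""
    x = list(x)
    y = list(y)
    u_obs = sum(1.0 for xi in x for yj in y if xi > yj) \
        + 0.5 * sum(1.0 for xi in x for yj in y if xi == yj)
    pooled = sorted(x + y)
    m, n = len(x), len(y)
    total = 0
    extreme = 0
    mn = m * n
    for idx in combinations(range(m + n), m):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(m + n) if i not in set(idx)]
        u = sum(1.0 for xi in xs for yj in ys if xi > yj)
        total += 1
        # two-sided: as or more extreme in either tail
        if min(u, mn - u) <= min(u_obs, mn - u_obs) + 1e-12:
            extreme += 1
    return u_obs, extreme / total
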