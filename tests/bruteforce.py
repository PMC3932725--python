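"""Literal, loop-based reference implementations of every metric and of the
Spearman matrix, written directly from the definitions (no numpy vector
tricks, no shared code with the package).  Used as the independent
cross-check in the oracle-equivalence tests."""

import math


def _bin_index(value, lo, hi, bins):
    """Equal-width binning, half-open bins, last bin closed (so value == hi
    lands in bin bins-1)."""
    if bins == 1:
        return 0
    if value >= hi:
        return bins - 1
    width = (hi - lo) / bins
    idx = int((value - lo) / width)
    return min(max(idx, 0), bins - 1)


def _entropy_bits(counts):
    total = sum(counts)
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * math.log2(p)
    return h


def _shared_range(r, s):
    lo = min(min(r), min(s))
    hi = max(max(r), max(s))
    return lo, hi


def msd_raw(r, s):
    return sum((a - b) ** 2 for a, b in zip(r, s)) / len(r)


def msd_score(r, s):
    raw = msd_raw(r, s)
    if raw == 0.0:
        return 1.0
    lo, hi = _shared_range(r, s)
    return min(max(1.0 - raw / (hi - lo) ** 2, 0.0), 1.0)


def adi_raw(r, s):
    return sum(abs(a - b) for a, b in zip(r, s)) / len(r)


def adi_score(r, s):
    raw = adi_raw(r, s)
    if raw == 0.0:
        return 1.0
    lo, hi = _shared_range(r, s)
    return min(max(1.0 - raw / (hi - lo), 0.0), 1.0)


def edi_raw(r, s, bins):
    d = [a - b for a, b in zip(r, s)]
    if min(d) == max(d):
        return 0.0
    lo, hi = min(d), max(d)
    counts = [0] * bins
    for v in d:
        counts[_bin_index(v, lo, hi, bins)] += 1
    return _entropy_bits(counts)


def edi_score(r, s, bins):
    raw = edi_raw(r, s, bins)
    if raw == 0.0:
        return 1.0
    return min(max(1.0 - raw / math.log2(bins), 0.0), 1.0)


def joint_entropies(r, s, bins):
    """(H_R, H_S, H_RS) from one joint histogram over the shared range."""
    lo, hi = _shared_range(r, s)
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    joint = {}
    for a, b in zip(r, s):
        key = (_bin_index(a, lo, hi, bins), _bin_index(b, lo, hi, bins))
        joint[key] = joint.get(key, 0) + 1
    marg_r, marg_s = {}, {}
    for (i, j), c in joint.items():
        marg_r[i] = marg_r.get(i, 0) + c
        marg_s[j] = marg_s.get(j, 0) + c
    return (
        _entropy_bits(list(marg_r.values())),
        _entropy_bits(list(marg_s.values())),
        _entropy_bits(list(joint.values())),
    )


def mi_family_values(r, s, bins):
    """raws and scores of {mif, nmi, red, uni, aum}; None where undefined.

    Returns dict name -> (raw, score).  The both-constant convention (all
    scores 1 if identical else 0) is handled by the caller.
    """
    h_r, h_s, h_rs = joint_entropies(r, s, bins)
    i_rs = max(h_r + h_s - h_rs, 0.0)
    h_min, h_max = min(h_r, h_s), max(h_r, h_s)
    out = {}
    out["mif"] = (i_rs, min(max(i_rs / h_min, 0.0), 1.0) if h_min > 0 else 0.0)
    if h_rs > 0:
        nmi = i_rs / h_rs + 1.0
        out["nmi"] = (nmi, min(max(nmi - 1.0, 0.0), 1.0))
        uni = 1.0 - i_rs / h_rs
        out["uni"] = (uni, min(max(1.0 - uni, 0.0), 1.0))
    else:
        out["nmi"] = (None, 0.0)
        out["uni"] = (None, 0.0)
    if h_r + h_s > 0:
        red = i_rs / (h_r + h_s)
        out["red"] = (red, min(max(2.0 * red, 0.0), 1.0))
    else:
        out["red"] = (None, 0.0)
    if h_max > 0:
        aum = 1.0 - i_rs / h_max
        out["aum"] = (aum, min(max(1.0 - aum, 0.0), 1.0))
    else:
        out["aum"] = (None, 0.0)
    return out


def ncc_raw(r, s):
    """None when undefined (a constant image)."""
    n = len(r)
    mr = sum(r) / n
    ms = sum(s) / n
    vr = sum((a - mr) ** 2 for a in r) / n
    vs = sum((b - ms) ** 2 for b in s) / n
    if vr == 0.0 or vs == 0.0:
        return None
    cov = sum((a - mr) * (b - ms) for a, b in zip(r, s)) / n
    return max(min(cov / math.sqrt(vr * vs), 1.0), -1.0)


def _conditional_groups(r, s):
    groups = {}
    for a, b in zip(r, s):
        groups.setdefault(a, []).append(b)
    return groups


def cor_raw(r, s):
    """Correlation ratio conditioning on exact intensity values of r.
    None when undefined (s constant)."""
    n = len(s)
    ms = sum(s) / n
    var_s = sum((b - ms) ** 2 for b in s) / n
    if var_s == 0.0:
        return None
    acc = 0.0
    for values in _conditional_groups(r, s).values():
        m = sum(values) / len(values)
        v = sum((b - m) ** 2 for b in values) / len(values)
        acc += len(values) * v
    return 1.0 - acc / (n * var_s)


def woo_raw(r, s, eps=1e-8):
    """Woods criterion on exact intensity values of r; None when all levels
    have |mean| <= eps."""
    n = len(r)
    acc = 0.0
    kept = 0
    for values in _conditional_groups(r, s).values():
        m = sum(values) / len(values)
        if abs(m) <= eps:
            continue
        v = sum((b - m) ** 2 for b in values) / len(values)
        acc += len(values) * math.sqrt(v) / m
        kept += 1
    if kept == 0:
        return None
    return 1.0 - acc / n


def ranks_average_ties(column):
    """Within-column ascending ranks, average on ties, from the definition."""
    order = sorted(range(len(column)), key=lambda i: column[i])
    ranks = [0.0] * len(column)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and column[order[j + 1]] == column[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman(col_a, col_b):
    """Spearman correlation = Pearson correlation of the ranks."""
    ra = ranks_average_ties(col_a)
    rb = ranks_average_ties(col_b)
    n = len(ra)
    ma = sum(ra) / n
    mb = sum(rb) / n
    va = sum((x - ma) ** 2 for x in ra) / n
    vb = sum((x - mb) ** 2 for x in rb) / n
    if va == 0.0 or vb == 0.0:
        return None
    cov = sum((x - ma) * (y - mb) for x, y in zip(ra, rb)) / n
    return cov / math.sqrt(va * vb)
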