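"""Direct, unoptimized reference implementations used as oracles.

These follow the written definitions with plain Python loops and stay
independent of the vectorized implementations they check.
"""

import math


def ref_bin_stats(base, aux, b, zero_bin):
    """Sort by base (stable), chunk into bins of b, per-bin mean/population
    sd of aux; optional dedicated bin for base == 0.

    Returns (bins, zero) where bins is a list of (mu, sigma, count) in bin
    order and zero is (mu0, sigma0, count0) or None.
    """
    base = list(base)
    aux = list(aux)
    zero = None
    if zero_bin:
        zvals = [aux[i] for i in range(len(base)) if base[i] == 0.0]
        if zvals:
            mu0 = sum(zvals) / len(zvals)
            sig0 = math.sqrt(sum((v - mu0) ** 2 for v in zvals) / len(zvals))
            zero = (mu0, sig0, len(zvals))
        keep = [i for i in range(len(base)) if base[i] != 0.0]
        base = [base[i] for i in keep]
        aux = [aux[i] for i in keep]
    order = sorted(range(len(base)), key=lambda i: base[i])  # stable, index tiebreak
    aux_sorted = [aux[i] for i in order]
    bins = []
    for start in range(0, len(aux_sorted), b):
        chunk = aux_sorted[start : start + b]
        mu = sum(chunk) / len(chunk)
        sig = math.sqrt(sum((v - mu) ** 2 for v in chunk) / len(chunk))
        bins.append((mu, sig, len(chunk)))
    return bins, zero


def ref_smooth_sigmas(sigmas, b, beta):
    """Weighted average of bin variances over a window of 2w+1 bins,
    weight 2**(-b*|k|/beta) for offset k, w = round(-beta*log(0.01)/(b*log 2))
    floored at 0; out-of-range neighbours dropped (renormalized)."""
    n = len(sigmas)
    w = max(0, round(-beta * math.log(0.01) / (b * math.log(2))))
    out = []
    for j in range(n):
        num = den = 0.0
        for k in range(-w, w + 1):
            if 0 <= j + k < n:
                weight = 2.0 ** (-b * abs(k) / beta)
                num += weight * sigmas[j + k] ** 2
                den += weight
        out.append(math.sqrt(num / den))
    return out


def ref_variance_instability(base_t, aux_t, b, per_position=False):
    """Sort by base_t (stable), B = floor(n/b) full bins, v_j = per-bin sum
    of squared differences; score = pop-var(v) / (pop-var(base_t) * pop-var(aux_t))."""
    n = len(base_t)
    order = sorted(range(n), key=lambda i: base_t[i])
    bs = [base_t[i] for i in order]
    as_ = [aux_t[i] for i in order]
    n_bins = n // b
    v = []
    for j in range(n_bins):
        s = sum((bs[i] - as_[i]) ** 2 for i in range(j * b, (j + 1) * b))
        v.append(s / b if per_position else s)
    vbar = sum(v) / len(v)
    var_v = sum((x - vbar) ** 2 for x in v) / len(v)

    def popvar(xs):
        m = sum(xs) / len(xs)
        return sum((x - m) ** 2 for x in xs) / len(xs)

    return var_v / (popvar(base_t) * popvar(aux_t))


def ref_per_base_values(track):
    """Expand a track to a {(chrom, base_position): value} map."""
    out = {}
    for chrom, start, end, value in zip(track.chroms, track.starts, track.ends, track.values):
        for p in range(int(start), int(end)):
            out[(str(chrom), p)] = value
    return out


def ref_align_per_base(tracks):
    """Brute-force alignment oracle: the per-base value tuples at bases
    covered by every track."""
    maps = [ref_per_base_values(t) for t in tracks]
    common = set(maps[0])
    for m in maps[1:]:
        common &= set(m)
    return {pos: tuple(m[pos] for m in maps) for pos in common}
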