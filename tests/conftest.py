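import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def exhaustive_changepoint_search(y, min_seg):
    """Independent oracle: brute-force (i1, i2) scan using np.polyfit."""
    y = np.asarray(y, dtype=float)
    n = y.size

    def seg_rss(a, b):
        x = np.arange(a, b, dtype=float)
        coef = np.polyfit(x, y[a:b], 1)
        resid = y[a:b] - np.polyval(coef, x)
        return float((resid**2).sum())

    best = (None, None, np.inf)
    for i1 in range(min_seg, n - 2 * min_seg + 1):
        r1 = seg_rss(0, i1)
        for i2 in range(i1 + min_seg, n - min_seg + 1):
            rss = r1 + seg_rss(i1, i2) + seg_rss(i2, n)
            if rss < best[2]:
                best = (i1, i2, rss)
    return best


def brute_force_otsu(counts, n_classes):
    """Independent oracle: direct between-class-variance maximization.

    A float scan shortlists candidates; exact ties (common with integer
    histograms) are then resolved in rational arithmetic toward the
    lowest threshold indices.
    """
    from fractions import Fraction

    counts = np.asarray(counts, dtype=float)
    n = counts.size
    p = counts / counts.sum()
    idx = np.arange(n, dtype=float)

    def score(bounds):
        # bounds: last-bin index of each lower class
        edges = [0] + [b + 1 for b in bounds] + [n]
        s = 0.0
        for a, b in zip(edges[:-1], edges[1:]):
            w = p[a:b].sum()
            if w > 0:
                mu = (p[a:b] * idx[a:b]).sum() / w
                s += w * mu * mu
        return s

    if n_classes == 2:
        cands = [(t,) for t in range(n - 1)]
    else:
        cands = [(t1, t2) for t1 in range(n - 2) for t2 in range(t1 + 1, n - 1)]
    scores = np.array([score(b) for b in cands])
    shortlist = [cands[i] for i in np.flatnonzero(scores >= scores.max() - 1e-8 * (abs(scores.max()) + 1))]
    if len(shortlist) == 1 or not np.allclose(counts, np.round(counts)):
        return shortlist[0], float(scores.max())

    ic = [int(x) for x in np.round(counts)]

    def exact_score(bounds):
        edges = [0] + [b + 1 for b in bounds] + [n]
        s = Fraction(0)
        for a, b in zip(edges[:-1], edges[1:]):
            w = sum(ic[a:b])
            if w > 0:
                m = sum(ic[i] * i for i in range(a, b))
                s += Fraction(m * m, w)
        return s

    best = max(shortlist, key=lambda b: (exact_score(b), [-x for x in b]))
    return best, float(scores.max())


def ks_d_enumeration(a, b):
    """Independent oracle: |F1 - F2| evaluated point-by-point."""
    a = np.sort(np.asarray(a, float))
    b = np.sort(np.asarray(b, float))
    d = 0.0
    for q in np.concatenate((a, b)):
        f1 = np.mean(a <= q)
        f2 = np.mean(b <= q)
        d = max(d, abs(f1 - f2))
    return d
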