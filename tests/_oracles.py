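"""Independent brute-force oracles, deliberately naive and unshared with the
package implementation paths they check."""

import itertools

import numpy as np
from sklearn.svm import SVC


def alff_literal(ts, tr, band):
    """Literal 'FFT, sqrt of power, average in band' on a detrended series."""
    ts = np.asarray(ts, dtype=float)
    n = ts.size
    x = np.arange(n)
    slope, intercept = np.polyfit(x, ts, 1)
    ts = ts - (slope * x + intercept)
    X = np.fft.fft(ts)
    total = 0.0
    count = 0
    for k in range(1, n // 2 + 1):
        f = k / (n * tr)
        if band[0] - 1e-12 <= f <= band[1] + 1e-12:
            power = (2.0 / n) ** 2 * (X[k] * np.conj(X[k])).real
            total += np.sqrt(power)
            count += 1
    if count == 0:
        raise ValueError("no in-band bin")
    return total / count


def auc_pairwise(scores, y):
    """P(score+ > score-) + 0.5 P(tie) by explicit double loop."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == -1]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def mannwhitney_exact_enum(a, b):
    """Exact two-sided Mann-Whitney p by enumerating all group splits."""
    a, b = list(a), list(b)
    pooled = a + b
    n, m = len(a), len(b)

    def u_stat(x, y):
        u = 0.0
        for xi in x:
            for yj in y:
                if xi > yj:
                    u += 1.0
                elif xi == yj:
                    u += 0.5
        return u

    u_obs = u_stat(a, b)
    us = []
    for comb in itertools.combinations(range(n + m), n):
        ga = [pooled[i] for i in comb]
        gb = [pooled[i] for i in range(n + m) if i not in comb]
        us.append(u_stat(ga, gb))
    us = np.array(us)
    p_le = (us <= u_obs + 1e-12).mean()
    p_ge = (us >= u_obs - 1e-12).mean()
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def bh_stepup(pvals, q):
    """Benjamini-Hochberg step-up flags, written from the definition."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    flags = np.zeros(m, dtype=bool)
    flags[order[:k_star]] = True
    return flags


def _loocv_accuracy_naive(X, y, sids, cols, C=1.0, scale="minmax"):
    """Subject-level LOOCV with per-fold min-max scaling, written naively."""
    X = np.asarray(X, dtype=float)[:, cols]
    y = np.asarray(y)
    correct = 0
    for sid in sorted(set(sids)):
        te = [i for i in range(len(y)) if sids[i] == sid]
        tr = [i for i in range(len(y)) if sids[i] != sid]
        Xtr, Xte = X[tr].copy(), X[te].copy()
        if scale == "minmax":
            for j in range(Xtr.shape[1]):
                lo, hi = Xtr[:, j].min(), Xtr[:, j].max()
                if hi > lo:
                    Xtr[:, j] = (Xtr[:, j] - lo) / (hi - lo)
                    Xte[:, j] = (Xte[:, j] - lo) / (hi - lo)
                else:
                    Xtr[:, j] = 0.5
                    Xte[:, j] = 0.5
        clf = SVC(kernel="linear", C=C)
        clf.fit(Xtr, y[tr])
        for i, row in zip(te, Xte):
            d = clf.decision_function(row[None, :])[0]
            if (1 if d >= 0 else -1) == y[i]:
                correct += 1
    return correct / len(y)


def rfe_greedy_simulator(X, y, sids, region_labels, C=1.0, scale="minmax"):
    """Independent simulation of the guarded greedy batch-elimination rule.

    Per round: accuracy_0 on the current set; accuracy_i without each single
    feature; batch-remove every feature with accuracy_i >= accuracy_0 (if the
    batch would empty the set, keep the single feature whose removal scored
    highest, ties to the lowest label); revert and stop if the joint accuracy
    after the batch drops below accuracy_0.
    """
    eps = 1e-12
    region_labels = list(region_labels)
    current = list(region_labels)
    col = {r: i for i, r in enumerate(region_labels)}
    acc0 = _loocv_accuracy_naive(X, y, sids, [col[r] for r in current], C, scale)
    trace = [acc0]
    while len(current) > 1:
        acc_wo = {}
        for r in current:
            cols = [col[s] for s in current if s != r]
            acc_wo[r] = _loocv_accuracy_naive(X, y, sids, cols, C, scale)
        removable = [r for r in current if acc_wo[r] >= acc0 - eps]
        if not removable:
            break
        if len(removable) == len(current):
            keep = max(current, key=lambda r: (acc_wo[r], -r))
            removable = [r for r in current if r != keep]
        tentative = [r for r in current if r not in removable]
        new_acc = _loocv_accuracy_naive(X, y, sids,
                                        [col[r] for r in tentative], C, scale)
        if new_acc < acc0 - eps:
            break
        current, acc0 = tentative, new_acc
        trace.append(acc0)
    return current, trace
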