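"""Independent brute-force oracles for the encoders and metrics.

Everything here is written as plain nested loops over the defining formulas,
deliberately sharing no code with the package implementation, so agreement
between the two is a meaningful check.
"""

from __future__ import annotations

import math

RESIDUES = sorted("ACDEFGHIKLMNPQRSTVWY")


def props_of(seq, table):
    """L x 13 list-of-lists profile from a PropertyTable."""
    idx = {r: i for i, r in enumerate(table.residues)}
    return [[float(table.values[idx[r]][k]) for k in range(13)] for r in seq]


def oracle_pseaac(seq, lam, table, w=0.05):
    L = len(seq)
    P = props_of(seq, table)
    comp = [seq.count(r) / L for r in RESIDUES]
    thetas = []
    for j in range(1, lam + 1):
        tot = 0.0
        for i in range(L - j):
            tot += sum((P[i + j][k] - P[i][k]) ** 2 for k in range(13)) / 13.0
        thetas.append(tot / (L - j))
    denom = sum(comp) + w * sum(thetas)
    return [c / denom for c in comp] + [w * t / denom for t in thetas]


def oracle_ac(seq, lam, table):
    L = len(seq)
    P = props_of(seq, table)
    out = []
    for k in range(13):
        mean = sum(P[i][k] for i in range(L)) / L
        for d in range(1, lam + 1):
            s = 0.0
            for i in range(L - d):
                s += (P[i][k] - mean) * (P[i + d][k] - mean)
            out.append(s / (L - d))
    return out


def oracle_ad(seq, lam, table):
    L = len(seq)
    P = props_of(seq, table)
    mb, moran, geary = [], [], []
    for k in range(13):
        mean = sum(P[i][k] for i in range(L)) / L
        col = [P[i][k] for i in range(L)]
        # constant column => zero variance by convention (exact test)
        ss = 0.0 if min(col) == max(col) else sum((v - mean) ** 2 for v in col)
        for d in range(1, lam + 1):
            s_mb = sum(P[i][k] * P[i + d][k] for i in range(L - d))
            mb.append(s_mb / (L - d))
            if ss == 0:
                moran.append(0.0)
            else:
                num = sum((P[i][k] - mean) * (P[i + d][k] - mean) for i in range(L - d))
                moran.append((num / (L - d)) / (ss / L))
            denom_g = ss / (L - 1) if L > 1 else 0.0
            if denom_g == 0:
                geary.append(0.0)
            else:
                num = sum((P[i][k] - P[i + d][k]) ** 2 for i in range(L - d))
                geary.append((num / (2 * (L - d))) / denom_g)
    return mb + moran + geary


def oracle_ct(seq, cmap):
    c = [cmap.mapping[r] for r in seq]
    counts = [0] * 343
    for i in range(len(seq) - 2):
        counts[(c[i] - 1) * 49 + (c[i + 1] - 1) * 7 + (c[i + 2] - 1)] += 1
    lo, hi = min(counts), max(counts)
    return [(v - lo) / hi for v in counts]


def _ld_regions(L):
    fracs = [
        (0.0, 0.25), (0.25, 0.5), (0.5, 0.75), (0.75, 1.0),
        (0.0, 0.5), (0.5, 1.0), (0.25, 0.75),
        (0.0, 0.75), (0.25, 1.0), (0.125, 0.875),
    ]
    out = []
    for f0, f1 in fracs:
        start = int(round(f0 * L))
        end = max(int(round(f1 * L)), start + 1)
        out.append((min(start, L - 1), min(end, L)))
    return out


def oracle_ld(seq, cmap):
    classes = [cmap.mapping[r] for r in seq]
    out = []
    pairs = [(a, b) for a in range(1, 8) for b in range(a + 1, 8)]
    for start, end in _ld_regions(len(seq)):
        reg = classes[start:end]
        n = len(reg)
        for cls in range(1, 8):
            out.append(reg.count(cls) / n)
        for a, b in pairs:
            cnt = 0
            for i in range(n - 1):
                if {reg[i], reg[i + 1]} == {a, b}:
                    cnt += 1
            out.append(cnt / (n - 1) if n > 1 else 0.0)
        for cls in range(1, 8):
            pos = [i + 1 for i, v in enumerate(reg) if v == cls]
            if not pos:
                out.extend([0.0] * 5)
                continue
            m = len(pos)
            picks = [
                pos[0],
                pos[math.ceil(0.25 * m) - 1],
                pos[math.ceil(0.5 * m) - 1],
                pos[math.ceil(0.75 * m) - 1],
                pos[-1],
            ]
            out.extend(p / n for p in picks)
    return out


def oracle_mmi(seq, cmap):
    c = [cmap.mapping[r] - 1 for r in seq]
    L = len(c)
    f1 = [c.count(a) / L for a in range(7)]

    def pair_freq(a, b):
        cnt = 0
        for i in range(L - 1):
            if sorted((c[i], c[i + 1])) == sorted((a, b)):
                cnt += 1
        return cnt / (L - 1)

    def triple_freq(a, b, d):
        cnt = 0
        for i in range(L - 2):
            if sorted((c[i], c[i + 1], c[i + 2])) == sorted((a, b, d)):
                cnt += 1
        return cnt / (L - 2)

    def nlog(p, q):
        if p <= 0 or q <= 0:
            return 0.0
        return -p * math.log(p / q)

    def H1(a):
        return nlog(f1[a], 1.0)

    def Hcond(a, b):
        return nlog(pair_freq(a, b), f1[b])

    def I2(a, b):
        return H1(a) - Hcond(a, b)

    out = []
    for a in range(7):
        for b in range(a, 7):
            for d in range(b, 7):
                h_abc = nlog(triple_freq(a, b, d), pair_freq(b, d))
                out.append(I2(a, b) - (Hcond(a, d) - h_abc))
    for a in range(7):
        for b in range(a, 7):
            out.append(I2(a, b))
    out.extend(f1)
    return out


def oracle_metrics(truth, probs, threshold=0.5):
    """Confusion-matrix metrics from first principles."""
    tp = fp = tn = fn = 0
    for t, p in zip(truth, probs):
        pred = 1 if p >= threshold else 0
        if t == 1 and pred == 1:
            tp += 1
        elif t == 0 and pred == 1:
            fp += 1
        elif t == 0 and pred == 0:
            tn += 1
        else:
            fn += 1
    n = tp + fp + tn + fn

    def div(a, b):
        return a / b if b else 0.0

    pre = div(tp, tp + fp)
    se = div(tp, tp + fn)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)) or 0.0
    return {
        "TP": tp, "FP": fp, "TN": tn, "FN": fn,
        "ACC": div(tp + tn, n),
        "PRE": pre,
        "SE": se,
        "SP": div(tn, tn + fp),
        "F1": div(2 * pre * se, pre + se),
        "MCC": div(tp * tn - fp * fn, mcc_den),
    }


def oracle_auc_mannwhitney(truth, probs):
    """AUC as the Mann-Whitney U statistic / (n_pos * n_neg)."""
    pos = [p for t, p in zip(truth, probs) if t == 1]
    neg = [p for t, p in zip(truth, probs) if t == 0]
    u = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u / (len(pos) * len(neg))
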