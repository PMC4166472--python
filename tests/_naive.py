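"""Naive loop-based nearest-shrunken-centroid oracle.

Deliberately independent of the package implementation: plain Python
loops transcribing the defining formulas symbol by symbol, used to
verify every intermediate quantity (class centroids, pooled sd, d_kj,
shrunken centroids, discriminants, posteriors) on small fixtures.
"""

import math


def naive_fit(X, y, m_convention="minus"):
    """X: list of p feature rows, each a list of n values; y: n labels."""
    p, n = len(X), len(X[0])
    classes = sorted(set(y))
    K = len(classes)
    n_k = {c: sum(1 for lab in y if lab == c) for c in classes}

    class_mean = [[0.0] * p for _ in classes]
    overall = [0.0] * p
    for j in range(p):
        overall[j] = sum(X[j]) / n
        for ki, c in enumerate(classes):
            vals = [X[j][i] for i in range(n) if y[i] == c]
            class_mean[ki][j] = sum(vals) / len(vals)

    s = [0.0] * p
    for j in range(p):
        ssq = 0.0
        for ki, c in enumerate(classes):
            for i in range(n):
                if y[i] == c:
                    ssq += (X[j][i] - class_mean[ki][j]) ** 2
        s[j] = math.sqrt(ssq / (n - K))
    s_sorted = sorted(s)
    mid = p // 2
    s0 = s_sorted[mid] if p % 2 == 1 else 0.5 * (s_sorted[mid - 1] + s_sorted[mid])
    if s0 <= 0:
        s0 = 1e-6

    m = {}
    for c in classes:
        if m_convention == "minus":
            m[c] = math.sqrt(1.0 / n_k[c] - 1.0 / n)
        else:
            m[c] = math.sqrt(1.0 / n_k[c] + 1.0 / n)
    priors = {c: n_k[c] / n for c in classes}

    d = [[0.0] * p for _ in classes]
    for ki, c in enumerate(classes):
        for j in range(p):
            d[ki][j] = (class_mean[ki][j] - overall[j]) / (m[c] * (s[j] + s0))

    return {
        "classes": classes, "class_mean": class_mean, "overall": overall,
        "s": s, "s0": s0, "m": m, "priors": priors, "d": d,
    }


def naive_shrunken_centroids(fit, delta):
    classes, p = fit["classes"], len(fit["overall"])
    out = [[0.0] * p for _ in classes]
    for ki, c in enumerate(classes):
        for j in range(p):
            dkj = fit["d"][ki][j]
            dprime = math.copysign(max(abs(dkj) - delta, 0.0), dkj)
            out[ki][j] = fit["overall"][j] + fit["m"][c] * (fit["s"][j] + fit["s0"]) * dprime
    return out


def naive_predict(fit, X, delta):
    """Returns (labels, deltas, posteriors) for samples given as columns of X."""
    cent = naive_shrunken_centroids(fit, delta)
    classes = fit["classes"]
    p, n = len(X), len(X[0])
    labels, all_delta, all_post = [], [], []
    for i in range(n):
        deltas = []
        for ki, c in enumerate(classes):
            dist = 0.0
            for j in range(p):
                dist += (X[j][i] - cent[ki][j]) ** 2 / (fit["s"][j] + fit["s0"]) ** 2
            deltas.append(dist - 2.0 * math.log(fit["priors"][c]))
        dmin = min(deltas)
        w = [math.exp(-0.5 * (dd - dmin)) for dd in deltas]
        tot = sum(w)
        post = [x / tot for x in w]
        labels.append(classes[deltas.index(dmin)])
        all_delta.append(deltas)
        all_post.append(post)
    return labels, all_delta, all_post


def naive_anova_adjusted_r2(y, groups):
    """Longhand one-way ANOVA adjusted R-squared."""
    n = len(y)
    levels = sorted(set(groups))
    k = len(levels)
    grand = sum(y) / n
    ss_total = sum((v - grand) ** 2 for v in y)
    ss_within = 0.0
    for lev in levels:
        sub = [v for v, g in zip(y, groups) if g == lev]
        mean = sum(sub) / len(sub)
        ss_within += sum((v - mean) ** 2 for v in sub)
    r2 = 1.0 - ss_within / ss_total
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k)


def naive_kappa(labels_a, labels_b):
    """Cohen's kappa from first principles on paired labels."""
    n = len(labels_a)
    p_o = sum(1 for a, b in zip(labels_a, labels_b) if a == b) / n
    cats = sorted(set(labels_a) | set(labels_b))
    p_e = 0.0
    for c in cats:
        pa = sum(1 for a in labels_a if a == c) / n
        pb = sum(1 for b in labels_b if b == c) / n
        p_e += pa * pb
    return (p_o - p_e) / (1.0 - p_e), p_o, p_e


def naive_gene_cn(gene_start, gene_end, segments):
    """Per-basepair oracle for segment-to-gene summarization.

    ``segments`` is a list of (start, end, log_ratio) in 1-based closed
    coordinates.  Averages the log-ratio over every covered basepair of
    the gene span; returns None if no basepair is covered.
    """
    total, covered = 0.0, 0
    for bp in range(gene_start, gene_end + 1):
        for s, e, lr in segments:
            if s <= bp <= e:
                total += lr
                covered += 1
                break
    if covered == 0:
        return None
    return total / covered
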