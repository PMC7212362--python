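"""Independent loop-based reference implementations used as test oracles.

Deliberately written as literal triple loops over the defining sums, with
no shared code with the package, so agreement is meaningful.
"""

import numpy as np


def naive_degrees(M, degree_mode):
    n, q = M.shape
    if degree_mode == "binary":
        dm = np.array([(M[i, :] > 0).sum() for i in range(n)], dtype=float)
        dd = np.array([(M[:, j] > 0).sum() for j in range(q)], dtype=float)
    else:
        dm = np.array([M[i, :].sum() for i in range(n)], dtype=float)
        dd = np.array([M[:, j].sum() for j in range(q)], dtype=float)
    return dm, dd


def naive_augment_mirna(A, SM, delta):
    n, q = A.shape
    out = np.zeros((n, q))
    for i in range(n):
        for j in range(q):
            if A[i, j] == 1:
                out[i, j] = 1.0
            else:
                best = 0.0
                for t in range(n):
                    if A[t, j] == 1 and SM[i, t] > delta:
                        best = max(best, SM[i, t])
                out[i, j] = best
    return out


def naive_augment_disease(A, SD, eta):
    n, q = A.shape
    out = np.zeros((n, q))
    for i in range(n):
        for j in range(q):
            if A[i, j] == 1:
                out[i, j] = 1.0
            else:
                best = 0.0
                for t in range(q):
                    if A[i, t] == 1 and SD[j, t] > eta:
                        best = max(best, SD[j, t])
                out[i, j] = best
    return out


def naive_scores(A, SM, SD, delta, eta, gamma, degree_mode="binary"):
    """Two-pass biased heat conduction scores, all loops."""
    n, q = A.shape

    Ap = naive_augment_mirna(A, SM, delta)
    dm, dd = naive_degrees(Ap, degree_mode)
    fd = np.zeros(q)
    for j in range(q):
        for i in range(n):
            if dm[i] > 0:
                fd[j] += Ap[i, j] * 1.0 / dm[i]
    fm1 = np.zeros(n)
    for i in range(n):
        if dm[i] == 0:
            continue
        total = 0.0
        for j in range(q):
            if dd[j] > 0:
                total += Ap[i, j] * fd[j] / dd[j]
        fm1[i] = total / dm[i] ** gamma

    App = naive_augment_disease(A, SD, eta)
    dm2, dd2 = naive_degrees(App, degree_mode)
    fm2 = np.zeros(n)
    for i in range(n):
        for j in range(q):
            if dd2[j] > 0:
                fm2[i] += App[i, j] * 1.0 / dd2[j]
    fd2 = np.zeros(q)
    for j in range(q):
        if dd2[j] == 0:
            continue
        total = 0.0
        for i in range(n):
            if dm2[i] > 0:
                total += App[i, j] * fm2[i] / dm2[i]
        fd2[j] = total / dd2[j] ** gamma

    S = np.zeros((n, q))
    for i in range(n):
        for j in range(q):
            S[i, j] = (fm1[i] + fd2[j]) / 2.0
    return S


def naive_gip(profiles, bandwidth_prime):
    """Pairwise-loop Gaussian interaction-profile kernel."""
    k = profiles.shape[0]
    mean_sq = np.mean([np.dot(p, p) for p in profiles])
    gamma = bandwidth_prime / mean_sq
    K = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            d = profiles[a] - profiles[b]
            K[a, b] = np.exp(-gamma * np.dot(d, d))
    return K


def naive_mw_auc(positive_scores, candidate_scores):
    """Exhaustive pairwise Mann-Whitney statistic with half-credit ties."""
    wins = ties = 0
    for p in positive_scores:
        for c in candidate_scores:
            if p > c:
                wins += 1
            elif p == c:
                ties += 1
    return (wins + 0.5 * ties) / (len(positive_scores) * len(candidate_scores))
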