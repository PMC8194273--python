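"""Independent brute-force reference implementations used only by tests.

Everything here is written in deliberately naive scalar loops, straight
from the defining formulas, so it shares no code path with the package.
"""

from __future__ import annotations

import cmath
import math

import numpy as np


def oracle_spectral_matrices(coeffs, noise_cov, fs, freqs):
    """A(f), H(f), S(f) by scalar evaluation of the lag polynomial."""
    coeffs = np.asarray(coeffs, dtype=float)
    p, m, _ = coeffs.shape
    A_list, H_list, S_list = [], [], []
    for f in freqs:
        A = np.zeros((m, m), dtype=complex)
        for i in range(m):
            for j in range(m):
                acc = complex(1.0 if i == j else 0.0)
                for k in range(1, p + 1):
                    acc -= coeffs[k - 1, i, j] * cmath.exp(-2j * math.pi * f * k / fs)
                A[i, j] = acc
        H = np.linalg.inv(A)
        S = H @ np.asarray(noise_cov) @ H.conj().T
        A_list.append(A)
        H_list.append(H)
        S_list.append(S)
    return A_list, H_list, S_list


def oracle_gpdc(coeffs, noise_cov, fs, freqs):
    """GPDC by literal scalar loops; diagonal zeroed."""
    A_list, _, _ = oracle_spectral_matrices(coeffs, noise_cov, fs, freqs)
    m = np.asarray(noise_cov).shape[0]
    out = np.zeros((len(freqs), m, m))
    for fi, A in enumerate(A_list):
        for j in range(m):
            denom = 0.0
            for k in range(m):
                denom += abs(A[k, j]) ** 2 / noise_cov[k][k]
            for i in range(m):
                if i == j:
                    continue
                out[fi, i, j] = (
                    (1.0 / math.sqrt(noise_cov[i][i])) * abs(A[i, j])
                    / math.sqrt(denom)
                )
    return out


def oracle_ddtf(coeffs, noise_cov, fs, freqs):
    """dDTF = full-frequency DTF x partial coherence, scalar loops."""
    _, H_list, S_list = oracle_spectral_matrices(coeffs, noise_cov, fs, freqs)
    m = np.asarray(noise_cov).shape[0]
    nf = len(freqs)
    # ffDTF denominator per sink row i: sum over all freqs and all sources
    denom = [0.0] * m
    for i in range(m):
        for H in H_list:
            for k in range(m):
                denom[i] += abs(H[i, k]) ** 2
    out = np.zeros((nf, m, m))
    for fi in range(nf):
        H, S = H_list[fi], S_list[fi]
        P = np.linalg.inv(S)
        for i in range(m):
            for j in range(m):
                if i == j:
                    continue
                eta = math.sqrt(abs(H[i, j]) ** 2 / denom[i])
                chi = abs(P[i, j]) / math.sqrt(P[i, i].real * P[j, j].real)
                out[fi, i, j] = eta * chi
    return out


def oracle_best_split(X, y, candidate_features, min_leaf):
    """Exhaustive best split: every feature x every midpoint, no shortcuts.

    Returns (feature, threshold, decrease) or None; ties resolved toward
    the lowest feature index, then the lowest threshold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 2 * min_leaf:
        return None

    def gini(labels):
        if len(labels) == 0:
            return 0.0
        p = np.mean(labels)
        return p * (1 - p) + (1 - p) * p

    parent = gini(y)
    if parent == 0:
        return None
    best = None
    for feat in candidate_features:
        vals = sorted(set(X[:, feat]))
        for a, b in zip(vals[:-1], vals[1:]):
            thr = (a + b) / 2
            left = y[X[:, feat] <= thr]
            right = y[X[:, feat] > thr]
            if len(left) < min_leaf or len(right) < min_leaf:
                continue
            weighted = (len(left) * gini(left) + len(right) * gini(right)) / n
            dec = parent - weighted
            if dec <= 1e-12:
                continue
            if best is None or dec > best[2] + 1e-12:
                best = (feat, thr, dec)
    return best


def oracle_auc(scores, labels):
    """AUC as the normalised count of concordant pairs (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
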