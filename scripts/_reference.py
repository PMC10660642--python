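"""Straight-line per-element reference for the message-passing update,
kept deliberately independent of the vectorized implementation."""

import numpy as np


def naive_panda(motif, ppi, coexpr, alpha, iters):
    def nz(W):
        W = np.array(W, float)
        mu, sd = W.mean(), W.std()
        ov = (W - mu) / sd if sd > 0 else np.zeros_like(W)
        out = np.zeros_like(W)
        nr, nc = W.shape
        for i in range(nr):
            for j in range(nc):
                rsd, csd = W[i].std(), W[:, j].std()
                rz = (W[i, j] - W[i].mean()) / rsd if rsd > 0 else ov[i, j]
                cz = (W[i, j] - W[:, j].mean()) / csd if csd > 0 else ov[i, j]
                out[i, j] = 0.5 * (rz + cz)
        return out

    def tan(X, Y):
        out = np.zeros((X.shape[0], Y.shape[0]))
        for i in range(X.shape[0]):
            for j in range(Y.shape[0]):
                ip = float(np.dot(X[i], Y[j]))
                d2 = float(np.dot(X[i], X[i]) + np.dot(Y[j], Y[j]) - abs(ip))
                out[i, j] = ip / np.sqrt(d2) if d2 > 0 else 0.0
        return out

    def stab(S, inner, step):
        n = S.shape[0]
        if n < 2:
            return S
        off = np.array([[S[i, k] for k in range(n) if k != i] for i in range(n)])
        mu, sd = off.mean(), off.std()
        if sd > 0:
            diag = np.diag(S).copy()
            S = (S - mu) / sd
            for i in range(n):
                S[i, i] = diag[i]
        off = np.array([[S[i, k] for k in range(n) if k != i] for i in range(n)])
        for i in range(n):
            S[i, i] = off[i].std() * inner * np.exp(2 * alpha * step)
        return S

    W, P, C = nz(motif), nz(ppi), nz(coexpr)
    for it in range(1, iters + 1):
        R = tan(P, W.T)
        A = tan(W, C)
        Wn = (1 - alpha) * W + alpha * 0.5 * (R + A)
        P = (1 - alpha) * P + alpha * stab(tan(Wn, Wn), C.shape[0], it)
        C = (1 - alpha) * C + alpha * stab(tan(Wn.T, Wn.T), W.shape[0], it)
        W = Wn
    return W
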