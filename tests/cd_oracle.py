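"""Independent brute-force elastic-net oracle used to verify the path solver.

Plain cyclic coordinate descent on ``||y - X b||^2 + eta ||b||_1 +
gamma ||b||_2^2`` run to a very tight tolerance.  Deliberately naive and
independent of the package's LARS-based implementation.
"""

import numpy as np


def cd_elastic_net(X, y, eta, gamma, max_iter=200_000, tol=1e-12):
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    b = np.zeros(p)
    G = X.T @ X
    Xty = X.T @ y
    denom = np.diag(G) + gamma
    for _ in range(max_iter):
        delta = 0.0
        for j in range(p):
            z = Xty[j] - G[j] @ b + G[j, j] * b[j]
            bj = np.sign(z) * max(abs(z) - eta / 2.0, 0.0) / denom[j]
            delta = max(delta, abs(bj - b[j]))
            b[j] = bj
        if delta < tol:
            break
    return b
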