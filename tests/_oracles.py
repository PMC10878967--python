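"""Independent oracles used by the unit and acceptance tests.

These deliberately avoid the package's computational shortcuts: the
GEE oracle builds the full block-diagonal working covariance and
inverts it densely, and applies the Mancl-DeRouen correction through
the explicit n_i x n_i leverage matrix (I - H_i)^{-1}; the Robson
oracle is a set-membership lookup rather than an if-chain.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------
# dense GEE


def _mean(X, beta, family):
    eta = X @ beta
    if family == "poisson":
        mu = np.exp(eta)
        return mu, mu, mu  # mu, dmu/deta, v(mu)
    return eta, np.ones_like(eta), np.ones_like(eta)


def _alpha_moment(resid, idx_of, sizes, phi):
    num = 0.0
    pairs = 0.0
    for i, n_i in enumerate(sizes):
        r = resid[idx_of == i]
        num += r.sum() ** 2 - (r**2).sum()
        pairs += n_i * (n_i - 1)
    if pairs == 0 or phi < 1e-12:
        return 0.0
    alpha = num / (phi * pairs)
    lo = -0.95 / (max(sizes) - 1.0) if max(sizes) > 1 else 0.0
    return float(np.clip(alpha, lo, 1.0 - 1e-10))


def dense_gee(
    X,
    y,
    clusters,
    family="poisson",
    correlation="exchangeable",
    tol=1e-8,
    max_iter=100,
):
    """Full-matrix IRLS solve of the GEE score equations.

    Returns (beta, alpha, phi, cov_model, cov_sandwich, cov_md).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    labels, idx_of = np.unique(np.asarray(clusters), return_inverse=True)
    sizes = np.bincount(idx_of)
    n, p = X.shape

    beta = np.zeros(p)
    if family == "poisson":
        beta[0] = np.log(max(y.mean(), 1e-8))
    else:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)

    def cluster_matrices(beta):
        mu, dmu, v = _mean(X, beta, family)
        resid = (y - mu) / np.sqrt(v)
        phi = float(np.mean(resid**2))
        alpha = (
            _alpha_moment(resid, idx_of, sizes, phi)
            if correlation == "exchangeable"
            else 0.0
        )
        out = []
        for i in range(len(labels)):
            sel = idx_of == i
            n_i = sizes[i]
            R = np.full((n_i, n_i), alpha) + (1 - alpha) * np.eye(n_i)
            Ah = np.diag(np.sqrt(v[sel]))
            V = max(phi, 1e-12) * Ah @ R @ Ah
            D = np.diag(dmu[sel]) @ X[sel]
            e = y[sel] - mu[sel]
            out.append((D, np.linalg.inv(V), e))
        return out, alpha, phi

    for _ in range(max_iter):
        mats, alpha, phi = cluster_matrices(beta)
        A = sum(D.T @ Vi @ D for D, Vi, _ in mats)
        u = sum(D.T @ Vi @ e for D, Vi, e in mats)
        delta = np.linalg.solve(A, u)
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            break

    mats, alpha, phi = cluster_matrices(beta)
    A = sum(D.T @ Vi @ D for D, Vi, _ in mats)
    Ainv = np.linalg.inv(A)
    M_sw = np.zeros((p, p))
    M_md = np.zeros((p, p))
    for D, Vi, e in mats:
        q = D.T @ Vi @ e
        M_sw += np.outer(q, q)
        H = D @ Ainv @ D.T @ Vi
        e_md = np.linalg.solve(np.eye(len(e)) - H, e)
        q_md = D.T @ Vi @ e_md
        M_md += np.outer(q_md, q_md)
    return (
        beta,
        alpha,
        phi,
        Ainv,
        Ainv @ M_sw @ Ainv,
        Ainv @ M_md @ Ainv,
    )


# ---------------------------------------------------------------------
# Robson lookup oracle


def robson_oracle(parity, prev_cs, onset, presentation, n_fetuses, ga_weeks):
    """Set-membership encoding of the WHO ten-group table.

    Returns the group 1-10, or None for an invariant-violating cell
    (previous cesareans exceeding parity).
    """
    if prev_cs > parity:
        return None
    multiple = n_fetuses >= 2
    term = ga_weeks >= 37
    nullip = parity == 0
    if multiple:
        return 8
    lookup = {
        ("transverse_oblique",): 9,
        ("breech", True): 6,
        ("breech", False): 7,
    }
    if presentation == "transverse_oblique":
        return lookup[("transverse_oblique",)]
    if presentation == "breech":
        return lookup[("breech", nullip)]
    # cephalic singletons below
    if not term:
        return 10
    if prev_cs >= 1:
        return 5
    spontaneous = onset == "spontaneous"
    return {
        (True, True): 1,
        (True, False): 2,
        (False, True): 3,
        (False, False): 4,
    }[(nullip, spontaneous)]
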