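"""Shared independent oracles for the test suite."""

import numpy as np

from hologen.rkhs import _fixed_design


def blup_oracle(records, y, kernels, var_k, var_pen, var_e):
    """Henderson mixed-model solution via the V-inverse (GLS) route.

    Independent of the sampler's eigenbasis/precision algebra: builds the
    phenotypic covariance V on observed records and applies the standard
    BLUP projections.
    """
    y = np.asarray(y, dtype=float)
    obs = np.isfinite(y)
    W, _ = _fixed_design(records)
    pen_levels, pen_codes = np.unique(records["pen"].to_numpy(), return_inverse=True)
    Zp = np.eye(len(pen_levels))[pen_codes]
    V = var_e * np.eye(obs.sum()) + var_pen * (Zp @ Zp.T)[np.ix_(obs, obs)]
    for name, K in kernels.items():
        V += var_k[name] * K.matrix[np.ix_(obs, obs)]
    Vi = np.linalg.inv(V)
    Wo = W[obs]
    beta = np.linalg.solve(Wo.T @ Vi @ Wo, Wo.T @ Vi @ y[obs])
    resid = y[obs] - Wo @ beta
    u = {
        name: var_k[name] * K.matrix[:, obs] @ Vi @ resid
        for name, K in kernels.items()
    }
    pen = var_pen * Zp[obs].T @ Vi @ resid
    pred = W @ beta + Zp @ pen
    for v in u.values():
        pred = pred + v
    return beta, u, pen, pred
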