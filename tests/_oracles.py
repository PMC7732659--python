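"""Independent oracles shared across the test suite.

These deliberately avoid the package's own code paths: the mixed-model
oracle assembles the GLS normal equations person by person, and the data
generator draws straight from the two-level model without touching the
sensor pipeline.
"""

import numpy as np
import pandas as pd


def make_occasions(
    rng,
    n_persons=40,
    n_occ=20,
    beta=(13.5, 7.0, 11.5),
    sds=(3.29, 5.43, 8.88),
    resid_sd=10.53,
    p_single=0.4,
    p_group=0.1,
):
    """Direct draw from the two-level generative model (no sensor pipeline)."""
    rows = []
    for i in range(n_persons):
        r0, r1, r2 = rng.normal(0, sds[0]), rng.normal(0, sds[1]), rng.normal(0, sds[2])
        for _ in range(n_occ):
            u = rng.random()
            s, g = int(u < p_single), int(p_single <= u < p_single + p_group)
            y = beta[0] + r0 + (beta[1] + r1) * s + (beta[2] + r2) * g + rng.normal(0, resid_sd)
            rows.append({"person_id": f"P{i:03d}", "offendedness": y,
                         "single_chat": s, "group_chat": g})
    return pd.DataFrame(rows)


def gls_fixed_effects(df, tau0, tau1, tau2, sigma2):
    """Brute-force GLS with known variance components.

    beta = (X' V^-1 X)^-1 X' V^-1 y, with V built person by person as
    V_i = Z_i diag(tau0, tau1, tau2) Z_i' + sigma2 I.
    """
    X_cols = ["const", "single_chat", "group_chat"]
    df = df.assign(const=1.0)
    xtvx = np.zeros((3, 3))
    xtvy = np.zeros(3)
    for _, grp in df.groupby("person_id"):
        X = grp[X_cols].to_numpy(float)
        Z = X.copy()  # identical design: intercept + both dummies
        y = grp["offendedness"].to_numpy(float)
        V = Z @ np.diag([tau0, tau1, tau2]) @ Z.T + sigma2 * np.eye(len(grp))
        Vi = np.linalg.inv(V)
        xtvx += X.T @ Vi @ X
        xtvy += X.T @ Vi @ y
    return np.linalg.solve(xtvx, xtvy)


def normal_equations_r2(y, X):
    """Independent least-squares R^2 via the normal equations."""
    y = np.asarray(y, float)
    X1 = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(X1.T @ X1, X1.T @ y)
    resid = y - X1 @ beta
    return 1.0 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
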