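"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles against the
long-format data frame — explicit loops over observation pairs, dense n x n
linear algebra — and never reuses the package's stratified engine, so the
tests compare two independent routes to the same quantities.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg as la


def dense_design(frame, time_coding: str):
    """Fixed-effects design matrix built directly from the long frame."""
    conds = np.sort(frame["condition"].unique())
    periods = np.sort(frame["period"].unique())
    cols = [np.ones(len(frame))]
    for c in conds[1:]:
        cols.append((frame["condition"] == c).to_numpy(float))
    if time_coding == "categorical":
        for j in periods[1:]:
            cols.append((frame["period"] == j).to_numpy(float))
        for c in conds[1:]:
            for j in periods[1:]:
                cols.append(((frame["period"] == j) & (frame["condition"] == c)).to_numpy(float))
    else:
        tv = frame["time"].to_numpy(float)
        cols.append(tv)
        for c in conds[1:]:
            cols.append(tv * (frame["condition"] == c).to_numpy(float))
    return np.column_stack(cols)


def dense_covariance(frame, terms, theta_names, theta, has_residual):
    """Full n x n marginal covariance assembled pair-by-pair from the model terms."""
    n = len(frame)
    grp = frame["group_id"].to_numpy()
    mem = frame["member_id"].to_numpy()
    per = frame["period"].to_numpy()
    tv = frame["time"].to_numpy(float)
    th = dict(zip(theta_names, theta))
    V = np.zeros((n, n))
    same_group = grp[:, None] == grp[None, :]
    same_member = mem[:, None] == mem[None, :]
    for term in terms:
        s = "g" if term.level == "group" else "m"
        same = same_group if term.level == "group" else same_member
        if term.kind == "intercept":
            V += th[f"sigma2_{s}"] * same
        elif term.kind == "time_categorical":
            V += th[f"sigma2_t{s}"] * (same & (per[:, None] == per[None, :]))
        elif term.kind == "time_un":
            pre = "G_un" if s == "g" else "R_un"
            periods = np.sort(np.unique(per))
            for j in periods:
                for k in periods[periods <= j]:
                    pat = same & (
                        ((per[:, None] == j) & (per[None, :] == k))
                        | ((per[:, None] == k) & (per[None, :] == j))
                    )
                    V += th[f"{pre}({j},{k})"] * pat
        elif term.kind in ("rc_un", "rc_vc"):
            V += th[f"sigma2_{s}"] * same
            V += th[f"sigma2_t(lin){s}"] * same * tv[:, None] * tv[None, :]
            if term.kind == "rc_un":
                V += th[f"cov_{s}_ts"] * same * (tv[:, None] + tv[None, :])
        elif term.kind == "un1":
            for j in np.sort(np.unique(per)):
                pat = same & (per[:, None] == j) & (per[None, :] == j)
                V += th[f"R_un1({j})"] * pat
        else:  # pragma: no cover
            raise ValueError(term.kind)
    if has_residual:
        V += th["sigma2_e"] * np.eye(n)
    return V


def dense_reml_loglik(frame, time_coding, terms, theta_names, theta, has_residual):
    """Direct REML log-likelihood with the full n x n covariance."""
    X = dense_design(frame, time_coding)
    y = frame["y"].to_numpy(float)
    n, p = X.shape
    V = dense_covariance(frame, terms, theta_names, theta, has_residual)
    try:
        c, low = la.cho_factor(V, lower=True)
    except la.LinAlgError:
        return -np.inf
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    Vi_y = la.cho_solve((c, low), y)
    Vi_X = la.cho_solve((c, low), X)
    XtVX = X.T @ Vi_X
    beta = np.linalg.solve(XtVX, X.T @ Vi_y)
    quad = y @ Vi_y - (X.T @ Vi_y) @ beta
    _, logdet_t = np.linalg.slogdet(XtVX)
    return -0.5 * (logdet_v + logdet_t + quad) - 0.5 * (n - p) * np.log(2 * np.pi)


def dense_gls_beta(frame, time_coding, terms, theta_names, theta, has_residual):
    X = dense_design(frame, time_coding)
    y = frame["y"].to_numpy(float)
    V = dense_covariance(frame, terms, theta_names, theta, has_residual)
    Vi = np.linalg.inv(V)
    return np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)


def oneway_anova_components(frame, m):
    """Closed-form balanced one-way ANOVA REML estimators (single period).

    sigma2_e-hat = MSW;  sigma2_g-hat = (MSB - MSW) / m, with group means
    computed within condition (the fixed effect).
    """
    msb_num, msb_df, msw_num, msw_df = 0.0, 0, 0.0, 0
    for c, sub in frame.groupby("condition"):
        gmeans = sub.groupby("group_id")["y"].mean()
        grand = sub["y"].mean()
        msb_num += m * ((gmeans - grand) ** 2).sum()
        msb_df += len(gmeans) - 1
        for _, gsub in sub.groupby("group_id"):
            msw_num += ((gsub["y"] - gsub["y"].mean()) ** 2).sum()
            msw_df += len(gsub) - 1
    msb = msb_num / msb_df
    msw = msw_num / msw_df
    return (msb - msw) / m, msw, msb


def oneway_anova_f(frame):
    """Exact nested ANOVA F for the condition effect in a one-period GRT.

    F = MS(condition) / MS(group within condition), ddf = total groups - 2.
    """
    m = frame.groupby("group_id").size().iloc[0]
    cmeans = frame.groupby("condition")["y"].mean()
    grand = frame["y"].mean()
    ng_per_cond = frame.groupby("condition")["group_id"].nunique()
    msc = sum(ng_per_cond[c] * m * (cmeans[c] - grand) ** 2 for c in cmeans.index) / (len(cmeans) - 1)
    msg_num, msg_df = 0.0, 0
    for c, sub in frame.groupby("condition"):
        cmean = sub["y"].mean()
        gmeans = sub.groupby("group_id")["y"].mean()
        msg_num += m * ((gmeans - cmean) ** 2).sum()
        msg_df += len(gmeans) - 1
    msg = msg_num / msg_df
    return msc / msg, msg_df
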