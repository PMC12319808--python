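"""Trial-level mixed-model statistics linking spectral features to ratings.

The analysis asks how trial-level spectral features (aperiodic exponent and
offset, alpha peak power) estimated during a stimulus relate to the
arousal and valence ratings of the trial, controlling for the prestimulus
value of the same feature, with by-subject random intercepts and random
slopes for arousal and valence:

global model (average-electrode features)::

    X_is = b0 + b1 X_pre + b2 A_i + b3 V_i + b4 (A_i x V_i)
           + S_0s + u_As A_i + u_Vs V_i + e_is

cluster model (per electrode-cluster features)::

    X_isc = b0 + b1c (X_pre x E_c) + b5c (E_c x A_i) + b6c (E_c x V_i)
            + b4 (A_i x V_i) + S_0s + u_As A_i + u_Vs V_i + e_isc

Models are fit by REML (statsmodels MixedLM).  Each fixed-effect term gets
an F test whose denominator degrees of freedom use the Satterthwaite
approximation, computed here from the REML variance-parameter covariance
(numerical Hessian of the profiled REML log-likelihood).  Families of
cluster-interaction contrasts are corrected with the Holm step-down method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CLUSTERS_8",
    "CLUSTERS_9",
    "TRIAL_COLUMNS",
    "FTestResult",
    "LMMFit",
    "cluster_pca_reduce",
    "filter_trials",
    "fit_global_lmm",
    "fit_cluster_lmm",
    "holm_adjust",
    "validate_trials",
]

# Electrode clusters of the 32-channel montage.  The 9-cluster variant
# splits out a frontocentral group (reported in the cluster-level results);
# the 8-cluster variant follows the preprocessing description verbatim.
CLUSTERS_8 = {
    "prefrontal": ["AF3", "AF4", "Fp1", "Fp2"],
    "frontal": ["F7", "F3", "Fz", "F4", "F8"],
    "central": ["C3", "Cz", "C4"],
    "centroparietal": ["CP1", "CP5", "CP6", "CP2"],
    "parietal": ["P7", "P3", "Pz", "P4", "P8"],
    "parietooccipital": ["PO3", "O1", "Oz", "O2", "PO4"],
    "right_temporal": ["T8"],
    "left_temporal": ["T7"],
}
CLUSTERS_9 = {
    "prefrontal": ["AF3", "AF4", "Fp1", "Fp2"],
    "frontal": ["F7", "F3", "Fz", "F4", "F8"],
    "frontocentral": ["FC1", "FC5", "FC6", "FC2"],
    "central": ["C3", "Cz", "C4"],
    "centroparietal": ["CP1", "CP5", "CP6", "CP2"],
    "parietal": ["P7", "P3", "Pz", "P4", "P8"],
    "parietooccipital": ["PO3", "O1", "Oz", "O2", "PO4"],
    "right_temporal": ["T8"],
    "left_temporal": ["T7"],
}

# canonical trial-table schema; `cluster` is optional
TRIAL_COLUMNS = [
    "subject_id", "trial_id", "arousal", "valence",
    "task_exponent", "task_offset", "task_alpha",
    "pre_exponent", "pre_offset", "pre_alpha",
]

RESPONSES = {
    "exponent": ("task_exponent", "pre_exponent"),
    "offset": ("task_offset", "pre_offset"),
    "alpha": ("task_alpha", "pre_alpha"),
}


@dataclass(frozen=True)
class FTestResult:
    term: str
    f_value: float
    df_num: float
    df_den: float          # Satterthwaite
    p_value: float
    p_holm: float | None = None
    estimate: float | None = None
    std_error: float | None = None


@dataclass
class LMMFit:
    response: str
    fixed_effects: pd.Series
    std_errors: pd.Series
    random_variances: dict          # name -> variance
    residual_variance: float
    f_tests: list                   # of FTestResult
    converged: bool
    n_obs: int
    n_subjects: int
    method: str = "satterthwaite"   # df method actually used
    loglike: float = np.nan

    def summary_frame(self) -> pd.DataFrame:
        rows = [{
            "term": t.term, "estimate": t.estimate, "std_error": t.std_error,
            "F": t.f_value, "df_num": t.df_num, "df_den": t.df_den,
            "p": t.p_value, "p_holm": t.p_holm,
        } for t in self.f_tests]
        return pd.DataFrame(rows)


def validate_trials(records: pd.DataFrame, need_cluster: bool = False) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    if need_cluster and "cluster" not in records.columns:
        raise ValueError("trial table has no 'cluster' column")
    for col in ("arousal", "valence"):
        vals = records[col].dropna()
        if ((vals < 1) | (vals > 9)).any():
            raise ValueError(f"{col} ratings outside [1, 9]")
    key = ["subject_id", "trial_id"] + (
        ["cluster"] if "cluster" in records.columns else [])
    if records.duplicated(subset=key).any():
        raise ValueError(f"duplicate rows for key {key}")


def cluster_pca_reduce(epoch: np.ndarray, channel_names: list,
                       cluster_map: dict) -> dict:
    """Reduce a channels x time epoch to one series per electrode cluster.

    Each cluster's channels are centered and projected on the first
    principal axis of their channels x time matrix (the dominant spatial
    pattern of that region).  The loading sign is fixed so the loadings sum
    positive, making the reduced series' polarity reproducible.
    Single-channel clusters pass through unchanged (centered only).

    Returns ``{cluster: (series, loadings)}``; clusters with no channel
    present in ``channel_names`` are skipped.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2 or epoch.shape[0] != len(channel_names):
        raise ValueError("epoch must be (n_channels, n_times) matching "
                         "channel_names")
    index = {name: k for k, name in enumerate(channel_names)}
    out = {}
    for cluster, chans in cluster_map.items():
        rows = [index[c] for c in chans if c in index]
        if not rows:
            continue
        block = epoch[rows]
        block = block - block.mean(axis=1, keepdims=True)
        if len(rows) == 1:
            out[cluster] = (block[0].copy(), np.ones(1))
            continue
        # PC1 of the channel covariance via SVD of the centered block
        u, s, vt = np.linalg.svd(block, full_matrices=False)
        loadings = u[:, 0]
        if loadings.sum() < 0:
            loadings = -loadings
        out[cluster] = (loadings @ block, loadings)
    return out


def filter_trials(records: pd.DataFrame,
                  min_alpha_trials: int = 10) -> tuple:
    """Apply the trial/subject exclusion rules.

    Drops trials whose task exponent is <= 0 (a positive spectral slope,
    treated as noise), then drops subjects with fewer than
    ``min_alpha_trials`` trials carrying a detected alpha peak (non-missing
    ``task_alpha``).  Returns ``(filtered, report)`` where report is a
    DataFrame listing each exclusion and its reason.

    Raises
    ------
    ValueError
        If the table is empty or every subject is excluded.
    """
    if records.empty:
        raise ValueError("empty trial table")
    validate_trials(records)
    report = []
    bad = records["task_exponent"].notna() & (records["task_exponent"] <= 0)
    for _, row in records[bad].iterrows():
        report.append({"subject_id": row["subject_id"],
                       "trial_id": row["trial_id"],
                       "reason": "non-positive task exponent"})
    kept = records[~bad].copy()

    key = ["subject_id", "trial_id"]
    per_trial = kept.drop_duplicates(subset=key)
    n_alpha = per_trial.groupby("subject_id")["task_alpha"].apply(
        lambda s: int(s.notna().sum()))
    bad_subjects = n_alpha[n_alpha < min_alpha_trials].index
    for s in bad_subjects:
        report.append({"subject_id": s, "trial_id": None,
                       "reason": f"fewer than {min_alpha_trials} trials "
                                 "with an alpha peak"})
    kept = kept[~kept["subject_id"].isin(bad_subjects)].copy()
    if kept.empty:
        raise ValueError("all subjects excluded")
    return kept, pd.DataFrame(report,
                              columns=["subject_id", "trial_id", "reason"])


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


# ---------------------------------------------------------------------------
# REML machinery for Satterthwaite degrees of freedom.
#
# The mixed model is y_i = X_i beta + Z_i b_i + e_i per subject i with
# independent random effects b_i ~ N(0, diag(theta_1..theta_q)) and
# e_i ~ N(0, theta_0 I).  Satterthwaite's df for a contrast c is
#   nu = 2 (c' C c)^2 / (g' A g)
# with C(theta) the GLS covariance of beta, g the gradient of c'C c in
# theta and A the covariance of theta-hat, estimated as the inverse of the
# negative Hessian of the REML log-likelihood.  Both derivatives are taken
# numerically (central differences) on the log-variance scale.
# ---------------------------------------------------------------------------


def _group_matrices(y, X, Z, groups):
    order = np.argsort(groups, kind="stable")
    y, X, Z, groups = y[order], X[order], Z[order], groups[order]
    out = []
    for g in np.unique(groups):
        m = groups == g
        out.append((y[m], X[m], Z[m]))
    return out


def _beta_cov(theta, blocks):
    """GLS information and related pieces at variance parameters theta.

    Exploits the low rank of the random-effect design (Woodbury identity
    and determinant lemma), so the per-group cost is O(n q^2) rather than
    O(n^3).  Zero variance components simply drop out.
    """
    sigma2, gvars = float(theta[0]), np.asarray(theta[1:], dtype=float)
    active = gvars > 0
    XtVX = 0.0
    XtVy = 0.0
    ldet = 0.0
    quad = 0.0
    pieces = []
    for y_i, X_i, Z_i in blocks:
        n_i = len(y_i)
        K = Z_i[:, active] * np.sqrt(gvars[active])
        M = np.eye(K.shape[1]) + (K.T @ K) / sigma2
        ldet += n_i * np.log(sigma2) + np.linalg.slogdet(M)[1]

        def vsolve(B):
            KtB = K.T @ B
            return (B - K @ np.linalg.solve(sigma2 * M, KtB)) / sigma2

        Vi_X = vsolve(X_i)
        Vi_y = vsolve(y_i)
        XtVX = XtVX + X_i.T @ Vi_X
        XtVy = XtVy + X_i.T @ Vi_y
        pieces.append((y_i, X_i, Vi_y, Vi_X))
    C = np.linalg.inv(XtVX)
    beta = C @ XtVy
    for y_i, X_i, Vi_y, Vi_X in pieces:
        r_proj = Vi_y - Vi_X @ beta
        quad += y_i @ r_proj
    return C, beta, ldet, quad, XtVX


def _reml_loglike_full(theta, blocks):
    C, beta, ldet, quad, XtVX = _beta_cov(theta, blocks)
    sign, ld_info = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return -np.inf
    return -0.5 * (ldet + quad + ld_info)


def _satterthwaite_df(c, theta, blocks, rel_step=1e-4):
    """Satterthwaite denominator df for the scalar contrast c'beta.

    Variance components estimated at (or numerically indistinguishable
    from) the zero boundary carry no curvature information and are held
    fixed rather than differentiated.
    """
    theta = np.asarray(theta, dtype=float)
    active = theta > 1e-8 * theta.max()
    fixed = theta.copy()
    log_theta = np.log(theta[active])

    def expand(lt):
        full = fixed.copy()
        full[active] = np.exp(lt)
        return full

    def cCc(lt):
        C, *_ = _beta_cov(expand(lt), blocks)
        return float(c @ C @ c)

    def _reml_loglike(lt, blocks):
        return _reml_loglike_full(expand(lt), blocks)

    k = len(log_theta)
    h = rel_step * np.maximum(np.abs(log_theta), 1.0)
    grad = np.empty(k)
    for j in range(k):
        e = np.zeros(k)
        e[j] = h[j]
        grad[j] = (cCc(log_theta + e) - cCc(log_theta - e)) / (2 * h[j])

    # Hessian of the REML log-likelihood on the log-variance scale
    H = np.empty((k, k))
    f0 = _reml_loglike(log_theta, blocks)
    for j in range(k):
        for l in range(j, k):
            ej = np.zeros(k); ej[j] = h[j]
            el = np.zeros(k); el[l] = h[l]
            if j == l:
                fpp = _reml_loglike(log_theta + 2 * ej, blocks)
                fmm = _reml_loglike(log_theta - 2 * ej, blocks)
                H[j, j] = (fpp - 2 * f0 + fmm) / (4 * h[j] ** 2)
            else:
                fpp = _reml_loglike(log_theta + ej + el, blocks)
                fpm = _reml_loglike(log_theta + ej - el, blocks)
                fmp = _reml_loglike(log_theta - ej + el, blocks)
                fmm = _reml_loglike(log_theta - ej - el, blocks)
                H[j, l] = H[l, j] = (fpp - fpm - fmp + fmm) / (4 * h[j] * h[l])
    try:
        A = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return np.nan
    denom = float(grad @ A @ grad)
    if denom <= 0:
        return np.nan
    val = cCc(log_theta)
    return 2.0 * val ** 2 / denom


def _polish_theta(theta_start, blocks, y, floor=1e-10):
    """Re-maximize the REML criterion over the variance parameters.

    Runs L-BFGS-B on the log-variance scale from the supplied start and
    from a moment-based start, returning the better solution.  Components
    driven to the floor are truncated to exactly zero.
    """
    from scipy.optimize import minimize

    vy = float(np.var(y))
    starts = [np.maximum(theta_start, floor),
              np.array([0.7 * vy, 0.2 * vy, 1e-3 * vy, 1e-3 * vy])]
    def objective(lt):
        val = _reml_loglike_full(np.exp(lt), blocks)
        return -val if np.isfinite(val) else 1e12

    best, best_val, ok = None, -np.inf, False
    for s in starts:
        res = minimize(objective, np.log(np.maximum(s, 1e-8 * vy)),
                       method="L-BFGS-B",
                       bounds=[(np.log(1e-8 * vy), None)] +
                              [(np.log(floor * vy), None)] * (len(s) - 1))
        if np.isfinite(res.fun) and -res.fun > best_val:
            best, best_val, ok = np.exp(res.x), -res.fun, bool(res.success)
    if best is None:  # degenerate likelihood (e.g. noise-free data)
        return starts[0], False
    out = best.copy()
    out[1:][out[1:] <= 2 * floor * vy] = 0.0
    return out, ok


def _fit_mixed(records, response_col, fixed_cols, term_names):
    """Shared fitting path for the global and cluster models.

    ``fixed_cols`` is a design DataFrame (already including the intercept);
    random structure is by-subject intercept plus independent slopes for
    arousal and valence.
    """
    data = records.dropna(subset=[response_col]).copy()
    names = list(fixed_cols.columns)
    df = fixed_cols.loc[data.index].copy()
    df["_y"] = data[response_col].to_numpy(dtype=float)
    df["_subject"] = data["subject_id"].to_numpy()
    df["_arousal"] = data["arousal"].to_numpy(dtype=float)
    df["_valence"] = data["valence"].to_numpy(dtype=float)

    Xr = df[names].to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xr) < Xr.shape[1]:
        raise ValueError("rank-deficient fixed-effect design (collinear or "
                         "empty interaction cells)")

    formula = "_y ~ 0 + " + " + ".join(names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(
            formula, groups="_subject", re_formula="1",
            vc_formula={"arousal_slope": "0 + _arousal",
                        "valence_slope": "0 + _valence"},
            data=df)
        fit = model.fit(reml=True, method=["lbfgs", "cg"], maxiter=500)

    vc_order = list(model.exog_vc.names)  # statsmodels' component order
    vcomp = dict(zip(vc_order, np.maximum(np.asarray(fit.vcomp), 0.0)))
    vcomp["subject_intercept"] = max(float(np.asarray(fit.cov_re)[0, 0]), 0.0)
    theta = np.array([float(fit.scale), vcomp["subject_intercept"],
                      vcomp["arousal_slope"], vcomp["valence_slope"]])

    y = df["_y"].to_numpy()
    X = df[names].to_numpy(dtype=float)
    subj = pd.factorize(df["_subject"])[0]
    Z = np.column_stack([np.ones(len(df)), df["_arousal"].to_numpy(),
                         df["_valence"].to_numpy()])

    blocks = _group_matrices(y, X, Z, subj)
    # REML polish: with uncentered 1-9 ratings the intercept and slope
    # components trade off along a flat ridge and the MixedLM optimizer can
    # stall short of the optimum; re-maximize the (identical) REML
    # criterion from both its solution and a moment-based start.
    theta, converged = _polish_theta(theta, blocks, y)
    sigma2 = float(theta[0])
    vcomp = {"subject_intercept": float(theta[1]),
             "arousal_slope": float(theta[2]),
             "valence_slope": float(theta[3])}
    C, beta_gls, *_ = _beta_cov(theta, blocks)
    beta = pd.Series(beta_gls, index=names)
    se = pd.Series(np.sqrt(np.diag(C)), index=names)

    tests = []
    method = "satterthwaite"
    for term, cols in term_names.items():
        if len(cols) == 1:
            j = names.index(cols[0])
            c = np.zeros(len(names)); c[j] = 1.0
            fval = float(beta.iloc[j] ** 2 / (c @ C @ c))
            df_den = _satterthwaite_df(c, theta, blocks)
            if not np.isfinite(df_den):
                # containment-style fallback
                df_den = float(len(y) - len(names))
                method = "containment-fallback"
            p = float(sps.f.sf(fval, 1, df_den))
            tests.append(FTestResult(
                term=term, f_value=fval, df_num=1.0, df_den=df_den,
                p_value=p, estimate=float(beta.iloc[j]),
                std_error=float(se.iloc[j])))
        else:  # multi-column term: Wald F with averaged Satterthwaite df
            idx = [names.index(cn) for cn in cols]
            Cm = np.asarray(C)[np.ix_(idx, idx)]
            b = beta.iloc[idx].to_numpy()
            fval = float(b @ np.linalg.solve(Cm, b) / len(idx))
            dfs = []
            for j in idx:
                c = np.zeros(len(names)); c[j] = 1.0
                d = _satterthwaite_df(c, theta, blocks)
                if np.isfinite(d):
                    dfs.append(d)
            df_den = float(np.mean(dfs)) if dfs else float(len(y) - len(names))
            p = float(sps.f.sf(fval, len(idx), df_den))
            tests.append(FTestResult(term=term, f_value=fval,
                                     df_num=float(len(idx)), df_den=df_den,
                                     p_value=p))
    return LMMFit(
        response=response_col, fixed_effects=beta, std_errors=se,
        random_variances=vcomp, residual_variance=sigma2, f_tests=tests,
        converged=converged, n_obs=len(y),
        n_subjects=len(np.unique(subj)), method=method,
        loglike=float(_reml_loglike_full(theta, blocks)))


def fit_global_lmm(records: pd.DataFrame, response: str = "exponent",
                   center_ratings: bool = False) -> LMMFit:
    """Fit the global (average-electrode) mixed model for one response.

    ``response`` is one of {"exponent", "offset", "alpha"}; the matching
    prestimulus feature enters as the baseline covariate.  Ratings are used
    raw on their 1-9 scale unless ``center_ratings`` subtracts each
    subject's mean (off by default).
    """
    if response not in RESPONSES:
        raise ValueError(f"response must be one of {sorted(RESPONSES)}")
    validate_trials(records)
    task_col, pre_col = RESPONSES[response]
    data = records.dropna(subset=[task_col, pre_col, "arousal",
                                  "valence"]).copy()
    if center_ratings:
        for col in ("arousal", "valence"):
            data[col] = data[col] - data.groupby("subject_id")[col].transform(
                "mean")
    design = pd.DataFrame({
        "intercept": np.ones(len(data)),
        "prestimulus": data[pre_col].to_numpy(dtype=float),
        "arousal": data["arousal"].to_numpy(dtype=float),
        "valence": data["valence"].to_numpy(dtype=float),
        "arousal_x_valence": (data["arousal"] * data["valence"]).to_numpy(
            dtype=float),
    }, index=data.index)
    terms = {"prestimulus": ["prestimulus"], "arousal": ["arousal"],
             "valence": ["valence"],
             "arousal_x_valence": ["arousal_x_valence"]}
    return _fit_mixed(data, task_col, design, terms)


def fit_cluster_lmm(records: pd.DataFrame, response: str = "exponent",
                    holm_families: bool = True) -> LMMFit:
    """Fit the cluster-interaction mixed model for one response.

    The fixed design crosses the prestimulus covariate, arousal and valence
    with the electrode cluster (one coefficient per cluster, cell-means
    coding) and keeps a shared arousal x valence interaction; the random
    structure is as in the global model.  With ``holm_families`` the
    cluster x arousal and cluster x valence contrasts form one Holm family
    per response model.
    """
    if response not in RESPONSES:
        raise ValueError(f"response must be one of {sorted(RESPONSES)}")
    validate_trials(records, need_cluster=True)
    task_col, pre_col = RESPONSES[response]
    data = records.dropna(subset=[task_col, pre_col, "arousal",
                                  "valence"]).copy()
    clusters = sorted(data["cluster"].unique())
    cols = {"intercept": np.ones(len(data))}
    terms: dict = {}
    interaction_terms = []
    for c in clusters:
        ind = (data["cluster"] == c).to_numpy(dtype=float)
        cols[f"pre_x_{c}"] = ind * data[pre_col].to_numpy(dtype=float)
        terms[f"prestimulus_x_{c}"] = [f"pre_x_{c}"]
    for c in clusters:
        ind = (data["cluster"] == c).to_numpy(dtype=float)
        cols[f"arousal_x_{c}"] = ind * data["arousal"].to_numpy(dtype=float)
        terms[f"arousal_x_{c}"] = [f"arousal_x_{c}"]
        interaction_terms.append(f"arousal_x_{c}")
    for c in clusters:
        ind = (data["cluster"] == c).to_numpy(dtype=float)
        cols[f"valence_x_{c}"] = ind * data["valence"].to_numpy(dtype=float)
        terms[f"valence_x_{c}"] = [f"valence_x_{c}"]
        interaction_terms.append(f"valence_x_{c}")
    cols["arousal_x_valence"] = (
        data["arousal"] * data["valence"]).to_numpy(dtype=float)
    terms["arousal_x_valence"] = ["arousal_x_valence"]
    design = pd.DataFrame(cols, index=data.index)
    fit = _fit_mixed(data, task_col, design, terms)

    if holm_families:
        fam = [t for t in fit.f_tests if t.term in interaction_terms]
        adj = holm_adjust([t.p_value for t in fam])
        adj_map = {t.term: a for t, a in zip(fam, adj)}
        fit.f_tests = [
            FTestResult(term=t.term, f_value=t.f_value, df_num=t.df_num,
                        df_den=t.df_den, p_value=t.p_value,
                        p_holm=adj_map.get(t.term), estimate=t.estimate,
                        std_error=t.std_error)
            for t in fit.f_tests]
    return fit
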