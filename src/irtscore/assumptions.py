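"""IRT assumption screening and post-fit item-fit diagnostics.

Before fitting an IRT model the 9Q item scores are screened for

* **unidimensionality** - a single-factor confirmatory factor analysis with a
  maximum-likelihood estimator; adequate fit is CFI > 0.95, TLI > 0.95 and
  RMSEA < 0.06;
* **local independence** - residual correlations (observed minus
  model-implied) from the single-factor solution; |residual| > 0.20 marks a
  possibly locally dependent item pair;
* **monotonicity** - Loevinger's scalability coefficients in the Mokken
  covariance-ratio form; items should reach H_i >= 0.30 and the scale
  H >= 0.50.

After fitting, each item gets a Wald-type fit statistic comparing observed
and model-expected item mean scores across latent-severity bins, reported
against a chi-square(1) upper tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

from .instrument import ITEM_NAMES, N_ITEMS, PRODUCT_POINTS, category_matrix
from .estimate import FitResult
from .quadrature import QuadratureGrid, normal_grid

__all__ = [
    "CfaFit",
    "MonotonicityResult",
    "ItemFitResult",
    "one_factor_cfa",
    "local_dependence_flags",
    "loevinger_h",
    "chi2w_item_fit",
    "chi2_p_consistent",
    "assumption_report",
]


# ---------------------------------------------------------------------------
# Single-factor CFA (ML on the covariance matrix)
# ---------------------------------------------------------------------------


@dataclass
class CfaFit:
    chi2_model: float
    df_model: int
    chi2_baseline: float
    df_baseline: int
    cfi: float
    tli: float
    rmsea: float
    loadings: np.ndarray
    residual_corr: np.ndarray
    n_obs: int

    @property
    def adequate(self) -> dict[str, bool]:
        return {
            "cfi>0.95": self.cfi > 0.95,
            "tli>0.95": self.tli > 0.95,
            "rmsea<0.06": self.rmsea < 0.06,
        }


def _ml_discrepancy(S: np.ndarray, sigma: np.ndarray) -> float:
    p = S.shape[0]
    sign, logdet_sigma = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    _, logdet_s = np.linalg.slogdet(S)
    return float(logdet_sigma + np.trace(S @ np.linalg.inv(sigma)) - logdet_s - p)


def fit_indices(
    chi2_model: float, df_model: int, chi2_baseline: float, df_baseline: int, n_obs: int
) -> tuple[float, float, float]:
    """(CFI, TLI, RMSEA) from the standard chi-square-based formulas."""
    d_m = max(chi2_model - df_model, 0.0)
    d_b = max(chi2_baseline - df_baseline, d_m, 0.0)
    cfi = 1.0 if d_b == 0 else float(np.clip(1.0 - d_m / d_b, 0.0, 1.0))
    ratio_b = chi2_baseline / df_baseline
    ratio_m = chi2_model / df_model
    tli = 1.0 if ratio_b == 1.0 else float((ratio_b - ratio_m) / (ratio_b - 1.0))
    rmsea = float(np.sqrt(max(chi2_model - df_model, 0.0) / (df_model * (n_obs - 1))))
    return cfi, min(tli, 1.0), rmsea


def one_factor_cfa(
    records_or_scores,
    scoring: Literal["product", "combination"] = "product",
) -> CfaFit:
    """ML single-factor CFA of the nine item scores (treated as continuous).

    Accepts records (scored with the chosen coding's ordinal values) or a
    ready (N, 9) score matrix. Returns the chi-square fit statistics, CFI /
    TLI / RMSEA, the loadings and the residual correlation matrix.
    """
    if isinstance(records_or_scores, np.ndarray):
        Y = np.asarray(records_or_scores, dtype=float)
    else:
        X = category_matrix(records_or_scores, "product" if scoring == "product" else "combination")
        if scoring == "product":
            Y = np.asarray(PRODUCT_POINTS, dtype=float)[X]
        else:
            Y = X.astype(float)  # combination indices treated as ordinal codes
    N, p = Y.shape
    S = np.cov(Y, rowvar=False, ddof=1)
    sd = np.sqrt(np.diag(S))
    if np.any(sd <= 0):
        bad = [ITEM_NAMES[i] for i in np.flatnonzero(sd <= 0)]
        raise ValueError(f"zero-variance items: {bad}")
    n_free = 2 * p
    if N <= n_free:
        raise ValueError("sample too small for the single-factor model")

    # parameters: loadings (p) and log unique variances (p)
    r0 = np.corrcoef(Y, rowvar=False)
    lam0 = sd * np.sqrt(np.clip(np.abs(r0 - np.eye(p)).mean(axis=1), 0.1, 0.9))

    def objective(par: np.ndarray) -> float:
        lam = par[:p]
        psi = np.exp(par[p:])
        sigma = np.outer(lam, lam) + np.diag(psi)
        return _ml_discrepancy(S, sigma)

    par0 = np.concatenate([lam0, np.log(np.clip(np.diag(S) - lam0**2, 1e-3, None))])
    res = minimize(objective, par0, method="L-BFGS-B")
    lam = res.x[:p]
    psi = np.exp(res.x[p:])
    if lam.sum() < 0:
        lam = -lam  # sign convention: positive loadings dominate
    sigma = np.outer(lam, lam) + np.diag(psi)

    chi2_model = (N - 1) * res.fun
    df_model = p * (p + 1) // 2 - n_free
    R = np.corrcoef(Y, rowvar=False)
    sign, logdet_r = np.linalg.slogdet(R)
    chi2_baseline = -(N - 1) * logdet_r
    df_baseline = p * (p - 1) // 2
    cfi, tli, rmsea = fit_indices(chi2_model, df_model, chi2_baseline, df_baseline, N)

    d = np.sqrt(np.diag(sigma))
    implied_corr = sigma / np.outer(d, d)
    residual = R - implied_corr
    np.fill_diagonal(residual, 0.0)
    return CfaFit(
        chi2_model=float(chi2_model),
        df_model=df_model,
        chi2_baseline=float(chi2_baseline),
        df_baseline=df_baseline,
        cfi=cfi,
        tli=tli,
        rmsea=rmsea,
        loadings=lam,
        residual_corr=residual,
        n_obs=N,
    )


def local_dependence_flags(
    cfa: CfaFit, cutoff: float = 0.20
) -> list[tuple[int, int, float]]:
    """Item pairs (1-based) whose |residual correlation| exceeds ``cutoff``."""
    flags = []
    R = cfa.residual_corr
    for i in range(R.shape[0]):
        for j in range(i + 1, R.shape[1]):
            if abs(R[i, j]) > cutoff:
                flags.append((i + 1, j + 1, float(R[i, j])))
    return flags


# ---------------------------------------------------------------------------
# Loevinger's H (Mokken covariance-ratio form)
# ---------------------------------------------------------------------------


@dataclass
class MonotonicityResult:
    H: float
    H_items: np.ndarray
    pass_scale: bool
    pass_items: np.ndarray
    undefined_items: tuple[int, ...] = ()


def _cov_max(x: np.ndarray, y: np.ndarray) -> float:
    """Maximum covariance attainable with x's and y's marginals (comonotone)."""
    xs = np.sort(x)
    ys = np.sort(y)
    return float(np.mean(xs * ys) - xs.mean() * ys.mean())


def loevinger_h(
    records_or_scores,
    scoring: Literal["product", "combination"] = "product",
    h_item_threshold: float = 0.30,
    h_scale_threshold: float = 0.50,
) -> MonotonicityResult:
    """Loevinger's H for the scale and H_i per item.

    Uses the polytomous Mokken formulation H_ij = cov(X_i, X_j) /
    cov_max(X_i, X_j), where cov_max pairs the sorted marginals; item and
    scale coefficients aggregate numerators and denominators over pairs.
    Zero-variance items have undefined H_i and are reported as NaN.
    """
    if isinstance(records_or_scores, np.ndarray):
        Y = np.asarray(records_or_scores, dtype=float)
    else:
        X = category_matrix(records_or_scores, "product" if scoring == "product" else "combination")
        Y = np.asarray(PRODUCT_POINTS, dtype=float)[X] if scoring == "product" else X.astype(float)
    N, p = Y.shape
    cov = np.cov(Y, rowvar=False, ddof=0)
    variances = np.diag(cov)
    undefined = tuple(int(i + 1) for i in np.flatnonzero(variances == 0))
    num = np.zeros((p, p))
    den = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if variances[i] == 0 or variances[j] == 0:
                num[i, j] = num[j, i] = np.nan
                den[i, j] = den[j, i] = np.nan
                continue
            num[i, j] = num[j, i] = cov[i, j]
            den[i, j] = den[j, i] = _cov_max(Y[:, i], Y[:, j])
    with np.errstate(invalid="ignore"):
        H_items = np.nansum(num, axis=1) / np.nansum(den, axis=1)
    H_items[np.array([i - 1 for i in undefined], dtype=int)] = np.nan
    mask = ~np.isnan(np.triu(num, 1))
    H = float(np.triu(num, 1)[mask].sum() / np.triu(den, 1)[mask].sum())
    return MonotonicityResult(
        H=H,
        H_items=H_items,
        pass_scale=H >= h_scale_threshold,
        pass_items=H_items >= h_item_threshold,
        undefined_items=undefined,
    )


# ---------------------------------------------------------------------------
# chi2W-style item fit
# ---------------------------------------------------------------------------


@dataclass
class ItemFitResult:
    frame: pd.DataFrame  # item, name, chi2w, df, p, skipped


def chi2w_item_fit(
    records_or_X,
    fit: FitResult,
    n_bins: int = 10,
    grid: QuadratureGrid | None = None,
    scores_per_category: np.ndarray | None = None,
) -> ItemFitResult:
    """Binned Wald-type item-fit statistic against chi-square(1).

    For each item, every respondent's *rest posterior* (posterior over the
    latent severity given the other eight items) yields an expected item
    score and its variance; the residual observed-minus-expected score then
    has exactly zero mean under the fitted model. Respondents are binned into
    ``n_bins`` quantile bins of the rest-score EAP (bins thinner than 5
    respondents are merged), and a single linear-trend contrast of the bin
    residuals - the contrast most sensitive to a mis-specified slope - is
    squared and scaled by its variance, giving a df = 1 Wald statistic.

    ``scores_per_category`` assigns a numeric score to each category index
    (defaults: the traditional product points for GRM fits, the product of
    the decoded intensity and frequency for NRM fits).
    """
    grid = grid or normal_grid()
    from .estimate import _as_matrix_and_groups, _person_log_tables  # internals

    X, gidx, names = _as_matrix_and_groups(records_or_X, fit.model, fit.params)
    N = len(X)
    if scores_per_category is None:
        if fit.model == "grm":
            scores_per_category = np.asarray(PRODUCT_POINTS, dtype=float)
        else:
            from .instrument import COMBINATION_LABELS

            scores_per_category = np.array(
                [(lab // 10) * (lab % 10) for lab in COMBINATION_LABELS], dtype=float
            )

    logtabs = _person_log_tables(X, fit.params, fit.model, grid.nodes, gidx, names)
    total = logtabs.sum(axis=1)
    rows = []
    for i in range(N_ITEMS):
        obs = scores_per_category[X[:, i]]
        if np.all(obs == obs[0]):
            warnings.warn(f"item {i + 1}: zero observed variance; item fit skipped",
                          stacklevel=2)
            rows.append({"item": i + 1, "name": ITEM_NAMES[i], "chi2w": np.nan,
                         "df": 1, "p": np.nan, "skipped": True})
            continue
        rest = total - logtabs[:, i, :] + grid.log_weights[None, :]
        rest -= rest.max(axis=1, keepdims=True)
        W = np.exp(rest)
        W /= W.sum(axis=1, keepdims=True)  # rest posterior per person

        # conditional item-score moments at each node, per parameter group
        e1 = np.empty(N)
        e2 = np.empty(N)
        for g, name in enumerate(names):
            sel = np.flatnonzero(gidx == g) if gidx is not None else np.arange(N)
            if sel.size == 0:
                continue
            p = fit.params[name][i]
            from .estimate import _tables_from_params

            cmap, tab = _tables_from_params([p], fit.model, grid.nodes)[0]
            # representative category per local band: the smallest member
            rep = np.zeros(tab.shape[0], dtype=int)
            for c in range(len(cmap) - 1, -1, -1):
                if cmap[c] >= 0:
                    rep[cmap[c]] = c
            s = scores_per_category[rep]
            m1 = s @ tab  # E[score | theta] per node
            m2 = (s**2) @ tab
            e1[sel] = W[sel] @ m1
            e2[sel] = W[sel] @ m2
        resid = obs - e1
        var = np.maximum(e2 - e1**2, 1e-12)

        theta_rest = W @ grid.nodes
        order = np.argsort(theta_rest, kind="stable")
        edges = np.linspace(0, N, n_bins + 1).astype(int)
        bin_of = np.empty(N, dtype=int)
        for b_idx in range(n_bins):
            bin_of[order[edges[b_idx] : edges[b_idx + 1]]] = b_idx
        # merge thin bins into their left neighbour
        sizes = np.bincount(bin_of, minlength=n_bins)
        remap = np.arange(n_bins)
        for b_idx in range(1, n_bins):
            if sizes[b_idx] < 5:
                remap[b_idx] = remap[b_idx - 1]
        bin_of = remap[bin_of]

        bin_means = np.array(
            [theta_rest[bin_of == b].mean() for b in np.unique(bin_of)]
        )
        centred = {b: m - theta_rest.mean() for b, m in zip(np.unique(bin_of), bin_means)}
        c = np.array([centred[b] for b in bin_of])
        stat = float((c @ resid) ** 2 / (c**2 @ var))
        rows.append({"item": i + 1, "name": ITEM_NAMES[i], "chi2w": stat,
                     "df": 1, "p": float(stats.chi2.sf(stat, 1)), "skipped": False})
    return ItemFitResult(frame=pd.DataFrame(rows))


def chi2_p_consistent(
    chi2: float, p_text: str, df: int = 1, decimals: int = 3
) -> bool:
    """Is a printed (chi2, p) pair consistent with a chi-square(df) tail?

    Both numbers are rounded in print, so the check asks whether *some*
    chi-square value within the printed statistic's rounding interval yields
    a tail probability within the printed p's rounding interval. Censored
    entries like ``"<0.001"`` are consistent when the whole interval stays
    below the bound.
    """
    lo, hi = chi2 - 0.005, chi2 + 0.005
    p_hi = float(stats.chi2.sf(lo, df))  # sf is decreasing in chi2
    p_lo = float(stats.chi2.sf(hi, df))
    if p_text.startswith("<"):
        return p_hi < float(p_text[1:])
    p_printed = float(p_text)
    half = 0.5 * 10.0 ** (-decimals)
    return (p_lo <= p_printed + half) and (p_hi >= p_printed - half)


def assumption_report(
    records,
    scoring: Literal["product", "combination"] = "product",
) -> tuple[pd.DataFrame, str]:
    """Run the pre-fit screen and render (table, human-readable text block)."""
    cfa = one_factor_cfa(records, scoring)
    mono = loevinger_h(records, scoring)
    ld = local_dependence_flags(cfa)
    rows = [
        {"index": "CFI", "value": cfa.cfi, "threshold": "> 0.95", "pass": cfa.cfi > 0.95},
        {"index": "TLI", "value": cfa.tli, "threshold": "> 0.95", "pass": cfa.tli > 0.95},
        {"index": "RMSEA", "value": cfa.rmsea, "threshold": "< 0.06", "pass": cfa.rmsea < 0.06},
        {"index": "H", "value": mono.H, "threshold": ">= 0.50", "pass": mono.pass_scale},
    ]
    for i, (h_i, ok) in enumerate(zip(mono.H_items, mono.pass_items), start=1):
        rows.append({"index": f"H_{i}", "value": h_i, "threshold": ">= 0.30", "pass": bool(ok)})
    rows.append({
        "index": "locally_dependent_pairs",
        "value": float(len(ld)),
        "threshold": "|res corr| <= 0.20",
        "pass": len(ld) == 0,
    })
    frame = pd.DataFrame(rows)
    lines = [f"Assumption screen ({scoring} scoring, N = {cfa.n_obs})"]
    for _, r in frame.iterrows():
        lines.append(
            f"  {r['index']:<24} {r['value']:8.3f}  ({r['threshold']})  "
            f"{'pass' if r['pass'] else 'FAIL'}"
        )
    if ld:
        lines.append("  flagged pairs: " + ", ".join(f"{a}-{b} ({r:+.2f})" for a, b, r in ld))
    return frame, "\n".join(lines)
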