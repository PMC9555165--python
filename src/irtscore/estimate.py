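"""Marginal maximum likelihood (MMLE) estimation of the GRM and NRM by EM.

The latent severity is integrated out against a fixed N(0,1) prior on a
quadrature grid. The E-step computes each respondent's posterior weights over
the grid nodes; the M-step maximises, item by item, the expected
complete-data log-likelihood with an analytic gradient (L-BFGS-B on an
order-preserving reparameterisation for GRM thresholds). The observed
marginal log-likelihood is monotone non-decreasing along the iterations.

Gender-grouped fits support three per-item constraint levels, which is what
the likelihood-ratio DIF machinery in :mod:`irtscore.dif` needs:

* ``shared`` - one parameter set for everyone (the anchor state);
* ``thresholds_free`` - slope shared across genders, thresholds (GRM) or
  intercepts (NRM) gender-specific: the uniform-DIF alternative;
* ``free`` - everything gender-specific: the non-uniform-DIF alternative.

Categories never observed in a fitting scope are collapsed out of that
scope's likelihood; their parameters are reported as NaN and may be filled
downstream by the sparse-cell substitution rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp, softmax
from scipy import stats

from .instrument import N_ITEMS, ResponseRecord, category_matrix
from .params import GrmItemParams, NrmItemParams
from .quadrature import QuadratureGrid, normal_grid

__all__ = [
    "EmConfig",
    "FitResult",
    "RefitNeeded",
    "fit_mmle_em",
    "marginal_loglik",
    "eap_theta",
    "information_criteria",
    "likelihood_ratio_test",
]

Model = Literal["grm", "nrm"]
Constraint = Literal["shared", "thresholds_free", "free"]

_PCLIP = 1e-12


@dataclass(frozen=True)
class EmConfig:
    """EM controls: convergence tolerances, iteration caps, parameter bounds."""

    tol_loglik: float = 1e-6
    tol_param: float = 1e-4
    max_iter: int = 500
    a_cap: float = 30.0  # discrimination magnitude cap (sparse-cell guard)
    c_cap: float = 60.0  # NRM intercept magnitude cap
    mstep_maxiter: int = 40
    a_floor: float = 0.05  # GRM slopes are kept positive


@dataclass
class FitResult:
    """A converged (or capped-out) MMLE fit.

    ``params`` maps a group name (``"all"`` for ungrouped fits, else
    ``"male"``/``"female"``) to nine per-item parameter objects; items under a
    ``shared`` constraint hold identical values in every group.
    """

    model: Model
    params: dict[str, list]
    loglik: float
    n_params: int
    n_obs: int
    converged: bool
    n_iter: int
    loglik_trace: np.ndarray
    constraints: dict[int, str] = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.n_obs)


class RefitNeeded(RuntimeError):
    """A nested-model likelihood ordering is violated beyond tolerance."""


# ---------------------------------------------------------------------------
# Threshold reparameterisation (order-preserving)
# ---------------------------------------------------------------------------


def _b_to_t(b: np.ndarray) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    if b.size == 0:
        return b.copy()
    return np.concatenate([[b[0]], np.log(np.maximum(np.diff(b), 1e-6))])


def _t_to_b(t: np.ndarray) -> np.ndarray:
    if t.size == 0:
        return t.copy()
    return t[0] + np.concatenate([[0.0], np.cumsum(np.exp(t[1:]))])


# ---------------------------------------------------------------------------
# M-step objectives (negative expected complete-data log-likelihood + grad)
# ---------------------------------------------------------------------------


def _grm_negll(psi: np.ndarray, R_list: list[np.ndarray], nodes: np.ndarray):
    a = psi[0]
    grad = np.zeros_like(psi)
    nll = 0.0
    g_a = 0.0
    off = 1
    for R in R_list:
        K = R.shape[0]
        t = psi[off : off + K - 1]
        b = _t_to_b(t)
        F = expit(a * (nodes[None, :] - b[:, None]))  # (K-1, Q)
        ones = np.ones((1, nodes.size))
        zeros = np.zeros((1, nodes.size))
        ext = np.concatenate([ones, F, zeros], axis=0)
        P = np.clip(ext[:-1] - ext[1:], _PCLIP, None)
        nll -= float((R * np.log(P)).sum())
        G = -R / P  # d nll / d P
        GF = G[1:] - G[:-1]  # row j corresponds to boundary curve F[j]
        s = F * (1.0 - F)
        g_a += float((GF * s * (nodes[None, :] - b[:, None])).sum())
        g_b = (GF * (-a * s)).sum(axis=1)
        g_t = np.empty(K - 1)
        g_t[0] = g_b.sum()
        if K > 2:
            rev = np.cumsum(g_b[::-1])[::-1]
            g_t[1:] = np.exp(t[1:]) * rev[1:]
        grad[off : off + K - 1] = g_t
        off += K - 1
    grad[0] = g_a
    return nll, grad


def _mstep_grm(
    R_list: list[np.ndarray],
    nodes: np.ndarray,
    a0: float,
    b0_list: list[np.ndarray],
    config: EmConfig,
) -> tuple[float, list[np.ndarray]]:
    psi0 = np.concatenate([[a0]] + [_b_to_t(b0) for b0 in b0_list])
    bounds = [(config.a_floor, config.a_cap)]
    for b0 in b0_list:
        bounds += [(-12.0, 12.0)] + [(-9.0, 3.5)] * (len(b0) - 1)
    res = minimize(
        _grm_negll,
        psi0,
        args=(R_list, nodes),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": config.mstep_maxiter},
    )
    psi = res.x if res.fun <= _grm_negll(psi0, R_list, nodes)[0] else psi0
    a = float(psi[0])
    out, off = [], 1
    for b0 in b0_list:
        k = len(b0)
        out.append(_t_to_b(psi[off : off + k]))
        off += k
    return a, out


def _nrm_negll(
    psi: np.ndarray,
    R_list: list[np.ndarray],
    nodes: np.ndarray,
    ref: int,
    share_slopes: bool,
):
    K = R_list[0].shape[0]
    nfree = K - 1
    free_idx = np.array([k for k in range(K) if k != ref], dtype=int)
    grad = np.zeros_like(psi)
    nll = 0.0
    if share_slopes:
        a_free = psi[:nfree]
        c_offset = nfree
        g_a = np.zeros(nfree)
    else:
        c_offset = 0
    for gi, R in enumerate(R_list):
        if share_slopes:
            a_full = np.zeros(K)
            a_full[free_idx] = a_free
            c_free = psi[c_offset + gi * nfree : c_offset + (gi + 1) * nfree]
        else:
            a_full = np.zeros(K)
            a_full[free_idx] = psi[:nfree]
            c_free = psi[nfree : 2 * nfree]
        c_full = np.zeros(K)
        c_full[free_idx] = c_free
        logits = a_full[:, None] * nodes[None, :] + c_full[:, None]
        P = softmax(logits, axis=0)
        nq = R.sum(axis=0)
        nll -= float((R * np.log(np.clip(P, _PCLIP, None))).sum())
        D = R - nq[None, :] * P  # (K, Q); d loglik / d logits
        ga_full = -(D @ nodes)
        gc_full = -D.sum(axis=1)
        if share_slopes:
            g_a += ga_full[free_idx]
            grad[c_offset + gi * nfree : c_offset + (gi + 1) * nfree] = gc_full[free_idx]
        else:
            grad[:nfree] += ga_full[free_idx]
            grad[nfree : 2 * nfree] += gc_full[free_idx]
    if share_slopes:
        grad[:nfree] = g_a
    return nll, grad


def _mstep_nrm(
    R_list: list[np.ndarray],
    nodes: np.ndarray,
    a0_free: np.ndarray,
    c0_free_list: list[np.ndarray],
    ref: int,
    config: EmConfig,
) -> tuple[np.ndarray, list[np.ndarray]]:
    share = len(R_list) > 1
    psi0 = np.concatenate([a0_free] + c0_free_list)
    nfree = len(a0_free)
    bounds = [(-config.a_cap, config.a_cap)] * nfree
    bounds += [(-config.c_cap, config.c_cap)] * (nfree * len(c0_free_list))
    res = minimize(
        _nrm_negll,
        psi0,
        args=(R_list, nodes, ref, share),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": config.mstep_maxiter},
    )
    psi = res.x if res.fun <= _nrm_negll(psi0, R_list, nodes, ref, share)[0] else psi0
    a_free = psi[:nfree]
    c_list = [psi[nfree + g * nfree : nfree + (g + 1) * nfree] for g in range(len(c0_free_list))]
    return a_free, c_list


# ---------------------------------------------------------------------------
# Item blocks
# ---------------------------------------------------------------------------


class _Block:
    """One item's parameters, category collapse maps, and fitting scopes.

    A *scope* is a set of respondents sharing one parameter set: the whole
    sample for ``shared`` items, one gender for group-specific pieces.
    """

    def __init__(
        self,
        item: int,
        model: Model,
        x: np.ndarray,
        groups: np.ndarray,
        n_groups: int,
        constraint: Constraint,
        n_full: int,
        config: EmConfig,
    ):
        self.item = item
        self.model = model
        self.constraint = constraint if n_groups > 1 else "shared"
        self.n_full = n_full
        self.config = config
        self.n_groups = n_groups
        if self.constraint == "shared":
            self.scopes = [np.arange(n_groups)]
        else:
            self.scopes = [np.array([g]) for g in range(n_groups)]
        self.cats: list[np.ndarray] = []
        self.code_map: list[np.ndarray] = []
        for scope in self.scopes:
            mask = np.isin(groups, scope)
            cats = np.unique(x[mask])
            if cats.size < 2:
                raise ValueError(
                    f"item {item + 1}: fewer than 2 observed categories in scope"
                )
            cmap = np.full(n_full, -1, dtype=np.int64)
            cmap[cats] = np.arange(cats.size)
            self.cats.append(cats)
            self.code_map.append(cmap)
        if model == "nrm" and self.constraint == "thresholds_free":
            if not all(np.array_equal(c, self.cats[0]) for c in self.cats):
                raise ValueError(
                    f"item {item + 1}: shared-slope NRM constraint requires the "
                    "same observed categories in every gender; use 'free'"
                )
        self._init_params(x, groups)

    # -- starting values from empirical category proportions ----------------
    def _init_params(self, x: np.ndarray, groups: np.ndarray) -> None:
        if self.model == "grm":
            self.a = 1.0
            self.b: list[np.ndarray] = []
            for si, scope in enumerate(self.scopes):
                mask = np.isin(groups, scope)
                codes = self.code_map[si][x[mask]]
                K = self.cats[si].size
                counts = np.bincount(codes, minlength=K).astype(float)
                p_ge = 1.0 - np.cumsum(counts)[:-1] / counts.sum()
                b = -np.log(np.clip(p_ge, 1e-3, 1 - 1e-3) / (1 - np.clip(p_ge, 1e-3, 1 - 1e-3)))
                for k in range(1, b.size):  # enforce strict increase
                    b[k] = max(b[k], b[k - 1] + 1e-3)
                self.b.append(b)
            if self.constraint == "free":
                self.a_per = [1.0 for _ in self.scopes]
        else:
            self.refs: list[int] = []
            self.a_nrm: list[np.ndarray] = []
            self.c_nrm: list[np.ndarray] = []
            for si, scope in enumerate(self.scopes):
                mask = np.isin(groups, scope)
                codes = self.code_map[si][x[mask]]
                K = self.cats[si].size
                ref = int(np.where(self.cats[si] == 0)[0][0]) if 0 in self.cats[si] else 0
                counts = np.bincount(codes, minlength=K).astype(float) + 0.5
                c = np.log(counts / counts[ref])
                a = np.linspace(-0.5, 0.5, K)
                a -= a[ref]
                c -= c[ref]
                self.refs.append(ref)
                self.a_nrm.append(a)
                self.c_nrm.append(c)

    def warm_start_from(self, params: dict[str, list], group_names: list[str]) -> None:
        """Seed the block from a previous fit's exported parameters."""
        for si, scope in enumerate(self.scopes):
            name = group_names[scope[0]] if len(scope) == 1 else None
            source = params.get(name) or params.get("all") or next(iter(params.values()))
            p = source[self.item]
            if self.model == "grm":
                cats = self.cats[si]
                b_full = np.asarray(p.b, dtype=float)
                b = b_full[cats[1:] - 1]
                if np.any(~np.isfinite(b)):
                    continue  # category pattern changed; keep empirical start
                for k in range(1, b.size):
                    b[k] = max(b[k], b[k - 1] + 1e-4)
                self.b[si] = b
                if self.constraint == "free":
                    self.a_per[si] = float(p.a)
                else:
                    self.a = float(p.a)
            else:
                cats = self.cats[si]
                a = np.asarray(p.a, dtype=float)[cats]
                c = np.asarray(p.c, dtype=float)[cats]
                if np.any(~np.isfinite(a)) or np.any(~np.isfinite(c)):
                    continue
                ref = self.refs[si]
                self.a_nrm[si] = a - a[ref]
                self.c_nrm[si] = c - c[ref]

    # -- probability tables per group ---------------------------------------
    def tables(self, nodes: np.ndarray) -> list[np.ndarray]:
        """Per *scope* (K_local, Q) probability tables."""
        out = []
        for si in range(len(self.scopes)):
            if self.model == "grm":
                a = self.a_per[si] if self.constraint == "free" else self.a
                F = expit(a * (nodes[None, :] - self.b[si][:, None]))
                ext = np.concatenate(
                    [np.ones((1, nodes.size)), F, np.zeros((1, nodes.size))], axis=0
                )
                out.append(np.clip(ext[:-1] - ext[1:], _PCLIP, None))
            else:
                logits = self.a_nrm[si][:, None] * nodes[None, :] + self.c_nrm[si][:, None]
                out.append(np.clip(softmax(logits, axis=0), _PCLIP, None))
        return out

    def scope_of_group(self, g: int) -> int:
        return 0 if self.constraint == "shared" else g

    # -- M-step --------------------------------------------------------------
    def mstep(self, R_per_scope: list[np.ndarray], nodes: np.ndarray) -> None:
        cfg = self.config
        if self.model == "grm":
            if self.constraint == "free":
                for si, R in enumerate(R_per_scope):
                    a, bs = _mstep_grm([R], nodes, self.a_per[si], [self.b[si]], cfg)
                    self.a_per[si], self.b[si] = a, bs[0]
            else:
                self.a, self.b = _mstep_grm(R_per_scope, nodes, self.a, self.b, cfg)
        else:
            if self.constraint == "thresholds_free":
                ref = self.refs[0]
                free = [k for k in range(self.cats[0].size) if k != ref]
                a0 = self.a_nrm[0][free]
                c0s = [self.c_nrm[si][free] for si in range(len(self.scopes))]
                a_free, c_list = _mstep_nrm(R_per_scope, nodes, a0, c0s, ref, cfg)
                for si in range(len(self.scopes)):
                    self.a_nrm[si] = self._unpack(a_free, ref)
                    self.c_nrm[si] = self._unpack(c_list[si], ref)
            else:
                for si, R in enumerate(R_per_scope):
                    ref = self.refs[si]
                    free = [k for k in range(self.cats[si].size) if k != ref]
                    a_free, c_list = _mstep_nrm(
                        [R], nodes, self.a_nrm[si][free], [self.c_nrm[si][free]], ref, cfg
                    )
                    self.a_nrm[si] = self._unpack(a_free, ref)
                    self.c_nrm[si] = self._unpack(c_list[0], ref)

    @staticmethod
    def _unpack(free_vals: np.ndarray, ref: int) -> np.ndarray:
        full = np.zeros(free_vals.size + 1)
        full[np.arange(full.size) != ref] = free_vals
        return full

    # -- bookkeeping ---------------------------------------------------------
    def state_vector(self) -> np.ndarray:
        if self.model == "grm":
            a = self.a_per if self.constraint == "free" else [self.a]
            return np.concatenate([np.atleast_1d(a).ravel()] + [b for b in self.b])
        return np.concatenate(self.a_nrm + self.c_nrm)

    def n_params(self) -> int:
        if self.model == "grm":
            n_thr = sum(c.size - 1 for c in self.cats)
            n_slope = len(self.scopes) if self.constraint == "free" else 1
            return n_slope + n_thr
        n_int = sum(c.size - 1 for c in self.cats)
        if self.constraint == "thresholds_free":
            return (self.cats[0].size - 1) + n_int
        return n_int * 2  # slopes + intercepts per scope; scopes summed via n_int

    def export(self, group_names: list[str]) -> dict[str, object]:
        """Full-category parameter objects per group name (NaN = unestimated)."""
        out: dict[str, object] = {}
        for g, name in enumerate(group_names):
            si = self.scope_of_group(g)
            cats = self.cats[si]
            if self.model == "grm":
                b_full = np.full(self.n_full - 1, np.nan)
                b_local = self.b[si]
                b_full[cats[1:] - 1] = b_local
                a = self.a_per[si] if self.constraint == "free" else self.a
                out[name] = GrmItemParams(a=float(a), b=b_full)
            else:
                a_full = np.full(self.n_full, np.nan)
                c_full = np.full(self.n_full, np.nan)
                a_full[cats] = self.a_nrm[si]
                c_full[cats] = self.c_nrm[si]
                # if category 0 was never observed the local reference (first
                # observed category) stays pinned at 0 and slot 0 remains NaN
                out[name] = NrmItemParams(a=a_full, c=c_full)
        return out

    def check_cap(self) -> None:
        cap = self.config.a_cap
        if self.model == "grm":
            slopes = self.a_per if self.constraint == "free" else [self.a]
        else:
            slopes = [float(np.max(np.abs(a))) for a in self.a_nrm]
        if any(abs(s) >= cap - 1e-6 for s in np.atleast_1d(slopes)):
            warnings.warn(
                f"item {self.item + 1}: discrimination at the cap ({cap}); "
                "sparse categories may be driving divergence",
                stacklevel=3,
            )


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------


def _prepare(
    data,
    model: Model,
    group_by: str | None,
    groups,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(data, np.ndarray):
        X = np.asarray(data, dtype=np.int64)
        if groups is None:
            return X, np.zeros(len(X), dtype=np.int64), ["all"]
        groups = np.asarray(groups)
        names = sorted(set(groups.tolist()))
        gidx = np.array([names.index(g) for g in groups], dtype=np.int64)
        return X, gidx, [str(n) for n in names]
    records: Sequence[ResponseRecord] = [r for r in data if r.complete]
    if group_by == "gender":
        kept = [r for r in records if r.gender is not None]
        if len(kept) < len(records):
            warnings.warn(
                f"{len(records) - len(kept)} records without gender excluded "
                "from the gender-grouped fit",
                stacklevel=3,
            )
        records = kept
        coding = "product" if model == "grm" else "combination"
        X = category_matrix(records, coding)
        names = ["male", "female"]
        gidx = np.array([names.index(r.gender) for r in records], dtype=np.int64)
        return X, gidx, names
    coding = "product" if model == "grm" else "combination"
    return category_matrix(records, coding), np.zeros(len(records), dtype=np.int64), ["all"]


# ---------------------------------------------------------------------------
# The EM driver
# ---------------------------------------------------------------------------


def fit_mmle_em(
    data,
    model: Model = "grm",
    grid: QuadratureGrid | None = None,
    group_by: str | None = None,
    groups=None,
    constraints: dict[int, Constraint] | None = None,
    config: EmConfig | None = None,
    start: FitResult | None = None,
) -> FitResult:
    """Fit a GRM or NRM by MMLE-EM.

    Parameters
    ----------
    data
        Complete :class:`ResponseRecord` sequence, or an (N, 9) integer
        category-index matrix (product categories for GRM, combination-label
        indices for NRM).
    group_by, groups
        ``group_by="gender"`` splits records by gender; with a matrix, pass
        ``groups`` explicitly. ``constraints`` maps 1-based item numbers to
        ``shared`` (default), ``thresholds_free`` or ``free``.
    start
        A previous :class:`FitResult` used as warm start (e.g. the anchored
        fit when testing one item's DIF).
    """
    config = config or EmConfig()
    grid = grid or normal_grid()
    X, gidx, group_names = _prepare(data, model, group_by, groups)
    N, n_items = X.shape
    if N == 0:
        raise ValueError("no complete records to fit")
    if n_items != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} items, got {n_items}")
    n_groups = len(group_names)
    n_full = 7 if model == "grm" else 10
    constraints = {int(k): v for k, v in (constraints or {}).items()}
    blocks = [
        _Block(
            i, model, X[:, i], gidx, n_groups,
            constraints.get(i + 1, "shared"), n_full, config,
        )
        for i in range(n_items)
    ]
    if start is not None:
        for blk in blocks:
            blk.warm_start_from(start.params, group_names)

    nodes, logw = grid.nodes, grid.log_weights
    Q = nodes.size
    group_rows = [np.flatnonzero(gidx == g) for g in range(n_groups)]
    # local codes per (item, group): constant across iterations
    local_codes = [
        [blk.code_map[blk.scope_of_group(g)][X[rows, blk.item]] for g, rows in enumerate(group_rows)]
        for blk in blocks
    ]

    trace: list[float] = []
    prev_state = np.concatenate([blk.state_vector() for blk in blocks])
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        tables = [blk.tables(nodes) for blk in blocks]
        logL = np.zeros((N, Q))
        for bi, blk in enumerate(blocks):
            for g, rows in enumerate(group_rows):
                if rows.size == 0:
                    continue
                tab = tables[bi][blk.scope_of_group(g)]
                logL[rows] += np.log(tab)[local_codes[bi][g]]
        lw = logL + logw[None, :]
        person_ll = logsumexp(lw, axis=1)
        ll = float(person_ll.sum())
        trace.append(ll)
        W = np.exp(lw - person_ll[:, None])  # posterior weights, rows sum to 1

        for bi, blk in enumerate(blocks):
            R_per_scope = []
            for si, scope in enumerate(blk.scopes):
                K = blk.cats[si].size
                R = np.zeros((K, Q))
                for g in scope:
                    rows = group_rows[g]
                    if rows.size:
                        np.add.at(R, local_codes[bi][g], W[rows])
                R_per_scope.append(R)
            blk.mstep(R_per_scope, nodes)

        state = np.concatenate([blk.state_vector() for blk in blocks])
        dparam = float(np.max(np.abs(state - prev_state)))
        prev_state = state
        if it > 1 and abs(trace[-1] - trace[-2]) < config.tol_loglik and dparam < config.tol_param:
            converged = True
            break

    # final log-likelihood at the last parameter values
    tables = [blk.tables(nodes) for blk in blocks]
    logL = np.zeros((N, Q))
    for bi, blk in enumerate(blocks):
        for g, rows in enumerate(group_rows):
            if rows.size == 0:
                continue
            logL[rows] += np.log(tables[bi][blk.scope_of_group(g)])[local_codes[bi][g]]
    ll = float(logsumexp(logL + logw[None, :], axis=1).sum())
    trace.append(ll)

    for blk in blocks:
        blk.check_cap()

    params: dict[str, list] = {name: [] for name in group_names}
    for blk in blocks:
        exported = blk.export(group_names)
        for name in group_names:
            params[name].append(exported[name])
    n_params = sum(blk.n_params() for blk in blocks)
    return FitResult(
        model=model,
        params=params,
        loglik=ll,
        n_params=n_params,
        n_obs=N,
        converged=converged,
        n_iter=it,
        loglik_trace=np.asarray(trace),
        constraints={i + 1: blk.constraint for i, blk in enumerate(blocks)},
    )


# ---------------------------------------------------------------------------
# Likelihood / posterior utilities on exported parameters
# ---------------------------------------------------------------------------


def _tables_from_params(
    items: Sequence, model: Model, nodes: np.ndarray
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per item: (full->local code map, (K_local, Q) table); NaN cats dropped."""
    out = []
    for p in items:
        if model == "grm":
            finite = np.isfinite(p.b)
            boundary_cats = np.flatnonzero(finite) + 1  # category entered at each threshold
            F = expit(p.a * (nodes[None, :] - p.b[finite][:, None]))
            ext = np.concatenate([np.ones((1, nodes.size)), F, np.zeros((1, nodes.size))])
            tab = np.clip(ext[:-1] - ext[1:], _PCLIP, None)
            n_full = len(p.b) + 1
            # NaN thresholds band categories together: any category below the
            # first estimated boundary shares the bottom band, a category with
            # a missing threshold shares the band of the boundary below it
            cmap = np.searchsorted(boundary_cats, np.arange(n_full), side="right").astype(np.int64)
        else:
            finite = np.isfinite(p.a) & np.isfinite(p.c)
            cats = np.flatnonzero(finite)
            logits = p.a[finite][:, None] * nodes[None, :] + p.c[finite][:, None]
            tab = np.clip(softmax(logits, axis=0), _PCLIP, None)
            n_full = len(p.a)
            cmap = np.full(n_full, -1, dtype=np.int64)
            cmap[cats] = np.arange(cats.size)
        out.append((cmap, tab))
    return out


def _person_log_tables(
    X: np.ndarray,
    params: dict[str, list],
    model: Model,
    nodes: np.ndarray,
    group_of: np.ndarray | None,
    group_names: list[str],
) -> np.ndarray:
    """(N, items, Q) per-item log-probabilities at each node."""
    N, n_items = X.shape
    Q = nodes.size
    out = np.zeros((N, n_items, Q))
    for g, name in enumerate(group_names):
        rows = np.flatnonzero(group_of == g) if group_of is not None else np.arange(N)
        if rows.size == 0:
            continue
        tabs = _tables_from_params(params[name], model, nodes)
        for i, (cmap, tab) in enumerate(tabs):
            codes = cmap[X[rows, i]]
            if np.any(codes < 0):
                bad = X[rows, i][codes < 0]
                raise ValueError(
                    f"item {i + 1}: responses in categories with no parameters: "
                    f"{sorted(set(bad.tolist()))}"
                )
            out[rows, i, :] = np.log(tab)[codes]
    return out


def _as_matrix_and_groups(data, model: Model, params: dict[str, list]):
    group_names = list(params.keys())
    if isinstance(data, np.ndarray):
        if len(group_names) > 1:
            raise ValueError("pass records (with gender) for group-specific parameters")
        return np.asarray(data, dtype=np.int64), None, group_names
    records = [r for r in data if r.complete]
    coding = "product" if model == "grm" else "combination"
    X = category_matrix(records, coding)
    if len(group_names) == 1:
        return X, None, group_names
    gidx = np.array([group_names.index(r.gender) for r in records], dtype=np.int64)
    return X, gidx, group_names


def marginal_loglik(
    data,
    params: dict[str, list],
    grid: QuadratureGrid | None = None,
    model: Model = "grm",
) -> float:
    """Observed marginal log-likelihood of ``data`` under fixed parameters."""
    grid = grid or normal_grid()
    X, gidx, names = _as_matrix_and_groups(data, model, params)
    if len(X) == 0:
        raise ValueError("empty record set")
    tabs = _person_log_tables(X, params, model, grid.nodes, gidx, names)
    lw = tabs.sum(axis=1) + grid.log_weights[None, :]
    return float(logsumexp(lw, axis=1).sum())


def eap_theta(
    data,
    params: dict[str, list],
    grid: QuadratureGrid | None = None,
    model: Model = "grm",
    exclude_item: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """EAP severity estimates (posterior mean, posterior SD) per respondent.

    ``exclude_item`` (1-based) drops one item from the posterior — the
    rest-score posterior used by the item-fit diagnostic. A respondent with no
    contributing items gets the prior mean 0 and the prior SD.
    """
    grid = grid or normal_grid()
    single = isinstance(data, ResponseRecord)
    if single:
        data = [data]
    if not isinstance(data, np.ndarray):
        data = [r for r in data]
        # allow incomplete records: answered items contribute, others are ignored
        from .instrument import COMBINATION_INDEX, combination_category, product_category

        X_rows = []
        for rec in data:
            row = []
            for resp in rec.responses:
                if resp is None:
                    row.append(-1)
                elif model == "grm":
                    row.append(product_category(resp))
                else:
                    row.append(COMBINATION_INDEX[combination_category(resp)])
            X_rows.append(row)
        X = np.asarray(X_rows, dtype=np.int64)
        names = list(params.keys())
        if len(names) > 1:
            gidx = np.array([names.index(r.gender) for r in data], dtype=np.int64)
        else:
            gidx = None
    else:
        X = np.asarray(data, dtype=np.int64)
        names = list(params.keys())
        gidx = None

    N = len(X)
    Q = len(grid)
    logpost = np.tile(grid.log_weights, (N, 1))
    answered = X >= 0
    Xs = np.where(answered, X, 0)
    tabs = _person_log_tables(Xs, params, model, grid.nodes, gidx, names)
    tabs = np.where(answered[:, :, None], tabs, 0.0)
    if exclude_item is not None:
        tabs[:, exclude_item - 1, :] = 0.0
    logpost = logpost + tabs.sum(axis=1)
    logpost -= logsumexp(logpost, axis=1, keepdims=True)
    W = np.exp(logpost)
    mean = W @ grid.nodes
    second = W @ (grid.nodes**2)
    sd = np.sqrt(np.maximum(second - mean**2, 0.0))
    if single:
        return float(mean[0]), float(sd[0])
    return mean, sd


def information_criteria(loglik: float, n_params: int, n_obs: float) -> tuple[float, float]:
    """(AIC, BIC) from their defining formulas."""
    if not np.isfinite(loglik):
        raise ValueError("log-likelihood must be finite")
    if n_obs <= 1:
        raise ValueError("need more than one observation for BIC")
    aic = -2.0 * loglik + 2.0 * n_params
    bic = -2.0 * loglik + n_params * np.log(n_obs)
    return aic, bic


def likelihood_ratio_test(
    fit_constrained: FitResult, fit_free: FitResult, tol: float = 0.05
) -> tuple[float, int, float]:
    """LRT of nested fits: chi2 = 2 (ll_free - ll_constrained), upper-tail p."""
    df = fit_free.n_params - fit_constrained.n_params
    if df <= 0:
        raise ValueError("free model must have more parameters than the constrained one")
    chi2 = 2.0 * (fit_free.loglik - fit_constrained.loglik)
    if chi2 < -tol:
        raise RefitNeeded(
            f"constrained fit beats the free fit by {-chi2 / 2:.4f} log-lik units; "
            "one of the EM runs stopped at a local optimum - refit with more "
            "iterations or a better start"
        )
    chi2 = max(chi2, 0.0)
    return chi2, df, float(stats.chi2.sf(chi2, df))
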