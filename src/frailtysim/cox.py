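"""Semiparametric proportional-hazards machinery on counting-process data.

Newton maximization of the Breslow partial likelihood with optional offsets
(fixed coefficient 1, as required by the EM M-step of the frailty model),
the Breslow cumulative baseline hazard, and Schoenfeld / martingale
residuals.  Risk sets use half-open intervals: a row is at risk at t iff
``start < t <= stop``.  Ties are handled with the Breslow convention
throughout (simulated event times are continuous, so ties are measure-zero;
tied times in external data simply share a risk set).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from frailtysim.data import SurvData

__all__ = ["CoxFit", "CoxWorkspace", "fit_cox", "breslow_cumhaz", "residuals"]

_MAX_NEWTON = 50
_LOGLIK_TOL = 1e-9
# |beta| beyond this on a (centered) covariate scale indicates monotone
# likelihood: the partial likelihood plateaus and Newton "converges" at an
# arbitrary large value
_SEPARATION_BOUND = 15.0


class CoxWorkspace:
    """Precomputed risk-set structure for repeated fits on one dataset.

    The frailty EM refits the same dataset hundreds of times, so the
    risk-set bookkeeping is built once: right-censored data (all rows start
    at 0) get O(n) suffix-cumsum risk sums over rows sorted by stop time,
    genuine start-stop data a dense at-risk matrix.
    """

    def __init__(self, data: SurvData):
        self.data = data
        status = data.status.astype(bool)
        if not status.any():
            raise ValueError("need at least one event to fit a Cox model")
        self.event_rows = np.flatnonzero(status)
        ev_times = data.stop[self.event_rows]
        self.times, inverse, counts = np.unique(
            ev_times, return_inverse=True, return_counts=True
        )
        self.event_time_idx = inverse  # per event row -> unique-time index
        self.d = counts.astype(float)  # events per unique time
        # right-censored data (all start at 0): risk-set sums are suffix
        # cumsums over rows sorted by stop, O(n); otherwise a dense at-risk
        # matrix over half-open intervals start < t_k <= stop
        self.simple = bool(np.all(data.start == 0))
        if self.simple:
            self.order = np.argsort(data.stop, kind="stable")
            self._pos = np.searchsorted(
                data.stop[self.order], self.times, side="left"
            )
            self.R = None
        else:
            t = self.times[:, None]
            self.R = (
                (data.start[None, :] < t) & (t <= data.stop[None, :])
            ).astype(np.float64)
        self.Xc_mean = data.X.mean(axis=0) if data.X.size else np.zeros(0)
        self.Xc = data.X - self.Xc_mean
        # sum of centered covariates over events at each unique time
        p = self.Xc.shape[1]
        self.sx = np.zeros((len(self.times), p))
        np.add.at(self.sx, self.event_time_idx, self.Xc[self.event_rows])
        self.n_events = int(status.sum())

    def risk_sums(self, values: np.ndarray) -> np.ndarray:
        """Sum `values` over the risk set of each unique event time."""
        if self.simple:
            v = values[self.order]
            suffix = np.cumsum(v[::-1], axis=0)[::-1]
            pad_shape = (1,) + v.shape[1:]
            suffix = np.concatenate([suffix, np.zeros(pad_shape)], axis=0)
            return suffix[self._pos]
        return self.R @ values

    def interval_cumhaz(self, dL: np.ndarray) -> np.ndarray:
        """Per-row baseline hazard mass accumulated over (start, stop]."""
        cum = np.concatenate([[0.0], np.cumsum(dL)])
        hi = np.searchsorted(self.times, self.data.stop, side="right")
        lo = np.searchsorted(self.times, self.data.start, side="right")
        return cum[hi] - cum[lo]


@dataclass
class CoxFit:
    """Result of a partial-likelihood fit."""

    beta: np.ndarray
    var: np.ndarray  # inverse observed information of beta
    loglik: float  # maximized Breslow partial log-likelihood
    baseline_times: np.ndarray  # unique event times
    baseline_steps: np.ndarray  # Breslow increments dLambda0 at those times
    n_events: int
    offsets: np.ndarray | None
    workspace: CoxWorkspace
    flags: list[str] = field(default_factory=list)
    n_iter: int = 0

    @property
    def converged(self) -> bool:
        return "not_converged" not in self.flags and "separation" not in self.flags

    def full_loglik(self) -> float:
        """Log-likelihood including the Breslow baseline term.

        ``sum_events [eta + log dLambda0] - N`` (the integral term collapses
        to the event count by the Breslow property).
        """
        ws = self.workspace
        eta = self.linear_predictor()
        ev = ws.event_rows
        return float(
            eta[ev].sum()
            + (ws.d * np.log(self.baseline_steps)).sum()
            - ws.n_events
        )

    def linear_predictor(self) -> np.ndarray:
        eta = self.workspace.data.X @ self.beta
        if self.offsets is not None:
            eta = eta + self.offsets
        return eta


def _newton(ws: CoxWorkspace, offsets, init_beta, max_iter, tol):
    """Maximize the Breslow partial likelihood; returns beta, var, ll, iters, flags."""
    p = ws.Xc.shape[1]
    flags: list[str] = []
    off = np.zeros(len(ws.data)) if offsets is None else np.asarray(offsets, float)
    if p == 0:
        w = np.exp(off)
        S0 = ws.risk_sums(w)
        ll = float(off[ws.event_rows].sum() - (ws.d * np.log(S0)).sum())
        return np.zeros(0), np.zeros((0, 0)), ll, 0, flags

    beta = np.zeros(p) if init_beta is None else np.array(init_beta, float)

    def eval_ll(b):
        eta = off + ws.Xc @ b
        w = np.exp(eta - eta.max())
        S0 = ws.risk_sums(w)
        ll = float(
            (eta[ws.event_rows] - eta.max()).sum() - (ws.d * np.log(S0)).sum()
        )
        return ll, w, S0

    ll, w, S0 = eval_ll(beta)
    info = np.eye(p)
    it = 0
    for it in range(1, max_iter + 1):
        if p == 1:
            x1 = ws.Xc[:, 0]
            wx = w * x1
            sums = ws.risk_sums(np.column_stack([wx, wx * x1]))
            xbar = sums[:, 0] / S0
            U = np.array([(ws.sx[:, 0] - ws.d * xbar).sum()])
            info = np.array([[(ws.d * (sums[:, 1] / S0 - xbar * xbar)).sum()]])
        else:
            WX = w[:, None] * ws.Xc
            iu, ju = np.triu_indices(p)
            sums = ws.risk_sums(
                np.column_stack([WX, WX[:, iu] * ws.Xc[:, ju]])
            )
            S1 = sums[:, :p]
            Xbar = S1 / S0[:, None]
            U = (ws.sx - ws.d[:, None] * Xbar).sum(axis=0)
            S2 = np.zeros((len(S0), p, p))
            S2[:, iu, ju] = sums[:, p:]
            S2[:, ju, iu] = sums[:, p:]
            info = (
                ws.d[:, None, None]
                * (S2 / S0[:, None, None] - Xbar[:, :, None] * Xbar[:, None, :])
            ).sum(axis=0)
        try:
            step = np.linalg.solve(info, U)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, U, rcond=None)[0]
            flags.append("singular_information")
        # step-halving on overshoot
        new_beta = beta + step
        new_ll, new_w, new_S0 = eval_ll(new_beta)
        halvings = 0
        while not np.isfinite(new_ll) or new_ll < ll - 1e-12:
            halvings += 1
            if halvings > 30:
                break
            step = step / 2.0
            new_beta = beta + step
            new_ll, new_w, new_S0 = eval_ll(new_beta)
        delta = new_ll - ll
        beta, ll, w, S0 = new_beta, new_ll, new_w, new_S0
        if np.abs(delta) < tol * (np.abs(ll) + 1.0):
            break
    else:
        flags.append("not_converged")
    if np.any(np.abs(beta) > _SEPARATION_BOUND):
        flags.append("separation")
    # variance from the information at the solution
    try:
        var = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        var = np.linalg.pinv(info)
        if "singular_information" not in flags:
            flags.append("singular_information")
    return beta, var, ll, it, flags


def fit_cox(
    data: SurvData | CoxWorkspace,
    offsets: np.ndarray | None = None,
    init_beta: np.ndarray | None = None,
    max_iter: int = _MAX_NEWTON,
    tol: float = _LOGLIK_TOL,
) -> CoxFit:
    """Fit a proportional-hazards model by Breslow partial likelihood.

    ``offsets`` enter the linear predictor with coefficient fixed at 1.
    Monotone-likelihood (separation) is reported through ``fit.flags``
    rather than raised.
    """
    ws = data if isinstance(data, CoxWorkspace) else CoxWorkspace(data)
    beta, var, ll, it, flags = _newton(ws, offsets, init_beta, max_iter, tol)
    # Breslow baseline on the original (uncentered) covariate scale
    off = np.zeros(len(ws.data)) if offsets is None else np.asarray(offsets, float)
    eta = off + ws.data.X @ beta
    S0 = ws.risk_sums(np.exp(eta))
    steps = ws.d / S0
    return CoxFit(
        beta=beta,
        var=var,
        loglik=ll,
        baseline_times=ws.times,
        baseline_steps=steps,
        n_events=ws.n_events,
        offsets=None if offsets is None else np.asarray(offsets, float),
        workspace=ws,
        flags=flags,
        n_iter=it,
    )


def breslow_cumhaz(fit: CoxFit, t) -> np.ndarray | float:
    """Step-function estimate of the cumulative baseline hazard at times t."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    cum = np.concatenate([[0.0], np.cumsum(fit.baseline_steps)])
    idx = np.searchsorted(fit.baseline_times, t, side="right")
    out = cum[idx]
    return out if out.shape else float(out)


def residuals(fit: CoxFit, kind: str) -> np.ndarray:
    """Schoenfeld (per event), scaled Schoenfeld, or martingale (per row)."""
    ws = fit.workspace
    if kind == "martingale":
        eta = fit.linear_predictor()
        return ws.data.status - np.exp(eta) * ws.interval_cumhaz(
            fit.baseline_steps
        )
    if kind in ("schoenfeld", "scaled_schoenfeld"):
        eta = fit.linear_predictor()
        w = np.exp(eta - eta.max())
        S0 = ws.risk_sums(w)
        S1 = ws.risk_sums(w[:, None] * ws.Xc)
        xbar = S1 / S0[:, None]  # centered risk-set mean per unique time
        sch = ws.Xc[ws.event_rows] - xbar[ws.event_time_idx]
        if kind == "schoenfeld":
            return sch
        return fit.n_events * (sch @ fit.var) + fit.beta[None, :]
    raise ValueError(f"unknown residual kind {kind!r}")
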