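"""Per-position rate estimation by Levenberg-Marquardt least squares.

The observed quantity is the unity-normalized species x time intensity
matrix.  The model prediction is the simulated decay chain started from
the intact substrate, passed through the same unity-based normalization,
so the unknown fluorescence scale cancels and the removal rates are the
only free parameters.  The residual is the element-wise difference,
flattened over species x time, and is minimized with the MINPACK LM
algorithm.

Positivity of the rates is enforced by fitting ``theta = log(lambda)``
(default); a box-constrained fit of ``lambda`` directly is available via
``mode="box"``.  Standard errors come from the Gauss-Newton curvature:
``SE^2 = sigma2 * diag((J'J)^-1)`` with ``sigma2 = RSS / (m - k)``,
mapped back to rate units by the delta method in log mode.  For reactions
that do not run to completion the chain can be truncated: species beyond a
cut index are aggregated into the cut species, which the companion model
treats as absorbing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .densitometry import normalize_assay
from .kinetics import RateProfile, TimeCourseMatrix, simulate_deadenylation

__all__ = [
    "DeadenylationKineticsModel",
    "FitResult",
    "residual",
    "estimate_rates",
    "truncate_observations",
    "holdout_validate",
    "informative_positions",
    "nonoverlapping_intervals",
]


def _unit_scale(v: np.ndarray) -> np.ndarray:
    return v / v.max()


def _simulate_normalized(rates: np.ndarray, times: np.ndarray) -> np.ndarray:
    x0 = np.zeros(rates.size + 1)
    x0[0] = 1.0
    sim = simulate_deadenylation(rates, x0, times, method="expm")
    return _unit_scale(sim.values)


def residual(rates, observed: TimeCourseMatrix) -> np.ndarray:
    """Observed minus predicted, flattened over species x time.

    Both matrices pass through the same unity-based normalization before
    differencing.
    """
    lam = rates.rates if isinstance(rates, RateProfile) else np.asarray(rates, float)
    if lam.size != observed.n_species - 1:
        raise ValueError(
            f"rates length {lam.size} does not match {observed.n_species} species"
        )
    obs = _unit_scale(observed.values)
    pred = _simulate_normalized(lam, observed.times)
    return (obs - pred).ravel()


def truncate_observations(
    observed: TimeCourseMatrix, T: int, coordinate: str = "species"
) -> TimeCourseMatrix:
    """Aggregate species beyond ``T`` into species ``T``.

    Used when a reaction does not complete: marginal RNA levels beyond the
    cut are summed into the cut species, which the truncated model treats
    as absorbing (only ``lam_1..lam_{T-1}`` are then estimated).  Column
    totals are preserved exactly.  ``coordinate="species"`` (default)
    reads ``T`` as the gel-species index; ``coordinate="position"`` reads
    it as a tail position and cuts at species ``T`` counted from the 3'
    end of the tail, which for these substrates is the same index — the
    switch exists because the two conventions diverge for matrices that
    do not start at the intact species.
    """
    if coordinate not in ("species", "position"):
        raise ValueError("coordinate must be 'species' or 'position'")
    n = observed.n_species
    if not 2 <= T <= n:
        raise ValueError(f"truncation index {T} outside 2..{n}")
    if T == n:
        return observed.copy()
    vals = observed.values[:T].copy()
    vals[T - 1] += observed.values[T:].sum(axis=0)
    return TimeCourseMatrix(vals, observed.times, observed.normalized)


def _peak_time_init(obs_scaled: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Initial rates from species peak times.

    On a decay chain the reaction front populates species ``s`` maximally
    around cumulative time ``sum(1/lambda_q, q < s)``, so successive
    peak-time differences approximate per-position removal times.  Zero
    gaps (species peaking at the same coarse time point) are floored at a
    quarter of the median positive gap.
    """
    t_peak = np.maximum.accumulate(times[np.argmax(obs_scaled, axis=1)])
    gaps = np.diff(t_peak)
    positive = gaps[gaps > 0]
    if positive.size == 0:
        return np.full(obs_scaled.shape[0] - 1, (obs_scaled.shape[0] - 1) / times[-1])
    return 1.0 / np.clip(gaps, 0.25 * np.median(positive), None)


def informative_positions(
    observed: TimeCourseMatrix, threshold: float = 0.02
) -> np.ndarray:
    """Boolean mask over positions p = 1..N with adequate signal.

    The rate at position ``p`` is considered identifiable when both the
    species it drains (``s = p``) and the species it feeds (``s = p+1``)
    reach at least ``threshold`` of the matrix maximum at some time point.
    """
    v = observed.values / observed.values.max()
    peak = v.max(axis=1)
    return (peak[:-1] >= threshold) & (peak[1:] >= threshold)


class DeadenylationKineticsModel(BaseEstimator):
    """Markov decay-chain rate estimator (scikit-learn interface).

    ``fit`` takes a raw or normalized species x time matrix and estimates
    the per-position removal rates by Levenberg-Marquardt; ``predict``
    returns the normalized model matrix at the fitted rates (the in-silico
    re-simulation used to check the fit against the data).

    Parameters
    ----------
    init_rate : "auto", float or array
        Starting rate(s).  ``"auto"`` (default) reads initial removal
        times off the data as differences of species peak times — on a
        decay chain each species is maximally populated roughly when the
        reaction front passes it, so peak-time gaps approximate ``1 /
        lambda`` and place stalls near the right positions.  A scalar
        gives a uniform start; ``N / t_max`` (a uniform rate that just
        finishes the tail over the assay window) is a reasonable manual
        choice.  If the first solution is poor, a small set of fallback
        starts is tried and the best kept.
    mode : {"log", "box"}
        ``"log"`` fits ``log(lambda)`` with plain (unconstrained) LM;
        ``"box"`` fits ``lambda`` with nonnegativity bounds (trust-region
        reflective, since bounded MINPACK LM is not available).
    truncate : int, optional
        Truncation index ``T``; species beyond it are aggregated (see
        :func:`truncate_observations`) and treated as absorbing.
    truncate_coordinate : {"species", "position"}
        Interpretation of ``truncate``.
    max_iterations : int
        Cap on residual evaluations handed to the optimizer.
    tol : float
        ``ftol``/``xtol``/``gtol`` for the optimizer.
    signal_threshold : float
        Threshold for :func:`informative_positions`, used to flag
        positions whose estimates (and SEs) are unreliable.

    Attributes
    ----------
    rates_ : ndarray
        Fitted removal rates, 3'-anchored positions ``1..N`` (or
        ``1..T-1`` when truncated).
    rates_se_ : ndarray
        Standard errors (NaN where the curvature is singular).
    informative_ : ndarray of bool
        Adequate-signal mask over the fitted positions.
    predicted_ : TimeCourseMatrix
        Normalized model matrix at the fitted rates.
    residual_norm_ : float
        Euclidean norm of the final residual vector.
    converged_ : bool
    n_iter_ : int
        Number of residual evaluations used.
    """

    def __init__(
        self,
        init_rate="auto",
        mode: str = "log",
        truncate: int | None = None,
        truncate_coordinate: str = "species",
        max_iterations: int = 2000,
        tol: float = 1e-10,
        signal_threshold: float = 0.02,
        se_method: str = "relative",
    ):
        self.init_rate = init_rate
        self.mode = mode
        self.truncate = truncate
        self.truncate_coordinate = truncate_coordinate
        self.max_iterations = max_iterations
        self.tol = tol
        self.signal_threshold = signal_threshold
        self.se_method = se_method

    # -- fitting ---------------------------------------------------------

    def fit(self, X: TimeCourseMatrix, y=None):
        observed = self._coerce(X)
        if observed.values.max() <= 0:
            raise ValueError("observed matrix is all zero")
        observed = normalize_assay(observed)
        if self.truncate is not None:
            observed = truncate_observations(
                observed, self.truncate, self.truncate_coordinate
            )
        n_par = observed.n_species - 1
        if observed.values.size < 2 * n_par:
            raise ValueError(
                f"{observed.values.size} data cells cannot support {n_par} rates"
            )
        obs_scaled = _unit_scale(observed.values)
        times = observed.times

        if self.mode not in ("log", "box"):
            raise ValueError("mode must be 'log' or 'box'")
        sol = None
        for lam0 in self._initial_rate_candidates(obs_scaled, n_par, times):
            trial = self._solve(lam0, obs_scaled, times)
            if sol is None or np.linalg.norm(trial.fun) < np.linalg.norm(sol.fun):
                sol = trial
            # an RMS residual within 2% of the unity scale is a clean fit;
            # anything larger triggers the fallback starts
            if np.linalg.norm(sol.fun) / np.sqrt(sol.fun.size) <= 0.02:
                break
        if self.mode == "log":
            self.rates_ = np.exp(sol.x)
            jac_scale = self.rates_  # d lambda / d theta, for the delta method
        else:
            self.rates_ = sol.x
            jac_scale = np.ones_like(sol.x)

        self.converged_ = bool(sol.success)
        if not self.converged_:
            warnings.warn(
                f"LM did not converge ({sol.message}); returning partial estimates",
                stacklevel=2,
            )
        self.n_iter_ = int(sol.nfev)
        self.residual_norm_ = float(np.linalg.norm(sol.fun))
        self.observed_ = observed
        self.informative_ = informative_positions(observed, self.signal_threshold)
        pred_ravel = obs_scaled.ravel() - sol.fun
        self.rates_se_ = self._standard_errors(sol.jac, sol.fun, jac_scale, pred_ravel)
        if not self.informative_.all():
            # a rate the reaction never exercises has no meaningful SE
            self.rates_se_[~self.informative_] = np.nan
            warnings.warn(
                "standard errors unavailable for positions without signal: "
                f"{(np.flatnonzero(~self.informative_) + 1).tolist()}",
                stacklevel=2,
            )
        self.predicted_ = TimeCourseMatrix(
            _simulate_normalized(self.rates_, times), times, normalized="assay"
        )
        return self

    def _coerce(self, X) -> TimeCourseMatrix:
        if isinstance(X, TimeCourseMatrix):
            return X
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            return TimeCourseMatrix.from_frame(X)
        raise TypeError("X must be a TimeCourseMatrix or its DataFrame form")

    def _solve(self, lam0, obs_scaled, times):
        if self.mode == "log":

            def fun(th):
                # clip to keep exp (and the propagator) in a sane range when
                # LM probes extreme steps
                return (
                    obs_scaled
                    - _simulate_normalized(np.exp(np.clip(th, -16.0, 16.0)), times)
                ).ravel()

            sol = least_squares(
                fun,
                np.log(lam0),
                method="lm",
                ftol=self.tol,
                xtol=self.tol,
                gtol=self.tol,
                max_nfev=self.max_iterations,
            )
            sol.x = np.clip(sol.x, -16.0, 16.0)
            return sol

        def fun(lam):
            return (obs_scaled - _simulate_normalized(lam, times)).ravel()

        return least_squares(
            fun,
            lam0,
            bounds=(0.0, np.inf),
            method="trf",
            ftol=self.tol,
            xtol=self.tol,
            gtol=self.tol,
            max_nfev=self.max_iterations,
        )

    def _initial_rate_candidates(self, obs_scaled, n_par, times):
        uniform = n_par / times[-1]
        if self.init_rate == "auto":
            cands = [
                _peak_time_init(obs_scaled, times),
                np.full(n_par, uniform),
                np.full(n_par, 0.5 * uniform),
                np.full(n_par, 2.0 * uniform),
            ]
        elif self.init_rate is None:
            cands = [np.full(n_par, uniform)]
        else:
            cands = [
                np.broadcast_to(np.asarray(self.init_rate, dtype=float), (n_par,)).copy()
            ]
        for lam0 in cands:
            if np.any(lam0 <= 0):
                raise ValueError("initial rates must be positive")
        return cands

    def _standard_errors(self, jac, res, jac_scale, pred) -> np.ndarray:
        """SEs from the Gauss-Newton curvature at the estimates.

        ``"classical"`` uses ``sigma2 * diag((J'J)^-1)`` with ``sigma2 =
        RSS / (m - k)`` — the textbook homoscedastic formula.  Gel
        intensities carry multiplicative (heteroscedastic) noise, which
        that formula understates at positions driven by bright bands.
        The default ``"relative"`` therefore models the per-cell variance
        as proportional to the squared prediction (constant relative
        error, the natural model for densitometry) inside a sandwich
        around the same curvature; ``"hc2"``/``"hc3"`` are the standard
        residual-based heteroscedasticity-robust alternatives with no
        noise model at all.  Positions whose curvature is numerically
        singular get NaN with a warning; in log mode every covariance is
        mapped to rate units by the delta method.
        """
        if self.se_method not in ("relative", "hc3", "hc2", "classical"):
            raise ValueError(
                "se_method must be 'relative', 'hc3', 'hc2' or 'classical'"
            )
        m, k = jac.shape
        dof = m - k
        if dof <= 0:
            return np.full(k, np.nan)
        jtj = jac.T @ jac
        diag = np.diag(jtj)
        usable = diag > 1e-12 * max(diag.max(), 1.0)
        se = np.full(k, np.nan)
        if not usable.all():
            warnings.warn(
                "singular curvature: standard errors unavailable for "
                f"{int((~usable).sum())} position(s)",
                stacklevel=2,
            )
        ju = jac[:, usable]
        inv = np.linalg.pinv(ju.T @ ju)
        if self.se_method == "classical":
            sigma2 = float(res @ res) / dof
            var = np.clip(np.diag(inv), 0, None) * sigma2
        else:
            if self.se_method == "relative":
                # relative-error scale estimated from cells with meaningful
                # signal; cells near zero contribute noise, not information
                big = pred > 0.01
                n_big = int(big.sum())
                s2 = float(np.sum((res[big] / pred[big]) ** 2)) / max(n_big - k, 1)
                w = s2 * pred**2
            else:
                leverage = np.clip(np.einsum("ij,jk,ik->i", ju, inv, ju), 0.0, 0.99)
                power = 2 if self.se_method == "hc3" else 1
                w = res**2 / (1.0 - leverage) ** power
            cov = inv @ (ju.T @ (ju * w[:, None])) @ inv
            var = np.clip(np.diag(cov), 0, None)
        se[usable] = np.sqrt(var)
        return se * np.abs(jac_scale)

    # -- post-fit --------------------------------------------------------

    def predict(self, times=None) -> TimeCourseMatrix:
        self._check_fitted()
        if times is None:
            return self.predicted_.copy()
        times = np.asarray(times, dtype=float)
        return TimeCourseMatrix(
            _simulate_normalized(self.rates_, times), times, normalized="assay"
        )

    def rate_profile(self) -> RateProfile:
        self._check_fitted()
        return RateProfile(self.rates_, self.rates_se_)

    def _check_fitted(self) -> None:
        if not hasattr(self, "rates_"):
            raise RuntimeError("model is not fitted")


@dataclass
class FitResult:
    """Plain record of a completed fit (functional-interface return type)."""

    rates: RateProfile
    residual_norm: float
    iterations: int
    converged: bool
    predicted: TimeCourseMatrix
    informative: np.ndarray
    config: dict = field(default_factory=dict)


def estimate_rates(observed: TimeCourseMatrix, **params) -> FitResult:
    """Functional wrapper around :class:`DeadenylationKineticsModel`."""
    model = DeadenylationKineticsModel(**params).fit(observed)
    return FitResult(
        rates=model.rate_profile(),
        residual_norm=model.residual_norm_,
        iterations=model.n_iter_,
        converged=model.converged_,
        predicted=model.predicted_,
        informative=model.informative_,
        config=model.get_params(),
    )


def nonoverlapping_intervals(profile: RateProfile, n_se: float = 1.0) -> np.ndarray:
    """Pairwise matrix marking position pairs with non-overlapping error bars.

    Entry ``[i, j]`` is True when the ``lambda +/- n_se * SE`` intervals of
    positions ``i+1`` and ``j+1`` do not overlap — the paper-style reading
    of a substantial change in kinetics between two positions.
    """
    if profile.se is None:
        raise ValueError("rate profile carries no standard errors")
    lo = profile.rates - n_se * profile.se
    hi = profile.rates + n_se * profile.se
    return (lo[:, None] > hi[None, :]) | (lo[None, :] > hi[:, None])


def holdout_validate(
    observed: TimeCourseMatrix, holdout_times=(), **params
) -> dict:
    """Refit with some time points withheld; report out-of-sample error.

    ``holdout_times`` lists reaction times (minutes) to withhold.  The
    model is fit on the remaining columns; the report gives the RMS and
    maximum absolute prediction error on the withheld cells plus the
    maximum relative rate difference against the full-data fit (over
    positions informative in both fits).
    """
    holdout_times = np.atleast_1d(np.asarray(holdout_times, dtype=float))
    mask = np.isin(observed.times, holdout_times)
    if holdout_times.size and mask.sum() != holdout_times.size:
        missing = sorted(set(holdout_times) - set(observed.times))
        raise ValueError(f"holdout times {missing} not in the observation grid")
    if (~mask).sum() < 2:
        raise ValueError("holdout leaves fewer than two time points to fit")

    full = DeadenylationKineticsModel(**params).fit(observed)
    if not mask.any():
        return {
            "holdout_times": [],
            "rmse_heldout": 0.0,
            "max_abs_error_heldout": 0.0,
            "max_rate_rel_diff": 0.0,
            "rates": full.rate_profile(),
            "excluded_positions": [],
        }

    kept = TimeCourseMatrix(
        observed.values[:, ~mask], observed.times[~mask], observed.normalized
    )
    sub = DeadenylationKineticsModel(**params).fit(kept)

    obs_norm = _unit_scale(observed.values)
    pred = sub.predict(observed.times).values
    err = (obs_norm - pred)[:, mask]

    both = full.informative_ & sub.informative_
    excluded = np.flatnonzero(~both) + 1
    if excluded.size:
        warnings.warn(
            f"positions {excluded.tolist()} lack signal in one of the fits and "
            "are excluded from the rate comparison",
            stacklevel=2,
        )
    rel = np.abs(sub.rates_[both] - full.rates_[both]) / full.rates_[both]
    return {
        "holdout_times": holdout_times.tolist(),
        "rmse_heldout": float(np.sqrt(np.mean(err**2))),
        "max_abs_error_heldout": float(np.max(np.abs(err))),
        "max_rate_rel_diff": float(rel.max()) if rel.size else np.nan,
        "rates": sub.rate_profile(),
        "excluded_positions": excluded.tolist(),
    }
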