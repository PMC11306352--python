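"""Multiexponential fitting of TCSPC fluorescence decay histograms.

Time-correlated single-photon counting yields a histogram of photon
arrival times that is the convolution of the instrument response function
(IRF) with the molecular decay law, here a sum of 1-3 exponentials:

    model(t) = IRF(t) * [ sum_i a_i exp(-t / tau_i) ] + baseline

The fit minimizes the Neyman chi-square, sum_j (c_j - m_j)^2 / max(c_j, 1),
over lifetimes, pre-exponential amplitudes, baseline and a sub-bin IRF
shift.  Amplitudes and baseline enter the model linearly, so they are
solved by non-negative least squares inside the nonlinear search over
(log tau_i, shift) — a variable-projection scheme that is fast and robust
to poor lifetime starting values.

Reported amplitude fractions are pre-exponential (a_i / sum a_i), the
convention under which the amplitude-weighted average lifetime
tau_av = sum a_i tau_i / sum a_i is meaningful for comparing quenched and
unquenched species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, nnls

__all__ = [
    "DecayHistogram",
    "LifetimeFit",
    "FitError",
    "reconvolution_fit",
    "select_n_components",
    "amplitude_weighted_average",
]


class FitError(RuntimeError):
    """Raised when the decay fit fails to converge; carries the best candidate."""

    def __init__(self, message: str, best: "LifetimeFit | None" = None):
        super().__init__(message)
        self.best = best


@dataclass
class DecayHistogram:
    """Binned photon counts with an optional paired IRF histogram.

    ``bin_times`` are bin centers in ns on a uniform grid; ``counts`` are
    non-negative (floats are accepted so that noise-free expectations can be
    carried through the same container).
    """

    bin_times: np.ndarray
    counts: np.ndarray
    irf_counts: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_times = np.asarray(self.bin_times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_times.ndim != 1 or self.bin_times.shape != self.counts.shape:
            raise ValueError("bin_times and counts must be 1-D arrays of equal length")
        if self.bin_times.size < 50:
            raise ValueError(f"need at least 50 bins, got {self.bin_times.size}")
        dt = np.diff(self.bin_times)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12) or dt[0] <= 0:
            raise ValueError("bin_times must be uniformly spaced and increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.irf_counts is not None:
            self.irf_counts = np.asarray(self.irf_counts, dtype=float)
            if self.irf_counts.shape != self.counts.shape:
                raise ValueError("irf_counts must share the decay grid")
            if np.any(self.irf_counts < 0):
                raise ValueError("irf_counts must be non-negative")

    @property
    def bin_width(self) -> float:
        return float(self.bin_times[1] - self.bin_times[0])

    @property
    def n_bins(self) -> int:
        return self.bin_times.size


@dataclass
class LifetimeFit:
    """Fitted exponential decay components.

    ``components`` is a list of (tau_ns, amplitude_fraction) sorted by
    descending lifetime; fractions are pre-exponential and sum to 1.
    """

    components: list
    chi2_reduced: float
    tau_av: float
    n_components: int
    baseline: float = 0.0
    shift: float = 0.0
    tau_se: list = field(default_factory=list)
    flags: tuple = ()

    def __post_init__(self) -> None:
        taus = [c[0] for c in self.components]
        fracs = [c[1] for c in self.components]
        if any(t <= 0 for t in taus):
            raise ValueError("lifetimes must be positive")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("amplitude fractions must sum to 1")
        if not (min(taus) - 1e-12 <= self.tau_av <= max(taus) + 1e-12):
            raise ValueError("tau_av must lie between the component lifetimes")


def amplitude_weighted_average(components) -> float:
    """Amplitude-weighted average lifetime, tau_av = sum(a_i tau_i)/sum(a_i).

    ``components`` is an iterable of (tau, amplitude) pairs; amplitudes need
    not be normalized (relative amplitudes in percent work as-is).
    """
    comps = [(float(t), float(a)) for t, a in components]
    if not comps:
        raise ValueError("empty component list")
    total = sum(a for _, a in comps)
    if total <= 0:
        raise ValueError("amplitudes must have positive sum")
    return sum(a * t for t, a in comps) / total


def _normalized_irf(hist: DecayHistogram, shift: float) -> np.ndarray:
    """IRF kernel shifted by a continuous sub-bin offset (linear interpolation)."""
    t = hist.bin_times
    irf = np.interp(t - shift, t, hist.irf_counts, left=0.0, right=0.0)
    s = irf.sum()
    if s <= 0:
        raise ValueError("IRF histogram is empty after shifting")
    return irf / s


def _design_matrix(hist: DecayHistogram, taus: np.ndarray, shift: float, start: int, fit_baseline: bool) -> np.ndarray:
    """Columns: IRF-convolved unit exponentials (+ constant baseline column)."""
    n = hist.n_bins
    t = hist.bin_times - hist.bin_times[0]
    cols = []
    if hist.irf_counts is not None:
        irf = _normalized_irf(hist, shift)
        for tau in taus:
            e = np.exp(-t / tau)
            cols.append(np.convolve(irf, e)[:n])
    else:
        # tail mode: pure exponentials from the peak bin onward
        t0 = t[start]
        for tau in taus:
            e = np.zeros(n)
            e[start:] = np.exp(-(t[start:] - t0) / tau)
            cols.append(e)
    if fit_baseline:
        cols.append(np.ones(n))
    return np.column_stack(cols)


def _solve_linear(X: np.ndarray, y: np.ndarray, w: np.ndarray, mask: np.ndarray):
    amps, _ = nnls(X[mask] * w[mask, None], y[mask] * w[mask])
    resid = w * (X @ amps - y)
    resid[~mask] = 0.0
    return amps, resid


def _initial_tau_sets(hist: DecayHistogram, n_components: int, n_starts: int) -> list:
    span = hist.bin_times[-1] - hist.bin_times[0]
    lo, hi = np.log10(hist.bin_width), np.log10(span / 3.0)
    base = np.logspace(lo + 0.3 * (hi - lo), hi, n_components) if n_components > 1 else np.array([10 ** ((lo + hi) / 2)])
    sets = [base]
    # fixed multiplicative jitters: deterministic multi-start
    for k in range(1, n_starts):
        factor = 10 ** (0.25 * (-1) ** k * ((k + 1) // 2))
        sets.append(np.clip(base * factor, 10**lo * 0.5, 10**hi))
    return sets


def reconvolution_fit(
    hist: DecayHistogram,
    n_components: int,
    init_taus=None,
    fit_baseline: bool = True,
    fit_shift: bool = True,
    n_starts: int = 4,
) -> LifetimeFit:
    """Fit an n-exponential decay to a TCSPC histogram.

    With ``hist.irf_counts`` present the model is the discrete convolution
    of the (shift-adjusted, sum-normalized) IRF with the multiexponential
    decay; without an IRF a tail fit starting at the peak bin is performed
    and the shift is not fitted.

    Raises :class:`FitError` (carrying the best candidate) if no start
    converges.  A component collapsing below one tenth of the bin width
    triggers an automatic refit with one component fewer, flagged
    ``"collapsed-tau"``.
    """
    if not 1 <= n_components <= 3:
        raise ValueError("n_components must be 1, 2 or 3")
    if hist.counts.max() < 100:
        raise ValueError("peak counts below 100: histogram too sparse to fit")
    y = hist.counts
    w = 1.0 / np.sqrt(np.maximum(y, 1.0))  # Neyman weighting
    tail_mode = hist.irf_counts is None
    start = int(np.argmax(y)) if tail_mode else 0
    mask = np.ones(hist.n_bins, dtype=bool)
    if tail_mode:
        mask[:start] = False
        fit_shift = False
    else:
        # exclude the empty pre-trigger region (it carries no information but
        # would deflate the reduced chi-square through the dof count); keep a
        # margin of bins ahead of the rising edge for the shift fit
        rise = np.nonzero(y >= 0.02 * y.max())[0]
        if rise.size:
            mask[: max(int(rise[0]) - 10, 0)] = False

    bw = hist.bin_width
    span = hist.bin_times[-1] - hist.bin_times[0]

    def residual(params):
        taus = 10 ** params[:n_components]
        shift = params[n_components] if fit_shift else 0.0
        X = _design_matrix(hist, taus, shift, start, fit_baseline)
        _, resid = _solve_linear(X, y, w, mask)
        return resid

    tau_sets = [np.asarray(init_taus, dtype=float)] if init_taus is not None else _initial_tau_sets(hist, n_components, n_starts)
    lb = np.full(n_components, np.log10(bw / 20.0))
    ub = np.full(n_components, np.log10(span))
    if fit_shift:
        lb, ub = np.append(lb, -5 * bw), np.append(ub, 5 * bw)

    best = None
    for taus0 in tau_sets:
        p0 = np.log10(np.sort(taus0))
        if fit_shift:
            p0 = np.append(p0, 0.0)
        try:
            sol = least_squares(residual, np.clip(p0, lb, ub), bounds=(lb, ub), xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("no fit start converged")

    taus = 10 ** best.x[:n_components]
    shift = float(best.x[n_components]) if fit_shift else 0.0
    X = _design_matrix(hist, taus, shift, start, fit_baseline)
    amps, resid = _solve_linear(X, y, w, mask)
    baseline = float(amps[-1]) if fit_baseline else 0.0
    pre_exp = amps[:n_components]

    flags = []
    if np.any(taus < bw / 10.0) and n_components > 1:
        sub = reconvolution_fit(hist, n_components - 1, fit_baseline=fit_baseline, fit_shift=fit_shift, n_starts=n_starts)
        return LifetimeFit(
            sub.components, sub.chi2_reduced, sub.tau_av, sub.n_components,
            sub.baseline, sub.shift, sub.tau_se, sub.flags + ("collapsed-tau",),
        )

    if pre_exp.sum() <= 0:
        raise FitError("all amplitudes collapsed to zero")
    fracs = pre_exp / pre_exp.sum()
    if np.any(fracs < 0.01):
        flags.append("negligible-component")
    st = np.sort(taus)
    if n_components > 1 and np.any(st[1:] / st[:-1] < 1.05):
        flags.append("degenerate-tau")

    n_params = 2 * n_components + int(fit_baseline) + int(fit_shift)
    dof = int(mask.sum()) - n_params
    chi2_red = float(resid @ resid) / max(dof, 1)

    # asymptotic lifetime standard errors from the Jacobian of the
    # projected problem (errors on log10 tau, propagated to tau)
    tau_se = []
    try:
        J = best.jac
        cov = np.linalg.pinv(J.T @ J) * chi2_red
        log_se = np.sqrt(np.maximum(np.diag(cov)[:n_components], 0.0))
        tau_se = list(taus * np.log(10) * log_se)
    except Exception:
        tau_se = [float("nan")] * n_components

    order = np.argsort(taus)[::-1]
    comps = [(float(taus[i]), float(fracs[i])) for i in order]
    tau_se = [tau_se[i] for i in order]
    tau_av = amplitude_weighted_average(comps)
    return LifetimeFit(comps, chi2_red, tau_av, n_components, baseline, shift, tau_se, tuple(flags))


def select_n_components(
    hist: DecayHistogram,
    max_components: int = 3,
    chi2_improvement_threshold: float = 0.10,
    **fit_kwargs,
) -> LifetimeFit:
    """Pick the smallest component count justified by the fit quality.

    Starting from one component, an additional component is accepted only
    while it improves the reduced chi-square by at least
    ``chi2_improvement_threshold`` (relative).  Ties favor fewer components;
    an infinite threshold always returns the mono-exponential fit.
    """
    current = reconvolution_fit(hist, 1, **fit_kwargs)
    for n in range(2, max_components + 1):
        try:
            candidate = reconvolution_fit(hist, n, **fit_kwargs)
        except FitError:
            break
        improvement = (current.chi2_reduced - candidate.chi2_reduced) / current.chi2_reduced
        if not improvement >= chi2_improvement_threshold:
            break
        current = candidate
    return current


def check_truncation(hist: DecayHistogram, max_tau: float) -> None:
    """Warn when the record is too short for the slowest component."""
    span = hist.bin_times[-1] - hist.bin_times[0]
    if span < 5.0 * max_tau:
        warnings.warn(
            f"record length {span:.2f} ns < 5 x max lifetime {max_tau:.2f} ns: truncation bias likely"
        )
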