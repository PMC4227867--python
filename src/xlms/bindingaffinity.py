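"""1:1 binding-kinetics simulation and fitting.

SPR single-cycle kinetics: increasing analyte concentrations are injected
sequentially without regeneration; the response follows the Langmuir 1:1
model ``dR/dt = ka*C(t)*(Rmax - R) - kd*R``, which has closed-form
exponential solutions on every piecewise-constant concentration segment.
The equilibrium dissociation constant is always reported as
``Kd = kd / ka``.  ELISA-style saturation binding is fitted with the
hyperbola ``R = Bmax * C / (Kd + C)``.

Mass-transport limitation, baseline drift and bulk refractive-index jumps
are not modeled; instrument artifact windows can be excluded from the fit,
and double referencing is represented as subtraction of a blank
sensorgram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize


class FitError(RuntimeError):
    """Fit did not converge or the input is degenerate; carries diagnostics."""


@dataclass(frozen=True)
class KineticParams:
    """1:1 model parameters: ka in 1/(M s), kd in 1/s, rmax in response
    units.  ``Kd`` (M) is derived as ``kd / ka`` exactly."""

    ka: float
    kd: float
    rmax: float
    ka_stderr: float = 0.0
    kd_stderr: float = 0.0
    rmax_stderr: float = 0.0

    def __post_init__(self):
        if self.ka <= 0 or self.kd <= 0 or self.rmax <= 0:
            raise ValueError("ka, kd and rmax must all be > 0")

    @property
    def Kd(self) -> float:
        return self.kd / self.ka


@dataclass(frozen=True)
class InjectionSchedule:
    """Ordered (concentration M, start s, duration s) injections with
    dissociation gaps in between; concentrations strictly increase."""

    injections: tuple

    def __post_init__(self):
        prev_end = -np.inf
        prev_conc = 0.0
        for conc, start, dur in self.injections:
            if conc <= prev_conc:
                raise ValueError("concentrations must be strictly increasing")
            if start < prev_end:
                raise ValueError("injection intervals must not overlap")
            if dur <= 0:
                raise ValueError("injection duration must be > 0")
            prev_conc, prev_end = conc, start + dur

    def concentration_at(self, t: float) -> float:
        for conc, start, dur in self.injections:
            if start <= t < start + dur:
                return conc
        return 0.0

    def segments(self, t_end: float) -> list[tuple[float, float, float]]:
        """(start, end, concentration) pieces covering [0, t_end]."""
        edges = {0.0, t_end}
        for conc, start, dur in self.injections:
            edges.update((start, start + dur))
        edges = sorted(e for e in edges if 0.0 <= e <= t_end)
        segs = []
        for a, b in zip(edges, edges[1:]):
            if b > a:
                segs.append((a, b, self.concentration_at(0.5 * (a + b))))
        return segs


def single_cycle_schedule(
    concentrations=(6.25e-9, 12.5e-9, 25e-9, 50e-9, 100e-9),
    injection_s: float = 60.0,
    dissociation_s: float = 2436.0,
) -> InjectionSchedule:
    """Default single-cycle layout: 1-min injections of a doubling
    concentration series (6.25-100 nM), each followed by a 40.6-min
    dissociation gap."""
    inj = []
    t = 0.0
    for c in concentrations:
        inj.append((c, t, injection_s))
        t += injection_s + dissociation_s
    return InjectionSchedule(tuple(inj))


def response_curve(p: KineticParams, sched: InjectionSchedule, times: np.ndarray) -> np.ndarray:
    """Noiseless 1:1 response at ``times`` (sorted), piecewise closed form.

    On a segment of constant concentration C:
    ``R(t) = Req + (R0 - Req) * exp(-(ka*C + kd) * (t - t0))`` with
    ``Req = ka*C*Rmax / (ka*C + kd)`` (pure ``exp(-kd t)`` decay when
    C = 0).
    """
    times = np.asarray(times, dtype=float)
    out = np.empty_like(times)
    r0 = 0.0
    idx = 0
    for a, b, conc in sched.segments(float(times[-1]) + 1e-9):
        kobs = p.ka * conc + p.kd
        req = p.ka * conc * p.rmax / kobs if conc > 0 else 0.0
        while idx < len(times) and times[idx] <= b + 1e-12:
            t = times[idx]
            if t < a - 1e-12:
                out[idx] = r0
                idx += 1
                continue
            out[idx] = req + (r0 - req) * np.exp(-kobs * (t - a))
            idx += 1
        r0 = req + (r0 - req) * np.exp(-kobs * (b - a))
    while idx < len(times):
        out[idx] = r0
        idx += 1
    return out


def simulate_sck(
    p: KineticParams,
    sched: InjectionSchedule,
    times: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
    blank: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate a single-cycle sensorgram with Gaussian noise.

    ``blank`` (e.g. a buffer cycle) is added so that double referencing,
    i.e. subtracting it again, can be exercised downstream.
    """
    r = response_curve(p, sched, times)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        r = r + rng.normal(0.0, noise_sd, size=r.shape)
    if blank is not None:
        r = r + np.asarray(blank, dtype=float)
    return r


def double_reference(response: np.ndarray, blank: np.ndarray) -> np.ndarray:
    """Subtract a blank-cycle sensorgram from the measured response."""
    return np.asarray(response, dtype=float) - np.asarray(blank, dtype=float)


def fit_sck(
    times: np.ndarray,
    response: np.ndarray,
    sched: InjectionSchedule,
    p0: KineticParams | None = None,
    exclude_windows: list[tuple[float, float]] | None = None,
) -> KineticParams:
    """Least-squares fit of the 1:1 model to a single-cycle sensorgram.

    Parameters are fitted on a log scale to enforce positivity.
    ``exclude_windows`` removes time intervals (instrument artifacts)
    from the residuals.  Raises :class:`FitError` with diagnostics on
    degenerate input or non-convergence.
    """
    times = np.asarray(times, dtype=float)
    response = np.asarray(response, dtype=float)
    if len(sched.injections) < 2:
        raise FitError("single-cycle fitting needs >= 2 injection levels")
    keep = np.ones(len(times), dtype=bool)
    for a, b in exclude_windows or []:
        keep &= ~((times >= a) & (times <= b))
    t_fit, r_fit = times[keep], response[keep]
    scale = float(np.max(np.abs(r_fit))) if len(r_fit) else 0.0
    if scale <= 0 or not np.isfinite(scale):
        raise FitError("flat or invalid response: nothing to fit")
    if p0 is None:
        mid_c = sched.injections[len(sched.injections) // 2][0]
        # half-saturation at the mid concentration, minute-scale dissociation
        p0 = KineticParams(ka=1e-3 / mid_c, kd=1e-3, rmax=1.5 * scale)

    def residuals(logp):
        ka, kd, rmax = np.exp(logp)
        try:
            model = response_curve(KineticParams(ka, kd, rmax), sched, t_fit)
        except (OverflowError, FloatingPointError):
            return np.full_like(r_fit, 1e6)
        return model - r_fit

    x0 = np.log([p0.ka, p0.kd, p0.rmax])
    res = optimize.least_squares(residuals, x0, method="lm", max_nfev=20000)
    if not res.success:
        raise FitError(f"1:1 fit did not converge: {res.message} (cost {res.cost:.3g})")
    ka, kd, rmax = np.exp(res.x)
    # stderr from the Jacobian in log space, propagated to linear scale
    dof = max(len(r_fit) - 3, 1)
    s2 = 2 * res.cost / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        log_err = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        log_err = np.zeros(3)
    return KineticParams(
        ka, kd, rmax,
        ka_stderr=ka * log_err[0], kd_stderr=kd * log_err[1], rmax_stderr=rmax * log_err[2],
    )


@dataclass(frozen=True)
class SaturationCurve:
    """Equilibrium binding responses at increasing ligand concentrations."""

    concentrations: np.ndarray  # M
    responses: np.ndarray
    replicates: int = 1

    def __post_init__(self):
        object.__setattr__(self, "concentrations", np.asarray(self.concentrations, float))
        object.__setattr__(self, "responses", np.asarray(self.responses, float))
        if len(self.concentrations) != len(self.responses):
            raise ValueError("concentration/response length mismatch")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")


@dataclass(frozen=True)
class SaturationFit:
    Kd: float
    bmax: float
    Kd_stderr: float
    bmax_stderr: float
    reliable: bool  # False when the curve never reaches the Kd estimate


def saturation_response(conc, bmax: float, Kd: float):
    """Hyperbolic 1:1 saturation: ``R = Bmax * C / (Kd + C)``."""
    conc = np.asarray(conc, dtype=float)
    return bmax * conc / (Kd + conc)


def fit_saturation(curve: SaturationCurve) -> SaturationFit:
    """Non-linear least-squares fit of the saturation hyperbola.

    Needs >= 4 distinct concentrations.  The result is flagged
    unreliable when the highest tested concentration is below the fitted
    Kd (no saturation reached).
    """
    if len(np.unique(curve.concentrations)) < 4:
        raise FitError("saturation fitting needs >= 4 distinct concentrations")
    c, r = curve.concentrations, curve.responses
    p0 = (max(r.max(), 1e-12), max(np.median(c), 1e-12))
    try:
        popt, pcov = optimize.curve_fit(saturation_response, c, r, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"saturation fit did not converge: {exc}") from exc
    bmax, kd = popt
    if bmax <= 0 or kd <= 0:
        raise FitError(f"non-physical saturation fit (Bmax={bmax:.3g}, Kd={kd:.3g})")
    err = np.sqrt(np.clip(np.diag(pcov), 0, None))
    return SaturationFit(
        Kd=float(kd), bmax=float(bmax),
        Kd_stderr=float(err[1]), bmax_stderr=float(err[0]),
        reliable=bool(c.max() >= kd),
    )


def inverse_variance_mean(values, stderrs) -> tuple[float, float]:
    """Inverse-variance weighted mean of replicate estimates.

    Provided for combining repeated kinetic measurements; the weighting
    scheme is a package choice, flagged as such, since instrument software
    implementations differ.
    """
    values = np.asarray(values, float)
    w = 1.0 / np.asarray(stderrs, float) ** 2
    mean = float((w * values).sum() / w.sum())
    return mean, float(np.sqrt(1.0 / w.sum()))
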