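"""Pore dissolution detection and Arrhenius lifetime extrapolation.

Pore stability is monitored as the backbone RMSD of the assembly against
its initial structure; dissolution shows as a sustained rise of that RMSD
above an equilibrated baseline (about 3.5 Å).  Unfolding times measured at
a ladder of elevated temperatures follow Arrhenius kinetics,

    tau(T) = A * exp(Ea / (R*T)),

linear in ln tau vs 1/T, which permits extrapolation of mean pore
lifetimes down to physiological temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import R_KCAL
from .permclust import kabsch_rmsd


@dataclass
class RmsdSeries:
    """Backbone RMSD to the initial pore structure, per frame."""

    times: np.ndarray    # ps
    rmsd: np.ndarray     # Å

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rmsd = np.asarray(self.rmsd, dtype=float)
        if len(self.times) != len(self.rmsd):
            raise ValueError("times and rmsd must align")
        if np.any(self.rmsd < 0):
            raise ValueError("rmsd must be non-negative")


def pore_rmsd_series(
    coords_per_frame, reference: np.ndarray, times=None
) -> RmsdSeries:
    """Superpose each frame's pore backbone on the reference and record RMSD.

    The same physical pore is tracked, so the peptide correspondence is the
    identity — no permutation search.
    """
    ref = np.asarray(reference, dtype=float).reshape(-1, 3)
    rmsds = []
    for coords in coords_per_frame:
        c = np.asarray(coords, dtype=float).reshape(-1, 3)
        if c.shape != ref.shape:
            raise ValueError(f"frame layout {c.shape} != reference {ref.shape}")
        r, _, _ = kabsch_rmsd(ref, c)
        rmsds.append(r)
    if times is None:
        times = np.arange(len(rmsds), dtype=float)
    return RmsdSeries(times=np.asarray(times, float), rmsd=np.array(rmsds))


@dataclass
class UnfoldingResult:
    """First sustained RMSD excursion above threshold, or censoring."""

    tau: float | None            # ps, None when censored
    censored: bool
    run_length: float            # ps, trajectory span examined

    @property
    def observed(self) -> bool:
        return not self.censored


def unfolding_time(
    series: RmsdSeries,
    threshold: float = 6.0,
    window: int = 50,
    baseline: float = 3.5,
) -> UnfoldingResult:
    """Time of pore dissolution from an RMSD series.

    tau is the first time the RMSD exceeds ``threshold`` and stays above it
    for at least ``window`` consecutive frames; a single-frame spike does
    not count.  If the threshold is never sustainedly exceeded the sample
    is censored at the run length.
    """
    if threshold <= baseline:
        raise ValueError("threshold must exceed the equilibrated baseline")
    if window < 1:
        raise ValueError("persistence window must be >= 1 frame")
    r = series.rmsd
    if len(r) == 0:
        raise ValueError("empty RMSD series")
    above = r > threshold
    run = 0
    start = None
    for i, a in enumerate(above):
        if a:
            if start is None:
                start = i
            run += 1
            if run >= window:
                return UnfoldingResult(
                    tau=float(series.times[start]), censored=False,
                    run_length=float(series.times[-1] - series.times[0]),
                )
        else:
            run = 0
            start = None
    # terminal runs shorter than the window do not satisfy persistence
    return UnfoldingResult(
        tau=None, censored=True,
        run_length=float(series.times[-1] - series.times[0]) if len(r) > 1 else 0.0,
    )


@dataclass
class LifetimeSample:
    """One unfolding measurement at one temperature."""

    temperature: float           # K
    replicate: int
    tau: float | None            # ps
    censored: bool = False

    def __post_init__(self) -> None:
        if not self.censored and (self.tau is None or self.tau <= 0):
            raise ValueError("uncensored samples need a positive tau")


@dataclass
class ArrheniusFit:
    """Weighted linear fit of ln<tau> against 1/(R*T)."""

    ea: float                    # activation energy, kcal/mol
    ln_a: float                  # ln prefactor, A in ps
    covariance: np.ndarray       # 2x2 for (ln_a, ea)
    temperatures: np.ndarray     # K, fitted points
    mean_tau: np.ndarray         # ps per temperature
    sem_tau: np.ndarray          # ps per temperature
    n_points: int
    n_censored: int = 0

    def predict_ln_tau(self, temperature: float) -> float:
        return self.ln_a + self.ea / (R_KCAL * temperature)


def arrhenius_fit(samples: list[LifetimeSample]) -> ArrheniusFit:
    """Fit Arrhenius parameters to lifetime replicates.

    Replicates are averaged per temperature first (each fitted point is the
    mean of its replicates); censored replicates are excluded with a
    logged count.  The line ln<tau> = ln A + Ea/(R*T) is fitted by least
    squares weighted by the replicate count per temperature, with the
    parameter covariance scaled by the residual variance.
    """
    import logging

    by_t: dict[float, list[float]] = {}
    n_censored = 0
    for s in samples:
        if s.censored:
            n_censored += 1
            continue
        by_t.setdefault(s.temperature, []).append(s.tau)
    if len(by_t) < 2:
        raise ValueError("Arrhenius fit needs uncensored samples at >= 2 temperatures")
    if n_censored:
        logging.getLogger("poreform").info(
            "arrhenius_fit: excluded %d censored replicates", n_censored
        )
    temps = np.array(sorted(by_t))
    means = np.array([np.mean(by_t[t]) for t in temps])
    sems = np.array([
        np.std(by_t[t], ddof=1) / np.sqrt(len(by_t[t])) if len(by_t[t]) > 1 else np.nan
        for t in temps
    ])
    reps = np.array([len(by_t[t]) for t in temps], dtype=float)
    x = 1.0 / (R_KCAL * temps)
    y = np.log(means)
    design = np.stack([np.ones_like(x), x], axis=1)
    k = len(temps)
    w = reps / reps.mean()          # normalised to mean 1; equal reps -> OLS
    wd = design * w[:, None]
    normal = design.T @ wd
    beta = np.linalg.solve(normal, wd.T @ y)
    resid = y - design @ beta
    if k > 2:
        s2 = float((w * resid**2).sum() / (k - 2))
        cov = s2 * np.linalg.inv(normal)
    else:
        cov = np.zeros((2, 2))
    return ArrheniusFit(
        ea=float(beta[1]), ln_a=float(beta[0]), covariance=cov,
        temperatures=temps, mean_tau=means, sem_tau=sems,
        n_points=int(k), n_censored=n_censored,
    )


@dataclass
class LifetimeEstimate:
    """Extrapolated mean lifetime with a multiplicative confidence interval."""

    temperature: float
    tau: float                   # ps
    ci_lower: float
    ci_upper: float
    level: float


def extrapolate_lifetime(
    fit: ArrheniusFit, temperature: float, level: float = 0.95
) -> LifetimeEstimate:
    """Mean pore lifetime at an arbitrary temperature from the fit.

    The confidence interval is propagated from the linear-fit covariance
    through the exponential (delta method on ln tau), i.e. it is
    multiplicative; Student-t quantiles with (#temperatures - 2) degrees of
    freedom are used when available.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    x = 1.0 / (R_KCAL * temperature)
    ln_tau = fit.ln_a + fit.ea * x
    v = np.array([1.0, x])
    var = float(v @ fit.covariance @ v)
    df = fit.n_points - 2
    if df > 0 and var > 0:
        q = stats.t.ppf(0.5 + level / 2.0, df)
        half = q * np.sqrt(var)
    else:
        half = 0.0
    tau = float(np.exp(ln_tau))
    return LifetimeEstimate(
        temperature=temperature, tau=tau,
        ci_lower=float(np.exp(ln_tau - half)), ci_upper=float(np.exp(ln_tau + half)),
        level=level,
    )


def ea_confidence_interval(fit: ArrheniusFit, level: float = 0.95) -> tuple[float, float]:
    """Student-t confidence interval for the activation energy."""
    df = fit.n_points - 2
    se = float(np.sqrt(fit.covariance[1, 1]))
    if df <= 0 or se == 0:
        return fit.ea, fit.ea
    q = stats.t.ppf(0.5 + level / 2.0, df)
    return fit.ea - q * se, fit.ea + q * se
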