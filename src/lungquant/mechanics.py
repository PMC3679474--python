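"""Respiratory mechanics model fitting.

Three readouts from the forced-oscillation/ventilator workflow:

* single-compartment equation of motion P = R*V' + V/C + P0, fitted by
  ordinary least squares to a fixed-frequency oscillation record
  (resistance R, compliance C);
* constant-phase input impedance Z(f) = Rn + j*2*pi*f*Iaw
  + (G - j*H) / (2*pi*f)**alpha with alpha = (2/pi)*arctan(H/G), fitted by
  bounded nonlinear least squares (airway resistance Rn, airway inertance
  Iaw, tissue damping G, tissue elastance H);
* quasi-static pressure-volume loop metrics via the Salazar-Knowles
  exponential V(P) = A - B*exp(-K*P) on the deflation limb: static
  compliance Cst (slope at a reference pressure), total lung capacity TLC
  (fitted volume at maximal pressure), and hysteresis (loop area).

All fitters are deterministic: fixed multistart points, no RNG.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize


class MechanicsError(Exception):
    """Base class for mechanics-fitting failures."""


class SingularFitError(MechanicsError):
    """Raised when the regression design is rank deficient."""


class FitConvergenceError(MechanicsError):
    """Raised when a nonlinear fit fails to converge."""


# ---------------------------------------------------------------------------
# Forward models (shared with the synthetic-data generator)
# ---------------------------------------------------------------------------

def constant_phase_alpha(G: float, H: float) -> float:
    """alpha = (2/pi) * arctan(H/G); equals 0.5 when G == H."""
    return (2.0 / np.pi) * np.arctan2(H, G)


def constant_phase_impedance(
    freqs: np.ndarray, Rn: float, Iaw: float, G: float, H: float
) -> np.ndarray:
    """Constant-phase model impedance (cmH2O.s/mL) at frequencies in Hz."""
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be strictly positive")
    w = 2.0 * np.pi * freqs
    alpha = constant_phase_alpha(G, H)
    return Rn + 1j * w * Iaw + (G - 1j * H) / w**alpha


def salazar_knowles_volume(P: np.ndarray, A: float, B: float, K: float) -> np.ndarray:
    """Deflation-limb volume V(P) = A - B*exp(-K*P)."""
    return A - B * np.exp(-K * np.asarray(P, dtype=float))


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PerturbationRecord:
    """One fixed-frequency oscillation record (time series at the trachea)."""

    time: np.ndarray  # s, strictly increasing
    pressure: np.ndarray  # cmH2O
    flow: np.ndarray  # mL/s
    volume: np.ndarray  # mL
    peep: float = 3.0  # cmH2O

    def __post_init__(self) -> None:
        n = len(self.time)
        if n < 3:
            raise ValueError("record needs at least 3 samples")
        if not (len(self.pressure) == len(self.flow) == len(self.volume) == n):
            raise ValueError("time, pressure, flow, volume must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass(frozen=True)
class ImpedanceSpectrum:
    freqs: np.ndarray  # Hz, strictly increasing, > 0
    Z: np.ndarray  # complex, cmH2O.s/mL

    def __post_init__(self) -> None:
        if len(self.freqs) != len(self.Z):
            raise ValueError("freqs and Z must have equal length")
        if np.any(np.asarray(self.freqs) <= 0):
            raise ValueError("frequencies must be strictly positive")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequencies must be strictly increasing")


@dataclass(frozen=True)
class PVLoop:
    """Closed quasi-static PV loop: both limbs on a shared ascending grid."""

    pressure: np.ndarray  # cmH2O, ascending
    volume_inflation: np.ndarray  # mL
    volume_deflation: np.ndarray  # mL

    def __post_init__(self) -> None:
        n = len(self.pressure)
        if len(self.volume_inflation) != n or len(self.volume_deflation) != n:
            raise ValueError("limb arrays must match the pressure grid")
        if np.any(np.diff(self.pressure) <= 0):
            raise ValueError("pressure grid must be strictly ascending")

    def closed_polygon(self) -> np.ndarray:
        """(P, V) vertices tracing inflation up then deflation down."""
        P = np.concatenate([self.pressure, self.pressure[::-1]])
        V = np.concatenate([self.volume_inflation, self.volume_deflation[::-1]])
        return np.column_stack([P, V])


@dataclass(frozen=True)
class SingleCompartmentFit:
    R: float  # cmH2O.s/mL
    C: float  # mL/cmH2O
    P0: float  # cmH2O
    rss: float


@dataclass(frozen=True)
class ConstantPhaseFit:
    Rn: float
    Iaw: float
    G: float
    H: float
    alpha: float
    rss: float
    converged: bool


@dataclass(frozen=True)
class PVMetrics:
    Cst: float  # mL/cmH2O, d(V)/d(P) of the fitted deflation limb at P_ref
    TLC: float  # mL, fitted deflation volume at P_max
    area: float  # mL.cmH2O, absolute shoelace area of the closed loop
    A: float
    B: float
    K: float
    model: str  # "exponential" or "linear"
    rss: float


# ---------------------------------------------------------------------------
# Fitters
# ---------------------------------------------------------------------------

def fit_single_compartment(rec: PerturbationRecord) -> SingleCompartmentFit:
    """OLS fit of P(t) = R*flow(t) + (1/C)*volume(t) + P0.

    Closed-form linear solve over all samples.  A rank-deficient design
    (e.g. constant flow and volume) raises :class:`SingularFitError`.
    """
    X = np.column_stack([rec.flow, rec.volume, np.ones_like(rec.volume)])
    # Rank of the centred design decides identifiability of R and 1/C.
    if np.linalg.matrix_rank(X) < 3:
        raise SingularFitError("design is rank deficient: R and C not identifiable")
    beta, res, rank, _ = np.linalg.lstsq(X, rec.pressure, rcond=None)
    fitted = X @ beta
    rss = float(((rec.pressure - fitted) ** 2).sum())
    elastance = beta[1]
    if elastance == 0:
        raise SingularFitError("zero elastance: compliance undefined")
    return SingleCompartmentFit(R=float(beta[0]), C=float(1.0 / elastance),
                                P0=float(beta[2]), rss=rss)


#: Fixed multistart points (Rn, Iaw, G, H) spanning mouse-plausible scales.
_CP_STARTS: tuple[tuple[float, float, float, float], ...] = (
    (0.2, 0.001, 3.0, 15.0),
    (0.5, 0.01, 8.0, 40.0),
    (0.05, 1e-4, 1.0, 5.0),
)


def fit_constant_phase(spec: ImpedanceSpectrum) -> ConstantPhaseFit:
    """Fit the constant-phase model to a complex impedance spectrum.

    Minimises the summed squared modulus of the complex residual with
    alpha tied to (2/pi)*arctan(H/G).  Bounds keep Rn >= 0 and G, H > 0;
    three fixed starting points make the fit deterministic, and the best
    (lowest residual) solution is returned.
    """
    if len(spec.freqs) < 4:
        raise ValueError("need at least 4 frequencies for 4 free parameters")
    f = np.asarray(spec.freqs, dtype=float)
    Z = np.asarray(spec.Z, dtype=complex)

    def residuals(x: np.ndarray) -> np.ndarray:
        model = constant_phase_impedance(f, *x)
        d = Z - model
        return np.concatenate([d.real, d.imag])

    lb = [0.0, -np.inf, 1e-9, 1e-9]
    ub = [np.inf, np.inf, np.inf, np.inf]
    best = None
    any_converged = False
    for x0 in _CP_STARTS:
        try:
            sol = optimize.least_squares(
                residuals, x0, bounds=(lb, ub), method="trf",
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000,
            )
        except Exception:  # a bad start must not kill the multistart
            continue
        any_converged = any_converged or sol.status > 0
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitConvergenceError("constant-phase fit failed from every start")
    Rn, Iaw, G, H = best.x
    return ConstantPhaseFit(
        Rn=float(Rn), Iaw=float(Iaw), G=float(G), H=float(H),
        alpha=constant_phase_alpha(G, H),
        rss=float(2 * best.cost),  # least_squares cost is 0.5*sum(res^2)
        converged=bool(any_converged),
    )


def _shoelace_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)))


def pv_metrics(
    loop: PVLoop, cst_pressure: float = 5.0, tlc_pressure: float | None = None
) -> PVMetrics:
    """Salazar-Knowles metrics from a PV loop.

    The deflation limb is fitted to V = A - B*exp(-K*P); then
    Cst = B*K*exp(-K*P_ref) at ``cst_pressure`` (default 5 cmH2O) and
    TLC is the fitted volume at ``tlc_pressure`` (default: the loop's
    maximal recorded pressure).  Hysteresis is the absolute shoelace area
    of the closed loop polygon.  A loop that is better described by a
    straight line (the K -> 0 limit) falls back to a linear fit, for which
    Cst is the slope.
    """
    P = np.asarray(loop.pressure, dtype=float)
    V = np.asarray(loop.volume_deflation, dtype=float)
    if len(P) < 4:
        raise ValueError("need at least 4 deflation points")
    p_max = float(P.max()) if tlc_pressure is None else float(tlc_pressure)

    # Linear candidate (K -> 0 limit): V = a + c*P.
    lin = np.polynomial.polynomial.polyfit(P, V, 1)
    lin_rss = float(((V - (lin[0] + lin[1] * P)) ** 2).sum())

    exp_fit = None
    try:
        b0 = max(V.max() - V.min(), 1e-9)
        sol = optimize.least_squares(
            lambda x: V - salazar_knowles_volume(P, *x),
            x0=[float(V.max()) + 0.1 * b0, b0, 0.1],
            bounds=([-np.inf, 1e-12, 1e-12], [np.inf, np.inf, np.inf]),
            method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=5000,
        )
        if sol.status > 0:
            exp_fit = sol
    except Exception:
        exp_fit = None

    area = _shoelace_area(loop.closed_polygon())

    if exp_fit is not None and 2 * exp_fit.cost < lin_rss:
        A, B, K = (float(v) for v in exp_fit.x)
        cst = B * K * np.exp(-K * cst_pressure)
        tlc = A - B * np.exp(-K * p_max)
        return PVMetrics(Cst=float(cst), TLC=float(tlc), area=area,
                         A=A, B=B, K=K, model="exponential",
                         rss=float(2 * exp_fit.cost))
    # K -> 0 fallback: slope is the compliance everywhere.
    a, c = float(lin[0]), float(lin[1])
    return PVMetrics(Cst=c, TLC=a + c * p_max, area=area,
                     A=a, B=0.0, K=0.0, model="linear", rss=lin_rss)
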