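"""Survival-curve prediction and transition-probability calibration.

The three-state chain implies closed-form curves: PFS(t) is the
probability of never having left the initial state, ``p_pfs_pfs ** t``,
and OS(t) is one minus the death occupancy of the cohort trace. The
calibrator inverts this map: given tabulated OS and PFS curves on an
integer-month grid it finds the monthly transition probabilities whose
predicted curves minimise the summed squared error

    SSE = sum_t [OS(t) - OS_hat(t)]^2 + sum_t [PFS(t) - PFS_hat(t)]^2

over the three free parameters: the PFS stay probability, the split of
PFS exits between progression and death, and the PD stay probability.
The simplex constraints hold by construction (logit parameterisation).

The procedure is deterministic: a closed-form initialiser for the PFS
stay probability (log-linear fit, exp of the mean per-month log drop), a
fixed coarse grid (step 0.05 in each free parameter), then derivative-free
local refinement (Nelder-Mead) with an SSE tolerance of 1e-10 and at most
10,000 evaluations, ties broken by lowest SSE then lexicographic
parameter order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model import build_trace
from .params import ModelConfig, TransitionMatrix, ValidationError

__all__ = [
    "SurvivalCurve", "CalibrationResult", "TransitionCalibrator",
    "predict_curves", "calibrate_transitions", "read_curve", "write_curve",
    "interpolate_monthly", "CalibrationError",
]


class CalibrationError(RuntimeError):
    """The optimiser failed to produce a usable fit."""


@dataclass(frozen=True)
class SurvivalCurve:
    """An OS or PFS curve: survival fractions on an integer-month grid."""

    kind: str                 # "OS" or "PFS"
    months: np.ndarray        # integer months, ascending, starting at 0
    survival: np.ndarray      # fractions in [0, 1], non-increasing, S(0)=1

    def __post_init__(self) -> None:
        if self.kind not in ("OS", "PFS"):
            raise ValidationError(f"kind must be 'OS' or 'PFS', got {self.kind!r}")
        m = np.asarray(self.months, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        if m.shape != s.shape or m.ndim != 1 or m.size < 1:
            raise ValidationError("months and survival must be equal-length 1-d arrays")
        if np.any(np.diff(m) <= 0) or m[0] != 0:
            raise ValidationError("months must be strictly increasing and start at 0")
        if not np.isclose(s[0], 1.0, atol=1e-9):
            raise ValidationError(f"survival at month 0 must be 1, got {s[0]}")
        if np.any(s < -1e-12) or np.any(s > 1 + 1e-12):
            raise ValidationError("survival values must lie in [0, 1]")
        if np.any(np.diff(s) > 1e-9):
            raise ValidationError(f"{self.kind} curve must be non-increasing in month")
        object.__setattr__(self, "months", m.astype(int))
        object.__setattr__(self, "survival", s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"month": self.months, "survival": self.survival})


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted matrix with per-endpoint squared errors and diagnostics."""

    matrix: TransitionMatrix
    sse_os: float
    sse_pfs: float
    converged: bool
    message: str = ""
    n_evaluations: int = 0

    @property
    def sse(self) -> float:
        return self.sse_os + self.sse_pfs


def predict_curves(matrix: TransitionMatrix, horizon: int) -> tuple[SurvivalCurve, SurvivalCurve]:
    """Model-implied (OS, PFS) curves at months 0..horizon."""
    months = np.arange(horizon + 1)
    pfs = matrix.p_pfs_pfs ** months
    config = ModelConfig(horizon=horizon)
    trace = build_trace(matrix, config)
    os_ = 1.0 - trace.occupancy[:, 2]
    return (SurvivalCurve("OS", months, os_), SurvivalCurve("PFS", months, pfs))


def _predicted(a: float, w: float, b: float, months: np.ndarray):
    """PFS and OS at the given integer months for parameters
    (a = PFS stay, w = share of PFS exits that progress, b = PD stay)."""
    T = int(months.max())
    pfs_path = a ** np.arange(T + 1)
    pd_occ = np.zeros(T + 1)
    for t in range(T):
        pd_occ[t + 1] = pd_occ[t] * b + pfs_path[t] * (1.0 - a) * w
    os_path = pfs_path + pd_occ
    return pfs_path[months], os_path[months]


def _sse(params, os_curve, pfs_curve):
    a, w, b = params
    pfs_hat, os_hat = _predicted(a, w, b, os_curve.months)
    return (float(np.sum((pfs_curve.survival - pfs_hat) ** 2)),
            float(np.sum((os_curve.survival - os_hat) ** 2)))


def _logit(p):
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(p / (1 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


class TransitionCalibrator:
    """Fits monthly transition probabilities to OS/PFS curves.

    Parameters
    ----------
    os_curve, pfs_curve
        :class:`SurvivalCurve` pairs on a common integer-month grid with at
        least 3 points beyond month 0. Curves tabulated at non-integer
        times must be pre-interpolated (see :func:`interpolate_monthly`).
    """

    #: coarse-grid step in each free parameter
    GRID_STEP = 0.05
    SSE_TOL = 1e-10
    MAX_EVALS = 10_000

    def __init__(self, os_curve: SurvivalCurve, pfs_curve: SurvivalCurve):
        if os_curve.kind != "OS" or pfs_curve.kind != "PFS":
            raise ValidationError("pass (OS, PFS) curves with matching kinds")
        if not np.array_equal(os_curve.months, pfs_curve.months):
            raise ValidationError("OS and PFS curves must share one monthly grid")
        if np.sum(os_curve.months > 0) < 3:
            raise ValidationError("need at least 3 points beyond month 0")
        if np.any(os_curve.survival + 1e-9 < pfs_curve.survival):
            raise ValidationError("OS must dominate PFS at every month")
        self.os_curve = os_curve
        self.pfs_curve = pfs_curve
        self._n_eval = 0
        #: best-so-far SSE after each objective evaluation (monotone non-increasing)
        self.descent_path: list[float] = []

    # -- objective ---------------------------------------------------------
    def _objective(self, z):
        a, w, b = _expit(z)
        s_pfs, s_os = _sse((a, w, b), self.os_curve, self.pfs_curve)
        val = s_pfs + s_os
        self._n_eval += 1
        best = min(val, self.descent_path[-1]) if self.descent_path else val
        self.descent_path.append(best)
        return val

    def _init_pfs_stay(self) -> float:
        """Closed-form initialiser: exp of the mean per-month log PFS drop."""
        s = self.pfs_curve.survival
        pos = s > 0
        ratios = s[1:][pos[1:] & pos[:-1]] / s[:-1][pos[1:] & pos[:-1]]
        if ratios.size == 0:
            return 0.5
        return float(np.exp(np.mean(np.log(ratios))))

    def fit(self) -> CalibrationResult:
        pfs_s = self.pfs_curve.survival
        if np.all(pfs_s >= 1 - 1e-12):  # no PFS exits ever observed
            matrix = TransitionMatrix(1.0, 0.0, 0.0, 1.0, 0.0)
            return CalibrationResult(matrix, *_sse((1, 0, 1), self.os_curve, self.pfs_curve)[::-1],
                                     converged=False,
                                     message="flat PFS curve: no exits observed; "
                                             "PD parameters unidentifiable")
        a0 = self._init_pfs_stay()
        # deterministic coarse grid over (a, w, b); a grid augmented with
        # the closed-form initialiser
        grid = np.round(np.arange(self.GRID_STEP, 1.0, self.GRID_STEP), 10)
        a_grid = np.unique(np.append(grid, np.clip(a0, 1e-6, 1 - 1e-6)))
        best = None
        for a in a_grid:
            for w in grid:
                for b in grid:
                    s_pfs, s_os = _sse((a, w, b), self.os_curve, self.pfs_curve)
                    self._n_eval += 1
                    key = (s_pfs + s_os, a, w, b)
                    if best is None or key < best:
                        best = key
        self.descent_path.append(best[0])
        z0 = _logit(np.array(best[1:]))
        res = minimize(self._objective, z0, method="Nelder-Mead",
                       options={"fatol": self.SSE_TOL, "xatol": 1e-8,
                                "maxfev": self.MAX_EVALS, "maxiter": self.MAX_EVALS})
        a, w, b = _expit(res.x)
        matrix = TransitionMatrix(
            p_pfs_pfs=a, p_pfs_pd=(1 - a) * w, p_pfs_death=(1 - a) * (1 - w),
            p_pd_pd=b, p_pd_death=1 - b)
        s_pfs, s_os = _sse((a, w, b), self.os_curve, self.pfs_curve)
        # exits to PD are unidentifiable when the PD state is never
        # meaningfully occupied (OS ~ PFS everywhere)
        identifiable = np.any(self.os_curve.survival - self.pfs_curve.survival > 1e-6)
        converged = bool(res.success)
        message = "" if res.success else str(res.message)
        if not identifiable:
            converged = False
            message = (message + "; " if message else "") + \
                "OS ~ PFS everywhere: PD-state parameters weakly identified"
        return CalibrationResult(matrix, sse_os=s_os, sse_pfs=s_pfs,
                                 converged=converged, message=message,
                                 n_evaluations=self._n_eval)


def calibrate_transitions(os_curve: SurvivalCurve, pfs_curve: SurvivalCurve) -> CalibrationResult:
    """Fit a :class:`TransitionMatrix` to tabulated OS and PFS curves.

    Deterministic given its inputs; see :class:`TransitionCalibrator` for
    the procedure.
    """
    return TransitionCalibrator(os_curve, pfs_curve).fit()


# ---------------------------------------------------------------------------
# Curve I/O: 2-column delimited text (month, survival), header required.

def read_curve(path, kind: str, delimiter: str = ",") -> SurvivalCurve:
    df = pd.read_csv(path, sep=delimiter)
    cols = {c.lower().strip(): c for c in df.columns}
    if "month" not in cols or "survival" not in cols:
        raise ValidationError(
            f"curve file {path} must have 'month' and 'survival' columns, got {list(df.columns)}")
    return SurvivalCurve(kind, df[cols["month"]].to_numpy(),
                         df[cols["survival"]].to_numpy())


def write_curve(curve: SurvivalCurve, path, delimiter: str = ",") -> None:
    curve.to_frame().to_csv(path, sep=delimiter, index=False)


def interpolate_monthly(times, survival, kind: str) -> SurvivalCurve:
    """Linear interpolation of an arbitrarily-sampled curve onto integer
    months (opt-in helper for digitised or irregular curves)."""
    times = np.asarray(times, dtype=float)
    survival = np.asarray(survival, dtype=float)
    order = np.argsort(times)
    times, survival = times[order], survival[order]
    months = np.arange(int(np.floor(times.max())) + 1)
    interp = np.interp(months, times, survival)
    if times.min() > 0:  # anchor at S(0) = 1
        interp = np.interp(months, np.append(0.0, times), np.append(1.0, survival))
    return SurvivalCurve(kind, months, np.minimum.accumulate(np.clip(interp, 0, 1)))
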