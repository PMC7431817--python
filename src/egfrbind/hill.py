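"""Phenomenological analysis of saturation-binding curves.

The Hill isotherm is fitted in log10-concentration space,

    I(c) = Imin + (Imax - Imin) / (1 + 10**(n*(log10 Kd - log10 c))),

where Kd is the apparent dissociation constant (nM) and n the Hill
coefficient (n > 1: apparent positive cooperativity, n < 1: apparent
negative cooperativity).  The Scatchard transform (bound/free vs bound) is
provided as a model-free diagnostic: concave-down indicates apparent
positive, concave-up apparent negative cooperativity or site heterogeneity.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace
import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "BindingCurve",
    "FitFailureError",
    "HillModel",
    "HillResults",
    "background_correct",
    "fit_hill",
    "hill_curve",
    "scatchard",
]


class FitFailureError(RuntimeError):
    """No optimisation start converged; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: list | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass(frozen=True)
class BindingCurve:
    """One saturation-binding curve: EGF concentration vs mean intensity.

    ``conc`` is in nM (strictly increasing); ``intensity`` in arbitrary
    fluorescence units; ``sem`` (optional) the standard error of the mean of
    the replicate intensities, same units.
    """

    conc: np.ndarray
    intensity: np.ndarray
    sem: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        conc = np.asarray(self.conc, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "conc", conc)
        object.__setattr__(self, "intensity", inten)
        if conc.ndim != 1 or conc.shape != inten.shape:
            raise ValueError("conc and intensity must be 1-D arrays of equal length")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if np.any(conc < 0):
            raise ValueError("concentrations must be >= 0 nM")
        if self.sem is not None:
            sem = np.asarray(self.sem, dtype=float)
            if sem.shape != conc.shape:
                raise ValueError("sem must match conc in length")
            if np.any(sem < 0):
                raise ValueError("sem must be >= 0")
            object.__setattr__(self, "sem", sem)

    def __len__(self) -> int:
        return self.conc.size


def background_correct(raw: BindingCurve, blank: float) -> BindingCurve:
    """Subtract a blank intensity; negative results are clipped to zero.

    Clipping is reported through ``warnings.warn`` so silent truncation of
    real signal cannot pass unnoticed.
    """
    if blank < 0:
        raise ValueError("blank intensity must be >= 0")
    corrected = raw.intensity - blank
    n_clip = int(np.sum(corrected < 0))
    if n_clip:
        warnings.warn(
            f"background correction clipped {n_clip} negative intensit"
            f"{'y' if n_clip == 1 else 'ies'} to 0",
            stacklevel=2,
        )
        corrected = np.clip(corrected, 0.0, None)
    return replace(raw, intensity=corrected)


def hill_curve(conc, Imin: float, Imax: float, Kd: float, n: float) -> np.ndarray:
    """Evaluate the Hill isotherm on a concentration grid (nM)."""
    c = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.log10(c)
    return Imin + (Imax - Imin) / (1.0 + 10.0 ** (n * (math.log10(Kd) - logc)))


@dataclass
class HillResults:
    """Hill-fit estimates with asymptotic standard errors.

    ``bse`` are the usual asymptotic (linearised) standard errors from the
    Jacobian at the optimum; for weighted fits the residuals are
    SEM-weighted before the error propagation.
    """

    Imin: float
    Imax: float
    Kd: float
    n: float
    bse: dict[str, float]
    ssr: float
    nobs: int
    weighted: bool
    label: str = ""
    nstarts: int = 0

    @property
    def params(self) -> dict[str, float]:
        return {"Imin": self.Imin, "Imax": self.Imax, "Kd": self.Kd, "n": self.n}

    def predict(self, conc) -> np.ndarray:
        return hill_curve(conc, self.Imin, self.Imax, self.Kd, self.n)

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema_version": 1,
                "model": "hill",
                "label": self.label,
                "params": self.params,
                "bse": self.bse,
                "ssr": self.ssr,
                "nobs": self.nobs,
                "weighted": self.weighted,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, s: str) -> "HillResults":
        d = json.loads(s)
        return cls(
            **d["params"], bse=d["bse"], ssr=d["ssr"], nobs=d["nobs"],
            weighted=d["weighted"], label=d.get("label", ""),
        )

    def summary(self) -> str:
        lines = [
            f"Hill isotherm fit{': ' + self.label if self.label else ''}",
            f"  nobs = {self.nobs}, weighted = {self.weighted}, SSR = {self.ssr:.6g}",
            "  param      estimate     std err",
        ]
        for k, v in self.params.items():
            lines.append(f"  {k:<8} {v:>12.6g}  {self.bse[k]:>10.3g}")
        return "\n".join(lines)


class HillModel:
    """Least-squares Hill fit of one binding curve.

    The fit runs multi-start (n in {0.5, 1, 2} crossed with Kd at the
    concentration quartiles) and keeps the best residual norm, breaking ties
    toward the smallest Hill coefficient.  ``weighted=True`` uses 1/sem**2
    weights (requires ``curve.sem`` with no zeros).
    """

    #: minimum points and decades of concentration span for a meaningful fit
    MIN_POINTS = 5
    MIN_DECADES = 2.0

    def __init__(self, curve: BindingCurve, weighted: bool = False):
        if np.any(curve.conc <= 0):
            raise ValueError("Hill fitting requires strictly positive concentrations")
        if len(curve) < self.MIN_POINTS:
            raise ValueError(f"need >= {self.MIN_POINTS} points, got {len(curve)}")
        span = math.log10(curve.conc[-1] / curve.conc[0])
        if span < self.MIN_DECADES:
            raise ValueError(
                f"concentrations must span >= {self.MIN_DECADES} decades, got {span:.2f}"
            )
        if weighted:
            if curve.sem is None:
                raise ValueError("weighted fit requires per-point sem")
            if np.any(curve.sem == 0):
                raise ValueError("weighted fit requires strictly positive sem")
        self.curve = curve
        self.weighted = weighted
        self._w = 1.0 / curve.sem if weighted else np.ones(len(curve))

    # parameter vector: (Imin, Imax, log10 Kd, n)
    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        imin, imax, logkd, n = theta
        pred = imin + (imax - imin) / (
            1.0 + 10.0 ** (n * (logkd - np.log10(self.curve.conc)))
        )
        return self._w * (pred - self.curve.intensity)

    def _starts(self) -> list[np.ndarray]:
        c = self.curve.conc
        i = self.curve.intensity
        imin0 = max(float(i.min()), 0.0)
        imax0 = float(i.max())
        if imax0 <= imin0:
            imax0 = imin0 + 1.0
        kds = np.percentile(c, [25, 50, 75])
        return [
            np.array([imin0, imax0, math.log10(kd), n0])
            for n0 in (0.5, 1.0, 2.0)
            for kd in kds
        ]

    def fit(self) -> HillResults:
        c = self.curve.conc
        lo = [0.0, 0.0, math.log10(c[0]) - 2.0, 0.05]
        hi = [np.inf, np.inf, math.log10(c[-1]) + 2.0, 10.0]
        solutions, diagnostics = [], []
        for x0 in self._starts():
            try:
                sol = least_squares(
                    self._residuals, x0, bounds=(lo, hi),
                    method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
            except Exception as exc:  # pragma: no cover - defensive
                diagnostics.append({"x0": x0.tolist(), "error": str(exc)})
                continue
            diagnostics.append({"x0": x0.tolist(), "cost": sol.cost,
                                "status": sol.status})
            if sol.success and np.all(np.isfinite(sol.x)):
                solutions.append(sol)
        if not solutions:
            raise FitFailureError("Hill fit failed from every start", diagnostics)
        best = min(solutions, key=lambda s: (s.cost, s.x[3]))
        ssr = float(2.0 * best.cost)
        bse = self._asymptotic_errors(best, ssr)
        imin, imax, logkd, n = best.x
        return HillResults(
            Imin=float(imin), Imax=float(imax), Kd=float(10.0 ** logkd),
            n=float(n), bse=bse, ssr=ssr, nobs=len(self.curve),
            weighted=self.weighted, label=self.curve.label,
            nstarts=len(diagnostics),
        )

    def _asymptotic_errors(self, sol, ssr: float) -> dict[str, float]:
        dof = max(len(self.curve) - 4, 1)
        s2 = ssr / dof
        JTJ = sol.jac.T @ sol.jac
        try:
            cov = s2 * np.linalg.pinv(JTJ)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:  # pragma: no cover
            se = np.full(4, np.nan)
        kd = 10.0 ** sol.x[2]
        return {
            "Imin": float(se[0]),
            "Imax": float(se[1]),
            # delta method: Kd = 10**logKd
            "Kd": float(math.log(10.0) * kd * se[2]),
            "n": float(se[3]),
        }


def fit_hill(curve: BindingCurve, weighted: bool = False) -> HillResults:
    """Convenience wrapper: ``HillModel(curve, weighted).fit()``."""
    return HillModel(curve, weighted=weighted).fit()


def scatchard(curve: BindingCurve) -> np.ndarray:
    """Scatchard transform: (bound, bound/free) pairs.

    Bound is proxied by background-corrected intensity and free ligand by the
    nominal concentration (depletion negligible).  Points at c = 0 are
    dropped.  Returns an (m, 2) array.
    """
    mask = curve.conc > 0
    b = curve.intensity[mask]
    return np.column_stack([b, b / curve.conc[mask]])
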