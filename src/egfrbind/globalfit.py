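"""Global fit of the equilibrium model to multiple binding datasets.

Twelve datasets (3 pharmacological conditions x 4 expression gates) are
fitted simultaneously: K2-K9 are shared by all datasets while the
kinase-domain constant K1 takes one value per condition, giving 11 model
parameters.  Measured intensities relate to predicted bound EGF through a
per-condition nuisance scale that is profiled out analytically: for fixed
model parameters the least-squares scale for group g is

    scale_g = sum(w * I * p) / sum(w * p**2)

over all points of the group.  The objective is the (optionally
SEM-weighted) sum of squared deviations between intensity and scale * bound.
Optimisation runs in log10 parameter space with box bounds, multi-start from
a Latin hypercube, each start refined by trust-region least squares;
confidence intervals come from a parametric bootstrap (intensities
re-perturbed by their SEM, the full optimisation repeated).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .equilibrium import binding_curve
from .hill import BindingCurve, FitFailureError
from .parameters import ParameterSet, reference_parameters

__all__ = [
    "CONDITIONS",
    "GATES",
    "DesignCell",
    "GlobalFitConfig",
    "GlobalBindingModel",
    "GlobalFitResults",
    "UnreliableCIError",
    "default_bounds",
    "fit_global",
]

CONDITIONS = ("untreated", "erlotinib", "lapatinib")
GATES = ("low", "medium", "high", "all")


class UnreliableCIError(RuntimeError):
    """Fewer than half of the bootstrap repeats converged."""


@dataclass(frozen=True)
class DesignCell:
    """One condition x expression-gate dataset of the global design."""

    condition: str
    gate: str
    Rtot: float
    curve: BindingCurve

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.gate not in GATES:
            raise ValueError(f"gate must be one of {GATES}")
        if not self.Rtot > 0:
            raise ValueError("Rtot must be > 0")


def default_bounds(conditions: Sequence[str]) -> dict[str, tuple[float, float]]:
    """Box bounds per parameter: two decades below to four above the
    published magnitude of each constant."""
    ref = reference_parameters("untreated").as_dict() | {"K1": None}
    bounds: dict[str, tuple[float, float]] = {}
    for cond in conditions:
        v = reference_parameters(cond).K1
        bounds[f"K1:{cond}"] = (v * 1e-2, v * 1e4)
    for name in ("K2", "K3", "K4", "K5", "K6", "K7", "K8", "K9"):
        v = ref[name]
        bounds[name] = (v * 1e-2, v * 1e4)
    return bounds


@dataclass
class GlobalFitConfig:
    """Settings of the global optimisation.

    ``bounds`` maps parameter names (``K1:<condition>``, ``K2`` ... ``K9``)
    to (lower, upper) on the linear scale; ``starts`` Latin-hypercube starts
    are refined and the best norm wins, ties broken toward the smallest K7
    (the least identifiable axis).  ``repeats`` bootstrap refits build the
    95% CIs; ``ci_starts`` (None = same as ``starts``) controls the
    multi-start budget of each repeat, which always additionally warm-starts
    at the point estimate.  ``scale_per`` is "condition" (one nuisance scale
    per pharmacological condition, shared across gates measured with common
    staining and instrument settings) or "dataset".  ``weighting`` is
    "none" (plain SSE) or "sem" (1/sem**2 weights).

    ``fixed`` pins parameters at stated values instead of fitting them.  The
    default pins the two structurally non-identifiable directions of the
    model: bound-ligand curves are *exactly* invariant under
    K2+1 -> g*(K2+1), K3 -> K3/g, K4 -> K4/g**2, K7 -> K7/g**2 (see
    :func:`gauge_transform`), so K2 is fixed as a gauge choice, and a second,
    numerically exact flat direction trades the symmetric- against the
    asymmetric-dimer pathway (K5, K6, K8, K9, K7 and the K1s move jointly at
    constant fit quality), which fixing K5 pins.  With both pinned the
    remaining nine parameters are identifiable.  Pass ``fixed={}`` for the
    literal all-eleven-free fit; its K2/K3/K4/K7 and K5/K6/K8 outputs are
    then arbitrary points on the flat manifold.
    """

    bounds: dict[str, tuple[float, float]] | None = None
    starts: int = 40
    repeats: int = 100
    ci_starts: int | None = None
    seed: int = 0
    scale_per: str = "condition"
    weighting: str = "none"
    fixed: dict[str, float] | None = None  # None -> default gauge {K2, K5}
    x0: dict[str, float] | None = None  # optional extra (warm) start

    def __post_init__(self):
        if self.starts < 1:
            raise ValueError("starts must be >= 1")
        if self.scale_per not in ("condition", "dataset"):
            raise ValueError("scale_per must be 'condition' or 'dataset'")
        if self.weighting not in ("none", "sem"):
            raise ValueError("weighting must be 'none' or 'sem'")
        if self.fixed is not None:
            for name, v in self.fixed.items():
                if not (isinstance(v, (int, float)) and v > 0 and math.isfinite(v)):
                    raise ValueError(f"fixed value for {name} must be positive finite")
        if self.bounds is not None:
            for name, (lo, hi) in self.bounds.items():
                if not (0 < lo < hi < math.inf):
                    raise ValueError(f"bounds for {name} must be finite and positive")


@dataclass
class GlobalFitResults:
    """Point estimates, nuisance scales, diagnostics and CIs of a global fit."""

    params: dict[str, float]
    scales: dict[str, float]
    ssr: float
    nobs: int
    start_norms: list[float]
    boundary_flags: list[str]
    conditions: tuple[str, ...]
    model: "GlobalBindingModel" = field(repr=False)
    fixed: dict[str, float] = field(default_factory=dict)
    ci: dict[str, tuple[float, float]] | None = None

    def parameter_set(self, condition: str) -> ParameterSet:
        """Assemble the nine constants in force for one condition."""
        shared = {k: self.params[k] for k in
                  ("K2", "K3", "K4", "K5", "K6", "K7", "K8", "K9")}
        return ParameterSet(K1=self.params[f"K1:{condition}"], **shared)

    def predict(self, design: Sequence[DesignCell] | None = None) -> list[np.ndarray]:
        """Fitted intensity (scale * bound) on each dataset's grid."""
        design = list(design) if design is not None else self.model.design
        out = []
        for cell in design:
            p = self.parameter_set(cell.condition)
            bound = binding_curve(p, cell.Rtot, cell.curve.conc)
            out.append(self.scales[self.model.scale_key(cell)] * bound)
        return out

    def confidence_intervals(
        self, repeats: int | None = None, seed: int | None = None
    ) -> dict[str, tuple[float, float]]:
        """Parametric-bootstrap 95% CIs (2.5/97.5 percentiles over refits)."""
        self.ci = self.model.confidence_intervals(self, repeats=repeats, seed=seed)
        return self.ci

    def to_json(self) -> str:
        d = {
            "schema_version": 1,
            "model": "global_equilibrium_fit",
            "params": self.params,
            "scales": self.scales,
            "ssr": self.ssr,
            "nobs": self.nobs,
            "boundary_flags": self.boundary_flags,
            "fixed": self.fixed,
            "scale_per": self.model.config.scale_per,
            "weighting": self.model.config.weighting,
            "ci_method": "parametric bootstrap, SEM-perturbed intensities",
        }
        if self.ci is not None:
            d["ci95"] = {k: list(v) for k, v in self.ci.items()}
        return json.dumps(d, indent=2)

    def summary(self) -> str:
        lines = [
            "Global equilibrium binding fit",
            f"  datasets = {len(self.model.design)}, nobs = {self.nobs}, "
            f"SSR = {self.ssr:.6g}",
            f"  scale sharing = per {self.model.config.scale_per}, "
            f"weighting = {self.model.config.weighting}",
            "  param           estimate" + ("        95% CI" if self.ci else ""),
        ]
        for k, v in self.params.items():
            line = f"  {k:<14} {v:>10.4g}"
            if k in self.fixed:
                line += "    [fixed: identifiability gauge]"
            elif self.ci is not None:
                lo, hi = self.ci[k]
                line += f"    ({lo:.4g} - {hi:.4g})"
            lines.append(line)
        if self.boundary_flags:
            lines.append(f"  WARNING: at bounds: {', '.join(self.boundary_flags)}")
        return "\n".join(lines)


class GlobalBindingModel:
    """Simultaneous fit of the equilibrium model to a multi-dataset design."""

    def __init__(self, design: Sequence[DesignCell],
                 config: GlobalFitConfig | None = None):
        design = list(design)
        if len(design) < 2:
            raise ValueError("need at least two design cells for a global fit")
        seen = set()
        for cell in design:
            key = (cell.condition, cell.gate)
            if key in seen:
                raise ValueError(f"duplicate condition/gate pair {key}")
            seen.add(key)
            if len(cell.curve) < 8:
                raise ValueError(
                    f"curve for {key} has {len(cell.curve)} points; need >= 8"
                )
        self.design = design
        self.config = config or GlobalFitConfig()
        self.conditions = tuple(c for c in CONDITIONS
                                if any(d.condition == c for d in design))
        self.param_names = [f"K1:{c}" for c in self.conditions] + [
            "K2", "K3", "K4", "K5", "K6", "K7", "K8", "K9"
        ]
        if self.config.fixed is None:
            ref = reference_parameters("untreated")
            self.fixed = {"K2": ref.K2, "K5": ref.K5}
        else:
            self.fixed = dict(self.config.fixed)
        unknown = [n for n in self.fixed if n not in self.param_names]
        if unknown:
            raise ValueError(f"fixed refers to unknown parameters {unknown}")
        self.free_names = [n for n in self.param_names if n not in self.fixed]
        if not self.free_names:
            raise ValueError("at least one parameter must remain free")
        # full log10 parameter vector: fixed entries filled, free overwritten
        self._full_template = np.array([
            math.log10(self.fixed[n]) if n in self.fixed else np.nan
            for n in self.param_names
        ])
        self._free_idx = np.array(
            [i for i, n in enumerate(self.param_names) if n not in self.fixed],
            dtype=int,
        )
        bounds = self.config.bounds or default_bounds(self.conditions)
        missing = [n for n in self.free_names if n not in bounds]
        if missing:
            raise ValueError(f"bounds missing for parameters {missing}")
        self._lo = np.log10([bounds[n][0] for n in self.free_names])
        self._hi = np.log10([bounds[n][1] for n in self.free_names])
        if self.config.weighting == "sem":
            for cell in design:
                if cell.curve.sem is None or np.any(cell.curve.sem == 0):
                    raise ValueError(
                        "sem weighting requires strictly positive sem on every curve"
                    )
        self._w = [
            1.0 / cell.curve.sem if self.config.weighting == "sem"
            else np.ones(len(cell.curve))
            for cell in design
        ]
        self.nobs = sum(len(c.curve) for c in design)
        self._build_flat_arrays()

    def _build_flat_arrays(self) -> None:
        """Concatenate all datasets for a single-pass vectorised objective."""
        cond_index = {c: i for i, c in enumerate(self.conditions)}
        self._groups = sorted({self.scale_key(c) for c in self.design})
        group_index = {g: i for i, g in enumerate(self._groups)}
        L, R, ci, gi, slices = [], [], [], [], []
        start = 0
        for cell, w in zip(self.design, self._w):
            n = len(cell.curve)
            L.append(cell.curve.conc)
            R.append(np.full(n, cell.Rtot))
            ci.append(np.full(n, cond_index[cell.condition], dtype=int))
            gi.append(np.full(n, group_index[self.scale_key(cell)], dtype=int))
            slices.append(slice(start, start + n))
            start += n
        self._L = np.concatenate(L)
        self._R = np.concatenate(R)
        self._ci = np.concatenate(ci)
        self._gi = np.concatenate(gi)
        self._slices = slices
        self._w_flat = np.concatenate(self._w)
        self._I_flat = np.concatenate([c.curve.intensity for c in self.design])

    def scale_key(self, cell: DesignCell) -> str:
        if self.config.scale_per == "condition":
            return cell.condition
        return f"{cell.condition}:{cell.gate}"

    # ---- objective -------------------------------------------------------

    def _full_theta(self, theta: np.ndarray) -> np.ndarray:
        full = self._full_template.copy()
        full[self._free_idx] = theta
        return full

    def _params_from_theta(self, theta: np.ndarray) -> dict[str, float]:
        return dict(zip(self.param_names, 10.0 ** self._full_theta(theta)))

    def _bound_flat(self, theta: np.ndarray) -> np.ndarray:
        """Predicted bound EGF at every point, one vectorised pass.

        Inlines the closed-form equilibrium solution (same algebra as
        :func:`egfrbind.equilibrium.binding_curve`) with a per-point K1
        selected by condition; validation is skipped because log-space box
        bounds already guarantee positive finite constants.
        """
        v = 10.0 ** self._full_theta(np.asarray(theta))
        ncond = len(self.conditions)
        K1 = v[:ncond][self._ci]
        K2, K3, K4, K5, K6, K7, K8, K9 = v[ncond:]
        L, R = self._L, self._R
        inv_k1 = 1.0 / K1
        b = K2 + K2 * inv_k1 + 1.0 + inv_k1 + (L / K3) * (1.0 + inv_k1)
        a = 2.0 * ((1.0 + L / K5 + L * L / (K5 * K6)) / K4
                   + (1.0 + L / K8 + L * L / (K8 * K9)) * inv_k1 * inv_k1 / K7)
        EI = 2.0 * R / (b + np.sqrt(b * b + 4.0 * a * R))
        DES = EI * EI / K4
        DEA = (EI * inv_k1) ** 2 / K7
        return (EI * (1.0 + inv_k1) * L / K3
                + DES * (L / K5) * (1.0 + 2.0 * L / K6)
                + DEA * (L / K8) * (1.0 + 2.0 * L / K9))

    def _profiled_scale_vec(self, pred: np.ndarray,
                            intensity: np.ndarray) -> np.ndarray:
        w2 = self._w_flat * self._w_flat
        num = np.bincount(self._gi, w2 * intensity * pred, len(self._groups))
        den = np.bincount(self._gi, w2 * pred * pred, len(self._groups))
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        return scale

    def _profiled_scales(self, theta: np.ndarray,
                         intensity: np.ndarray) -> dict[str, float]:
        scale = self._profiled_scale_vec(self._bound_flat(theta), intensity)
        return dict(zip(self._groups, map(float, scale)))

    def _residuals(self, theta: np.ndarray, intensity: np.ndarray) -> np.ndarray:
        pred = self._bound_flat(theta)
        scale = self._profiled_scale_vec(pred, intensity)
        return self._w_flat * (intensity - scale[self._gi] * pred)

    # ---- optimisation ----------------------------------------------------

    def _start_points(self, n_lhs: int, seed: int,
                      extra: list[np.ndarray] | None = None) -> list[np.ndarray]:
        starts = list(extra or [])
        if self.config.x0 is not None:
            x0 = np.log10([self.config.x0[n] for n in self.free_names])
            starts.append(np.clip(x0, self._lo, self._hi))
        n_lhs = max(n_lhs - len(starts), 0)
        if n_lhs:
            sampler = qmc.LatinHypercube(d=len(self.free_names), seed=seed)
            unit = sampler.random(n_lhs)
            starts.extend(self._lo + unit * (self._hi - self._lo))
        return starts

    def _fit_once(self, intensity: np.ndarray, n_starts: int, seed: int,
                  extra_starts: list[np.ndarray] | None = None):
        """Run the multi-start optimisation; return (best_sol, norms, diags)."""
        solutions, norms, diags = [], [], []
        for x0 in self._start_points(n_starts, seed, extra_starts):
            try:
                sol = least_squares(
                    self._residuals, x0, args=(intensity,),
                    bounds=(self._lo, self._hi), method="trf",
                    x_scale="jac", xtol=1e-13, ftol=1e-13, gtol=1e-13,
                    max_nfev=4000,
                )
            except Exception as exc:
                diags.append({"x0": list(map(float, x0)), "error": str(exc)})
                continue
            diags.append({"x0": list(map(float, x0)), "cost": float(sol.cost),
                          "status": int(sol.status)})
            if sol.success and np.isfinite(sol.cost):
                solutions.append(sol)
                norms.append(float(2.0 * sol.cost))
        if not solutions:
            raise FitFailureError("every global-fit start failed", diags)
        best_norm = min(2.0 * s.cost for s in solutions)
        # ties include solutions whose norm sits at the floating-point floor
        # of the objective (residuals ~eps relative to the intensities)
        floor = self.nobs * (1e-13 * float(np.max(np.abs(intensity), initial=0.0))) ** 2
        tol = 1e-9 * max(best_norm, 1e-300) + floor
        contenders = [s for s in solutions if 2.0 * s.cost <= best_norm + tol]
        if "K7" in self.free_names and len(contenders) > 1:
            ik7 = self.free_names.index("K7")
            best = min(contenders, key=lambda s: s.x[ik7])
        else:
            best = min(contenders, key=lambda s: s.cost)
        return best, norms, diags

    def fit(self) -> GlobalFitResults:
        best, norms, _ = self._fit_once(
            self._I_flat, self.config.starts, self.config.seed
        )
        pdict = self._params_from_theta(best.x)
        scales = self._profiled_scales(best.x, self._I_flat)
        flags = [
            n for n, x, lo, hi in zip(self.free_names, best.x, self._lo, self._hi)
            if x - lo < 1e-6 or hi - x < 1e-6
        ]
        if flags:
            warnings.warn(f"parameters at bounds: {', '.join(flags)}", stacklevel=2)
        return GlobalFitResults(
            params={k: float(v) for k, v in pdict.items()},
            scales=scales,
            ssr=float(2.0 * best.cost),
            nobs=self.nobs,
            start_norms=norms,
            boundary_flags=flags,
            conditions=self.conditions,
            model=self,
            fixed=dict(self.fixed),
        )

    # ---- bootstrap confidence intervals ---------------------------------

    def confidence_intervals(
        self, results: GlobalFitResults,
        repeats: int | None = None, seed: int | None = None,
    ) -> dict[str, tuple[float, float]]:
        """95% CIs by parametric bootstrap.

        Each repeat perturbs every intensity by Normal(0, sem) and reruns the
        multi-start optimisation, always warm-starting at the point estimate.
        Raises :class:`UnreliableCIError` if fewer than half of the repeats
        converge.
        """
        for cell in self.design:
            if cell.curve.sem is None:
                raise ValueError("bootstrap CIs require per-point sem on every curve")
        repeats = repeats if repeats is not None else self.config.repeats
        seed = seed if seed is not None else self.config.seed + 1
        n_starts = (self.config.ci_starts if self.config.ci_starts is not None
                    else self.config.starts)
        rng = np.random.default_rng(seed)
        warm = np.log10([results.params[n] for n in self.free_names])
        sem_flat = np.concatenate([cell.curve.sem for cell in self.design])
        samples = []
        for _ in range(repeats):
            perturbed = self._I_flat + rng.normal(0.0, 1.0, self.nobs) * sem_flat
            try:
                best, _, _ = self._fit_once(
                    perturbed, n_starts, int(rng.integers(2**31 - 1)),
                    extra_starts=[warm],
                )
            except FitFailureError:
                continue
            samples.append(10.0 ** self._full_theta(best.x))
        if len(samples) < repeats / 2:
            raise UnreliableCIError(
                f"only {len(samples)}/{repeats} bootstrap repeats converged"
            )
        arr = np.array(samples)
        lo = np.percentile(arr, 2.5, axis=0)
        hi = np.percentile(arr, 97.5, axis=0)
        # the interval always contains the point estimate by convention
        est = np.array([results.params[n] for n in self.param_names])
        lo = np.minimum(lo, est)
        hi = np.maximum(hi, est)
        return {
            n: (float(l), float(h))
            for n, l, h in zip(self.param_names, lo, hi)
        }


def fit_global(design: Sequence[DesignCell],
               config: GlobalFitConfig | None = None) -> GlobalFitResults:
    """Convenience wrapper: ``GlobalBindingModel(design, config).fit()``."""
    return GlobalBindingModel(design, config).fit()
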