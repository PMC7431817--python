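"""Homo-FRET anisotropy analysis of receptor clustering.

Energy migration between spectrally identical fluorophores (homo-FRET)
depolarises emission, so clustering is read out as a drop in fluorescence
anisotropy

    r = (I_par - G * I_perp) / (I_par + 2 * G * I_perp),

where G corrects for the polarisation sensitivity of the detection path.
Progressive photobleaching dilutes FRET partners inside clusters: plotting
anisotropy against the residual unbleached fraction s and fitting a
binomial mixture model yields the cluster size N (fluorophores per cluster)
and the monomer fraction ``mon``.  For a cluster of N fluorophores of which
k survive bleaching (probability C(N,k) s^k (1-s)^(N-k)), the
intensity-weighted anisotropy contribution of the clustered population is

    (1-mon)/(N*s) * sum_k C(N,k) s^k (1-s)^(N-k) * k
        * [ r1*(1+d^6)/(1+k*d^6) + rFRET*(k-1)*d^6/(1+k*d^6) ],

added to ``mon * r1`` for the monomers.  r1 is the anisotropy of an isolated
fluorophore (0.34 for GFP), rFRET the anisotropy of FRET-excited emission
(taken as 0), and d the Foerster distance divided by the inter-fluorophore
distance (1 when the spacing equals R0 = 4.8 nm for a GFP pair).  The model
satisfies r -> r1 as s -> 0 and r = r1 for N = 1 or mon = 1.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
import numpy as np

__all__ = [
    "R1_GFP",
    "UndefinedAnisotropyError",
    "PolarizedReading",
    "BleachSeries",
    "ClusterModel",
    "ClusterResults",
    "anisotropy",
    "model_anisotropy",
    "fit_bleach_series",
    "mc_confidence",
]

#: Limiting anisotropy of monomeric GFP.
R1_GFP = 0.34


class UndefinedAnisotropyError(ZeroDivisionError):
    """Total intensity I_par + 2*G*I_perp is not positive."""


@dataclass(frozen=True)
class PolarizedReading:
    """One polarised intensity pair with its G factor."""

    I_par: float
    I_perp: float
    G: float = 1.0

    def __post_init__(self):
        if self.I_par < 0 or self.I_perp < 0:
            raise ValueError("intensities must be >= 0")
        if not self.G > 0:
            raise ValueError("G factor must be > 0")

    @property
    def r(self) -> float:
        return anisotropy(self.I_par, self.I_perp, self.G)


def anisotropy(I_par, I_perp, G: float = 1.0):
    """Fluorescence anisotropy from polarised intensity components.

    Accepts scalars or arrays; raises
    :class:`UndefinedAnisotropyError` when the total intensity
    I_par + 2*G*I_perp is zero (anisotropy undefined).
    """
    I_par = np.asarray(I_par, dtype=float)
    I_perp = np.asarray(I_perp, dtype=float)
    denom = I_par + 2.0 * G * I_perp
    if np.any(denom <= 0):
        raise UndefinedAnisotropyError("total intensity must be > 0")
    out = (I_par - G * I_perp) / denom
    return float(out) if out.ndim == 0 else out


def model_anisotropy(s, N, mon: float, d: float = 1.0,
                     r1: float = R1_GFP, r_fret: float = 0.0):
    """Anisotropy of a monomer/N-mer mixture at residual unbleached fraction s.

    Parameters
    ----------
    s
        Residual unbleached fraction in [0, 1]; scalar or array.  s = 0
        returns the analytic limit r1.
    N
        Cluster size, integer >= 1.  Non-integer N is accepted and handled
        by linear interpolation between the two neighbouring integer-N
        models (a smooth relaxation for sensitivity analysis).
    mon
        Monomer fraction in [0, 1].
    d
        Foerster distance over inter-fluorophore distance (default 1).
    r1, r_fret
        Anisotropy of directly and FRET-excited fluorophores.
    """
    if N < 1:
        raise ValueError("cluster size N must be >= 1")
    if not 0.0 <= mon <= 1.0:
        raise ValueError("monomer fraction must lie in [0, 1]")
    s_arr = np.asarray(s, dtype=float)
    if np.any((s_arr < 0) | (s_arr > 1)):
        raise ValueError("residual fraction s must lie in [0, 1]")
    if float(N) != int(N):
        n_lo = int(math.floor(N))
        frac = float(N) - n_lo
        lo = model_anisotropy(s_arr, n_lo, mon, d, r1, r_fret)
        hi = model_anisotropy(s_arr, n_lo + 1, mon, d, r1, r_fret)
        out = (1.0 - frac) * np.asarray(lo) + frac * np.asarray(hi)
        return float(out) if out.ndim == 0 else out
    N = int(N)
    d6 = d**6
    out = np.full(s_arr.shape, float(r1))
    pos = s_arr > 0
    sp = s_arr[pos]
    clustered = np.zeros_like(sp)
    # binomial survival of k of N fluorophores, intensity weight k
    for k in range(1, N + 1):
        pk = math.comb(N, k) * sp**k * (1.0 - sp) ** (N - k)
        rk = (r1 * (1.0 + d6) + r_fret * (k - 1) * d6) / (1.0 + k * d6)
        clustered += pk * k * rk
    clustered /= N * sp
    out[pos] = mon * r1 + (1.0 - mon) * clustered
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class BleachSeries:
    """Ordered (s, r, sd) points from one photobleaching sequence.

    ``s`` must start at 1 and decrease strictly; ``sd`` is the anisotropy
    standard deviation across images (optional, required for Monte-Carlo
    confidence intervals).
    """

    s: np.ndarray
    r: np.ndarray
    sd: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        s = np.asarray(self.s, dtype=float)
        r = np.asarray(self.r, dtype=float)
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "r", r)
        if s.ndim != 1 or s.shape != r.shape:
            raise ValueError("s and r must be 1-D arrays of equal length")
        if s[0] != 1.0:
            raise ValueError("the first residual fraction must be 1")
        if np.any(np.diff(s) >= 0):
            raise ValueError("residual fractions must decrease strictly")
        if np.any(s <= 0):
            raise ValueError("residual fractions must be > 0")
        if self.sd is not None:
            sd = np.asarray(self.sd, dtype=float)
            if sd.shape != s.shape:
                raise ValueError("sd must match s in length")
            if np.any(sd < 0):
                raise ValueError("sd must be >= 0")
            object.__setattr__(self, "sd", sd)

    def __len__(self) -> int:
        return self.s.size


@dataclass
class ClusterResults:
    """Cluster size and monomer fraction estimated from a bleach series."""

    N: int
    mon: float
    ssr: float
    r1: float
    d: float
    r_fret: float
    degenerate: bool
    profile: list[tuple[int, float, float]]  # (N, profiled mon, SSR)
    ci: dict[str, tuple[float, float]] | None = None

    def predict(self, s) -> np.ndarray:
        return model_anisotropy(s, self.N, self.mon, self.d, self.r1, self.r_fret)

    def to_json(self) -> str:
        d = {
            "schema_version": 1,
            "model": "homofret_cluster",
            "N": self.N,
            "mon": self.mon,
            "ssr": self.ssr,
            "fixed": {"r1": self.r1, "d": self.d, "r_fret": self.r_fret},
            "degenerate": self.degenerate,
        }
        if self.ci is not None:
            d["ci95"] = {k: list(v) for k, v in self.ci.items()}
        return json.dumps(d, indent=2)

    def summary(self) -> str:
        lines = [
            "Homo-FRET cluster fit",
            f"  cluster size N   = {self.N}",
            f"  monomer fraction = {self.mon:.4f}",
            f"  SSR = {self.ssr:.3e}  (r1 = {self.r1}, d = {self.d}, "
            f"rFRET = {self.r_fret})",
        ]
        if self.degenerate:
            lines.append("  WARNING: series is flat; cluster size unidentifiable")
        if self.ci is not None:
            for k, (lo, hi) in self.ci.items():
                lines.append(f"  95% CI {k}: ({lo:.3g} - {hi:.3g})")
        return "\n".join(lines)


class ClusterModel:
    """Fit (N, mon) to a bleach series with r1, d, rFRET fixed.

    N is optimised over the integer grid 1..n_max; for each N the monomer
    fraction enters the model linearly
    (r = g_N(s) + mon * (r1 - g_N(s)), with g_N the pure-cluster curve), so
    ``mon`` is profiled in closed form and clipped to [0, 1].  The best
    (N, mon) by SSR wins; ties break toward the smallest N.
    """

    MIN_POINTS = 6
    MAX_MIN_S = 0.3  # bleaching must reach below this residual fraction

    def __init__(self, series: BleachSeries, n_max: int = 30,
                 d: float = 1.0, r1: float = R1_GFP, r_fret: float = 0.0,
                 weighted: bool = False):
        if len(series) < self.MIN_POINTS:
            raise ValueError(f"need >= {self.MIN_POINTS} points, got {len(series)}")
        if series.s[-1] >= self.MAX_MIN_S:
            raise ValueError(
                f"bleaching must reach s < {self.MAX_MIN_S}; series stops at "
                f"s = {series.s[-1]:.2f}"
            )
        if weighted and (series.sd is None or np.any(series.sd == 0)):
            raise ValueError("weighted fit requires strictly positive sd")
        self.series = series
        self.n_max = int(n_max)
        self.d, self.r1, self.r_fret = d, r1, r_fret
        self._w = (1.0 / series.sd if weighted else np.ones(len(series)))

    def _profile_mon(self, N: int, r: np.ndarray) -> tuple[float, float]:
        """Closed-form least-squares mon for fixed N; returns (mon, SSR)."""
        g = np.asarray(
            model_anisotropy(self.series.s, N, 0.0, self.d, self.r1, self.r_fret)
        )
        basis = self.r1 - g  # model: g + mon * basis
        denom = float(np.sum((self._w * basis) ** 2))
        if denom == 0.0:  # N = 1: model is identically r1
            mon = 1.0
        else:
            mon = float(np.sum(self._w**2 * basis * (r - g)) / denom)
            mon = min(max(mon, 0.0), 1.0)
        resid = self._w * (g + mon * basis - r)
        return mon, float(np.sum(resid**2))

    def fit(self, r: np.ndarray | None = None,
            quiet: bool = False) -> ClusterResults:
        r = np.asarray(r, dtype=float) if r is not None else self.series.r
        profile = []
        for N in range(1, self.n_max + 1):
            mon, ssr = self._profile_mon(N, r)
            profile.append((N, mon, ssr))
        best_ssr = min(p[2] for p in profile)
        tol = 1e-12 * max(best_ssr, 1e-300) + 1e-30
        N, mon, ssr = next(p for p in profile if p[2] <= best_ssr + tol)
        degenerate = N == 1 or mon >= 1.0 - 1e-9
        if degenerate:
            # an all-monomer solution is flat at r1: N carries no information
            N, mon = 1, 1.0
            if not quiet:
                warnings.warn(
                    "anisotropy series is flat; cluster size unidentifiable "
                    "(returning the degenerate monomer solution)",
                    stacklevel=2,
                )
        return ClusterResults(
            N=N, mon=mon, ssr=ssr, r1=self.r1, d=self.d, r_fret=self.r_fret,
            degenerate=degenerate, profile=profile,
        )


def fit_bleach_series(series: BleachSeries, n_max: int = 30,
                      **kwargs) -> ClusterResults:
    """Convenience wrapper: ``ClusterModel(series, n_max, ...).fit()``."""
    return ClusterModel(series, n_max=n_max, **kwargs).fit()


def mc_confidence(series: BleachSeries, reps: int = 500,
                  seed: int | None = None, n_max: int = 30,
                  **kwargs) -> dict[str, object]:
    """Monte-Carlo 95% confidence intervals for cluster size and monomer
    fraction.

    ``reps`` synthetic series are drawn pointwise from Normal(r, sd) of the
    measured series and each is refitted; the 2.5/97.5 percentiles of the
    estimates form the intervals.  Returns a dict with keys ``"N"`` and
    ``"mon"`` mapping to (lo, hi), plus the raw ``"samples"`` arrays.
    """
    if series.sd is None:
        raise ValueError("Monte-Carlo CIs require per-point sd")
    rng = np.random.default_rng(seed)
    model = ClusterModel(series, n_max=n_max, **kwargs)
    ns = np.empty(reps)
    mons = np.empty(reps)
    for i in range(reps):
        r_sim = series.r + rng.normal(0.0, 1.0, len(series)) * series.sd
        res = model.fit(r=r_sim, quiet=True)
        ns[i] = res.N
        mons[i] = res.mon
    return {
        "N": (float(np.percentile(ns, 2.5)), float(np.percentile(ns, 97.5))),
        "mon": (float(np.percentile(mons, 2.5)), float(np.percentile(mons, 97.5))),
        "samples": {"N": ns, "mon": mons},
    }
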