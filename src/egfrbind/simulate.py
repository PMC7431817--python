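"""Synthetic binding and photobleaching experiments from known ground truth.

The binding generator emulates the flow-cytometric design the analysis
assumes: a 2-fold EGF dilution series (default 14 points descending from
260 nM) measured in 3 replicates on cell populations of known receptor
number, under 3 pharmacological conditions (untreated, erlotinib,
lapatinib — modelled as condition-specific K1) x 4 expression gates
(low/medium/high/all, default 390,000 / 630,000 / 1,070,000 / 560,000
receptors/cell).  Replicate intensities carry multiplicative Gaussian noise
(default CV 5%, the error-bar scale of high-count flow-cytometry means);
the reported intensity is the replicate mean with its SEM.

The bleach generator draws anisotropy-vs-residual-fraction series from the
binomial cluster-mixture model plus additive Gaussian noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .equilibrium import binding_curve
from .globalfit import DesignCell
from .hill import BindingCurve
from .homofret import R1_GFP, BleachSeries, model_anisotropy
from .parameters import REFERENCE_K1, ParameterSet, reference_parameters

__all__ = [
    "AVOGADRO",
    "DEFAULT_RTOT",
    "BindingSimDesign",
    "FretSimDesign",
    "concentration_grid",
    "bleach_schedule",
    "simulate_binding_experiment",
    "simulate_bleach_experiment",
    "depletion_check",
]

logger = logging.getLogger(__name__)

AVOGADRO = 6.02214076e23

#: Receptor number per expression gate (receptors/cell).
DEFAULT_RTOT = {
    "low": 390_000.0,
    "medium": 630_000.0,
    "high": 1_070_000.0,
    "all": 560_000.0,
}


def concentration_grid(top: float = 260.0, n: int = 14) -> np.ndarray:
    """Ascending 2-fold dilution series ending at ``top`` nM (n points)."""
    if n < 2 or top <= 0:
        raise ValueError("need top > 0 and at least two points")
    return top / 2.0 ** np.arange(n - 1, -1, -1, dtype=float)


def bleach_schedule(steps: int = 12, ratio: float = 0.77) -> np.ndarray:
    """Geometric photobleaching schedule: s = 1, ratio, ratio^2, ..."""
    if steps < 2 or not 0 < ratio < 1:
        raise ValueError("need steps >= 2 and 0 < ratio < 1")
    return ratio ** np.arange(steps, dtype=float)


@dataclass
class BindingSimDesign:
    """Ground truth and sampling plan for a synthetic binding experiment.

    ``truth`` holds the shared constants K2-K9 (its K1 is ignored when
    ``k1_by_condition`` is given); ``scale_by_condition`` sets the
    intensity-per-bound-EGF nuisance scale of each condition.
    """

    truth: ParameterSet = field(default_factory=reference_parameters)
    k1_by_condition: dict[str, float] = field(
        default_factory=lambda: dict(REFERENCE_K1))
    rtot_by_gate: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RTOT))
    grid: np.ndarray = field(default_factory=concentration_grid)
    replicates: int = 3
    cv: float = 0.05
    scale_by_condition: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.size < 8:
            raise ValueError("concentration grid must have >= 8 points")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.cv < 0:
            raise ValueError("noise CV must be >= 0")
        for cond, k1 in self.k1_by_condition.items():
            if not k1 > 0:
                raise ValueError(f"K1 for {cond} must be > 0")
        for gate, rtot in self.rtot_by_gate.items():
            if not rtot > 0:
                raise ValueError(f"Rtot for {gate} must be > 0")
        if self.scale_by_condition is None:
            self.scale_by_condition = {c: 1.0 for c in self.k1_by_condition}


def simulate_binding_experiment(design: BindingSimDesign) -> list[DesignCell]:
    """Generate one condition x gate design of noisy saturation curves.

    Each replicate intensity is scale * bound * (1 + eps) with
    eps ~ Normal(0, CV); reported intensity is the replicate mean and sem
    the replicate SEM (0 when CV = 0 or replicates = 1).  Negative draws are
    truncated at 0 and logged.  Output is deterministic for a given seed.
    """
    rng = np.random.default_rng(design.seed)
    cells = []
    n_trunc = 0
    for cond, k1 in design.k1_by_condition.items():
        params = design.truth.replace(K1=k1)
        scale = design.scale_by_condition[cond]
        for gate, rtot in design.rtot_by_gate.items():
            mean = scale * binding_curve(params, rtot, design.grid)
            eps = rng.normal(0.0, design.cv, (design.replicates, mean.size)) \
                if design.cv > 0 else np.zeros((design.replicates, mean.size))
            reps = mean * (1.0 + eps)
            neg = reps < 0
            n_trunc += int(neg.sum())
            reps[neg] = 0.0
            intensity = reps.mean(axis=0)
            if design.replicates > 1 and design.cv > 0:
                sem = reps.std(axis=0, ddof=1) / np.sqrt(design.replicates)
            else:
                sem = np.zeros_like(intensity)
            curve = BindingCurve(
                conc=design.grid, intensity=intensity, sem=sem,
                label=f"{cond}/{gate}",
            )
            cells.append(DesignCell(condition=cond, gate=gate,
                                    Rtot=rtot, curve=curve))
    if n_trunc:
        logger.warning("truncated %d negative replicate intensities to 0", n_trunc)
    return cells


@dataclass
class FretSimDesign:
    """Ground truth and schedule for a synthetic photobleaching series."""

    N: int = 4
    mon: float = 0.2
    schedule: np.ndarray = field(default_factory=bleach_schedule)
    sd: float = 0.003
    d: float = 1.0
    r1: float = R1_GFP
    r_fret: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.schedule = np.asarray(self.schedule, dtype=float)
        if self.N < 1 or not 0 <= self.mon <= 1 or self.sd < 0:
            raise ValueError("invalid FRET simulation design")


def simulate_bleach_experiment(design: FretSimDesign) -> BleachSeries:
    """Draw one anisotropy-vs-residual-fraction series from the mixture model."""
    rng = np.random.default_rng(design.seed)
    r_true = np.asarray(model_anisotropy(
        design.schedule, design.N, design.mon, design.d,
        design.r1, design.r_fret,
    ))
    noise = rng.normal(0.0, design.sd, r_true.size) if design.sd > 0 else 0.0
    return BleachSeries(
        s=design.schedule,
        r=r_true + noise,
        sd=np.full(r_true.size, float(design.sd)),
        label=f"N={design.N}, mon={design.mon}",
    )


def depletion_check(bound_per_cell: float, cells: float,
                    volume_liters: float, L_total_nM: float) -> float:
    """Fraction of the added ligand captured by the cells.

    The solver treats free ligand as equal to added ligand; this utility
    quantifies the error of that assumption.  A value << 1 (e.g. the
    ~3e-4 obtained for 1e6 EGF/cell on 1e5 cells in 520 ul at 1 nM)
    justifies neglecting depletion.
    """
    if cells < 0 or bound_per_cell < 0:
        raise ValueError("bound_per_cell and cells must be >= 0")
    if volume_liters <= 0 or L_total_nM <= 0:
        raise ValueError("volume and total ligand must be > 0")
    total_ligand = L_total_nM * 1e-9 * AVOGADRO * volume_liters
    return bound_per_cell * cells / total_ligand
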