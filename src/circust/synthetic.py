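"""Ground-truthed synthetic cohorts for testing the ordering pipeline.

The generator emulates the statistical structure the method assumes: a set
of rhythmic genes following FMM waves of a common circular time (the 12
canonical seed clock genes with fixed, biologically ordered peak phases,
plus additional rhythmic genes with stratified peaks), non-rhythmic
confound genes (flat noise, monotone drift, batch shifts, sharp spikes),
and sample collection times that are equispaced, uniform, or clustered in
two von Mises modes to mimic time-of-death distributions in postmortem
cohorts.  Columns are emitted in a random permutation; the truth (times,
parameters, rhythmic flags) is returned alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data_io import ExpressionMatrix
from .fmm import FMMParameters, fmm_evaluate
from .metrics import arc_distance

TWO_PI = 2.0 * np.pi

__all__ = ["DEFAULT_SEED_PHASES", "SimulationSpec", "GroundTruth",
           "simulate", "make_fixture_suite"]

# Canonical peak phases (radians; 0 = lights-on) for the 12 seed clock
# genes.  The morning cluster (NR1D1, PER genes, DBP, TEF) precedes the
# CRY genes, with ARNTL peaking at the light/dark transition (pi) and
# RORA/CLOCK in the inactive half -- the precedence chain
# DBP <= {CRY1, CRY2} <= ARNTL holds counterclockwise.
DEFAULT_SEED_PHASES: dict[str, float] = {
    "NR1D1": 0.6,
    "PER1": 0.9,
    "PER3": 1.0,
    "DBP": 1.2,
    "TEF": 1.3,
    "PER2": 1.5,
    "CRY2": 2.2,
    "CRY1": 2.6,
    "ARNTL": float(np.pi),
    "STAT3": 3.5,
    "RORA": 4.5,
    "CLOCK": 5.5,
}


@dataclass
class SimulationSpec:
    """Conditions of one synthetic cohort.

    ``n_rhythmic`` counts all rhythmic genes including the 12 seed genes
    (which are always present; with ``seed_mode="noise"`` they are emitted
    as flat noise instead, for quality-gate fixtures).  ``noise_sd`` is the
    Gaussian noise standard deviation in normalized units (one unit = one
    wave amplitude).
    """

    m: int = 100
    time_scheme: str = "uniform"  # equispaced | uniform | bimodal
    n_rhythmic: int = 40
    n_confound: int = 60
    seed_phases: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEED_PHASES))
    omega_range: tuple[float, float] = (0.3, 1.0)
    seed_omega_range: tuple[float, float] = (0.6, 1.0)
    amplitude_range: tuple[float, float] = (1.0, 3.0)
    baseline_range: tuple[float, float] = (5.0, 10.0)
    noise_sd: float = 0.1
    confound_kinds: tuple[str, ...] = ("flat", "linear-drift", "batch-shift",
                                       "spike")
    seed_mode: str = "rhythmic"  # rhythmic | noise
    bimodal_locs: tuple[float, float] = (np.pi / 2, 3 * np.pi / 2)
    bimodal_kappa: float = 4.0
    rng_seed: int = 20230928

    def __post_init__(self) -> None:
        if self.m < 10:
            raise ValueError("need at least 10 samples")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.seed_mode == "rhythmic" and self.n_rhythmic < len(self.seed_phases):
            raise ValueError("n_rhythmic must cover the seed genes")
        if self.time_scheme not in {"equispaced", "uniform", "bimodal"}:
            raise ValueError(f"unknown time scheme {self.time_scheme!r}")


@dataclass
class GroundTruth:
    """True per-sample times (aligned to emitted columns), per-gene wave
    parameters (None for confounds) and rhythmic flags."""

    true_times: np.ndarray
    gene_params: dict[str, Optional[FMMParameters]]
    rhythmic: dict[str, bool]
    permutation: np.ndarray

    @property
    def n_rhythmic(self) -> int:
        return sum(self.rhythmic.values())

    def true_peak(self, gene: str) -> float:
        from .fmm import peak_time
        p = self.gene_params[gene.upper()]
        if p is None:
            raise KeyError(f"{gene} is not rhythmic")
        return peak_time(p)


def _alpha_for_peak(t_u: float, beta: float, omega: float) -> float:
    """Translation alpha placing the wave's peak at t_u for given beta, omega."""
    inner = 2.0 * np.arctan2(np.sin(-beta / 2.0), omega * np.cos(-beta / 2.0))
    return float(np.mod(t_u - inner, TWO_PI))


def _sample_times(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.time_scheme == "equispaced":
        return TWO_PI * np.arange(spec.m) / spec.m
    if spec.time_scheme == "uniform":
        return rng.uniform(0.0, TWO_PI, spec.m)
    comp = rng.integers(0, 2, spec.m)
    locs = np.asarray(spec.bimodal_locs)[comp]
    return np.mod(rng.vonmises(locs, spec.bimodal_kappa), TWO_PI)


def _rhythmic_gene(t: np.ndarray, t_u: float, beta: float, omega: float,
                   spec: SimulationSpec,
                   rng: np.random.Generator) -> tuple[np.ndarray, FMMParameters]:
    a = rng.uniform(*spec.amplitude_range)
    m0 = rng.uniform(*spec.baseline_range)
    params = FMMParameters(m=m0, a=a, alpha=_alpha_for_peak(t_u, beta, omega),
                           beta=beta, omega=omega)
    y = fmm_evaluate(params, t)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd * a, len(t))
    return y, params


def _confound_gene(kind: str, t: np.ndarray, spec: SimulationSpec,
                   rng: np.random.Generator) -> np.ndarray:
    m = len(t)
    a = rng.uniform(*spec.amplitude_range)
    m0 = rng.uniform(*spec.baseline_range)
    if kind == "flat":
        return m0 + rng.normal(0.0, 0.5 * a, m)
    if kind == "linear-drift":
        # monotone in emitted sample index, not in circular time
        return m0 + a * np.linspace(-1.0, 1.0, m) + rng.normal(0.0, 0.1 * a, m)
    if kind == "batch-shift":
        groups = rng.permutation(m) < m // 2
        return m0 + a * (groups - 0.5) + rng.normal(0.0, 0.1 * a, m)
    if kind == "spike":
        t0 = rng.uniform(0.0, TWO_PI)
        width = 0.12
        bump = np.exp(-0.5 * (arc_distance(t, t0) / width) ** 2)
        return m0 + a * bump + rng.normal(0.0, 0.05 * a, m)
    raise ValueError(f"unknown confound kind {kind!r}")


def simulate(spec: SimulationSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate one cohort; deterministic given ``spec.rng_seed``."""
    rng = np.random.default_rng(spec.rng_seed)
    base_times = _sample_times(spec, rng)
    perm = rng.permutation(spec.m)
    t = base_times[perm]

    names: list[str] = []
    rows: list[np.ndarray] = []
    params: dict[str, Optional[FMMParameters]] = {}
    rhythmic: dict[str, bool] = {}

    seeds = list(spec.seed_phases)
    if spec.seed_mode == "rhythmic":
        for gene in seeds:
            beta = float(np.mod(rng.uniform(-0.5, 0.5), TWO_PI))
            omega = rng.uniform(*spec.seed_omega_range)
            y, p = _rhythmic_gene(t, spec.seed_phases[gene], beta, omega,
                                  spec, rng)
            names.append(gene)
            rows.append(y)
            params[gene] = p
            rhythmic[gene] = True
        n_extra = spec.n_rhythmic - len(seeds)
    else:
        for gene in seeds:
            names.append(gene)
            rows.append(_confound_gene("flat", t, spec, rng))
            params[gene] = None
            rhythmic[gene] = False
        n_extra = spec.n_rhythmic

    # non-seed rhythmic genes: peaks stratified around the circle (jittered)
    # so every quarter is covered, shapes drawn from the spec ranges
    for i in range(n_extra):
        gene = f"RHY{i + 1:03d}"
        t_u = np.mod(TWO_PI * (i + 0.5) / max(n_extra, 1)
                     + rng.uniform(-0.2, 0.2), TWO_PI)
        beta = rng.uniform(0.0, TWO_PI)
        omega = rng.uniform(*spec.omega_range)
        y, p = _rhythmic_gene(t, float(t_u), beta, omega, spec, rng)
        names.append(gene)
        rows.append(y)
        params[gene] = p
        rhythmic[gene] = True

    for i in range(spec.n_confound):
        kind = spec.confound_kinds[i % len(spec.confound_kinds)]
        gene = f"CONF{i + 1:03d}_{kind.replace('-', '_').upper()}"
        names.append(gene)
        rows.append(_confound_gene(kind, t, spec, rng))
        params[gene] = None
        rhythmic[gene] = False

    x = ExpressionMatrix(
        values=np.vstack(rows),
        gene_ids=names,
        sample_ids=[f"S{j + 1:04d}" for j in range(spec.m)],
        state="raw",
    )
    truth = GroundTruth(true_times=t, gene_params=params, rhythmic=rhythmic,
                        permutation=perm)
    return x, truth


def make_fixture_suite() -> list[tuple[str, ExpressionMatrix, GroundTruth]]:
    """Canonical named fixtures exercising the pipeline's regimes."""
    specs = {
        "clean-equispaced": SimulationSpec(
            m=50, time_scheme="equispaced", n_rhythmic=12, n_confound=0,
            noise_sd=0.0, omega_range=(1.0, 1.0), seed_omega_range=(1.0, 1.0),
            rng_seed=101),
        "noisy-uneven": SimulationSpec(
            m=100, time_scheme="uniform", n_rhythmic=40, n_confound=20,
            noise_sd=0.1, rng_seed=102),
        "asymmetric-heavy": SimulationSpec(
            m=100, time_scheme="uniform", n_rhythmic=30, n_confound=10,
            noise_sd=0.1, omega_range=(0.1, 0.4), seed_omega_range=(0.4, 0.7),
            rng_seed=103),
        "confound-heavy": SimulationSpec(
            m=100, time_scheme="uniform", n_rhythmic=40, n_confound=60,
            noise_sd=0.1, rng_seed=104),
        "gate-fail": SimulationSpec(
            m=60, time_scheme="uniform", n_rhythmic=0, n_confound=50,
            seed_mode="noise", noise_sd=0.3, rng_seed=105),
    }
    return [(name, *simulate(s)) for name, s in specs.items()]
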