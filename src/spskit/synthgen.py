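"""Parametric generator of biased time series, plus a small SSA fixture.

Training and evaluating warm-up detectors needs trajectories whose true
steady-state mean and warm-up length are *known*.  The generator produces

    x_i = mu + bias_i + eps_i

where the bias occupies the first L = floor(l * n) observations and then
vanishes.  The bias is the product of an amplitude A, a trend envelope
(constant, or quadratically decaying to zero at L) and a shape (straight
line, oscillation, or random), giving six bias types.  The noise is an
AR(1)-autocorrelated stream of symmetric uniform innovations scaled as a
percentage of mu; symmetry keeps the true steady-state mean exactly mu.

The SSA fixture generates trajectories of a reversible bimolecular binding
system A + B <-> AB with Gillespie's exact algorithm, emulating the
species-count time series that stochastic reaction-network simulators
produce: a noisy approach from the initial condition to a steady level.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
import numpy as np

from .core import TimeSeries

TRENDS = ("constant", "quadratic")
SHAPES = ("line", "oscillating", "random")


@dataclass(frozen=True)
class GeneratorSpec:
    """All knobs of one generated problem; ``seed`` makes output bit-reproducible.

    ``noise_low``/``noise_high`` are percentages of ``steady_mean``: the
    per-series noise level theta is drawn once, uniformly from [low, high],
    and innovations are then uniform on ±theta% of the mean.
    """

    n: int = 1000
    bias_fraction: float = 0.25
    trend: str = "constant"
    shape: str = "line"
    steady_mean: float = 10.0
    bias_amplitude: float = 5.0
    noise_low: float = 0.0
    noise_high: float = 0.0
    autocorr: float = 0.0
    oscillation_period: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"invalid n: {self.n}")
        if not 0 <= self.bias_fraction < 1:
            raise ValueError(f"invalid bias_fraction: {self.bias_fraction}")
        if self.trend not in TRENDS:
            raise ValueError(f"invalid trend: {self.trend!r} (one of {TRENDS})")
        if self.shape not in SHAPES:
            raise ValueError(f"invalid shape: {self.shape!r} (one of {SHAPES})")
        if self.steady_mean <= 0:
            raise ValueError(f"invalid steady_mean: {self.steady_mean}")
        if self.bias_amplitude < 0:
            raise ValueError(f"invalid bias_amplitude: {self.bias_amplitude}")
        if not 0 <= self.noise_low <= self.noise_high:
            raise ValueError(
                f"invalid noise bounds: low={self.noise_low}, high={self.noise_high}"
            )
        if not 0 <= self.autocorr < 1:
            raise ValueError(f"invalid autocorr: {self.autocorr}")
        if self.oscillation_period < 1:
            raise ValueError(f"invalid oscillation_period: {self.oscillation_period}")

    @property
    def warmup_length(self) -> int:
        return int(self.bias_fraction * self.n)


@dataclass(frozen=True)
class LabeledSeries:
    """A generated series with its ground truth attached."""

    values: TimeSeries
    true_mean: float
    warmup_length: int
    spec: GeneratorSpec
    problem_id: str = ""
    replication: int = 0


def _bias(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    n, L, A = spec.n, spec.warmup_length, spec.bias_amplitude
    i = np.arange(1, n + 1, dtype=float)
    envelope = np.zeros(n)
    if L > 0:
        head = i[:L]
        if spec.trend == "constant":
            envelope[:L] = 1.0
        else:  # quadratic decay, reaching 0 exactly at i = L
            envelope[:L] = ((L - head) / L) ** 2
    if spec.shape == "line":
        shape = np.ones(n)
    elif spec.shape == "oscillating":
        shape = np.sin(2 * np.pi * i / spec.oscillation_period)
    else:  # random
        shape = rng.uniform(-1.0, 1.0, size=n)
    return A * envelope * shape


def _noise(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    theta = rng.uniform(spec.noise_low, spec.noise_high)
    if theta == 0.0:
        return np.zeros(spec.n)
    innovations = rng.uniform(-theta, theta, size=spec.n) * spec.steady_mean / 100.0
    rho = spec.autocorr
    if rho == 0.0:
        return innovations
    eps = np.empty(spec.n)
    prev = 0.0
    scaled = (1 - rho) * innovations
    for i in range(spec.n):  # AR(1): eps_i = rho*eps_{i-1} + (1-rho)*nu_i
        prev = rho * prev + scaled[i]
        eps[i] = prev
    return eps


def generate_series(spec: GeneratorSpec) -> LabeledSeries:
    """One labeled series; the same spec (incl. seed) always yields the same output."""
    rng = np.random.default_rng(spec.seed)
    # draw order is fixed: bias shape stream first, then the noise stream
    values = spec.steady_mean + _bias(spec, rng) + _noise(spec, rng)
    return LabeledSeries(
        values=values,
        true_mean=spec.steady_mean,
        warmup_length=spec.warmup_length,
        spec=spec,
    )


def enumerate_bias_types() -> list[tuple[str, str]]:
    """The six (trend, shape) combinations, in fixed order."""
    return [(t, s) for t in TRENDS for s in SHAPES]


@dataclass(frozen=True)
class ProblemGrid:
    """A full-factorial design over the generator's key factors.

    Defaults are the package's standard study conditions: bias lengths of
    10-60% of the series, noise from 0 to 50% of the steady mean, AR(1)
    factor 0.3, all six bias types, series of 1000 and 2000 points.
    """

    bias_fractions: tuple[float, ...] = (0.1, 0.25, 0.4, 0.6)
    bias_types: tuple[tuple[str, str], ...] = tuple(
        (t, s) for t in TRENDS for s in SHAPES
    )
    noise_levels: tuple[float, ...] = (0.0, 10.0, 25.0, 50.0)
    lengths: tuple[int, ...] = (1000, 2000)
    autocorr: float = 0.3
    steady_mean: float = 10.0
    bias_amplitude: float = 5.0
    oscillation_period: int = 20
    replications: int = 10

    def __post_init__(self) -> None:
        for name in ("bias_fractions", "bias_types", "noise_levels", "lengths"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"empty grid dimension: {name}")
        if self.replications < 1:
            raise ValueError("replications must be >= 1")


def default_training_grid() -> ProblemGrid:
    """The standard training conditions for the shipped pipeline.

    A single series length (1000) and 5 replications per problem definition
    keep the training set at 480 series, which trains in about a minute on
    one core while covering all six bias types, four bias lengths and four
    noise levels.
    """
    return ProblemGrid(lengths=(1000,), replications=5)


def default_test_grid() -> ProblemGrid:
    """Held-out test conditions: factor values between the training points."""
    return ProblemGrid(
        bias_fractions=(0.15, 0.3, 0.5),
        noise_levels=(5.0, 20.0, 40.0),
        lengths=(1000,),
        replications=2,
    )


def _derived_seed(master_seed: int, spec_key: str, replication: int) -> int:
    digest = hashlib.sha256(f"{spec_key}|{replication}".encode()).hexdigest()
    return (master_seed + int(digest[:8], 16) + replication) % (2**31 - 1)


def generate_problem_set(grid: ProblemGrid, seed: int) -> list[LabeledSeries]:
    """Cross product of the grid, ``replications`` labeled series per cell.

    Every replication gets a distinct seed derived from the master seed and
    a stable hash of the problem definition, so two runs with the same
    master seed produce identical output.
    """
    problems: list[LabeledSeries] = []
    for l in grid.bias_fractions:
        for trend, shape in grid.bias_types:
            for noise in grid.noise_levels:
                for n in grid.lengths:
                    base = GeneratorSpec(
                        n=n,
                        bias_fraction=l,
                        trend=trend,
                        shape=shape,
                        steady_mean=grid.steady_mean,
                        bias_amplitude=grid.bias_amplitude,
                        noise_low=noise,
                        noise_high=noise,
                        autocorr=grid.autocorr,
                        oscillation_period=grid.oscillation_period,
                    )
                    pid = f"l{l}_{trend}_{shape}_noise{noise}_n{n}"
                    key = json.dumps(asdict(base), sort_keys=True)
                    for rep in range(grid.replications):
                        spec = replace(base, seed=_derived_seed(seed, key, rep))
                        labeled = generate_series(spec)
                        problems.append(
                            replace(labeled, problem_id=pid, replication=rep)
                        )
    return problems


def problem_specs(grid: ProblemGrid, seed: int) -> list[GeneratorSpec]:
    """The specs of :func:`generate_problem_set`, without generating values."""
    return [p.spec for p in generate_problem_set(grid, seed)]


# ---------------------------------------------------------------------------
# Gillespie SSA fixture: A + B <-> AB

def ssa_fixture(
    kf: float,
    kr: float,
    a0: int,
    b0: int,
    ab0: int = 0,
    n_samples: int = 500,
    t_end: float = 50.0,
    seed: int = 0,
) -> LabeledSeries:
    """Exact stochastic simulation of reversible bimolecular binding.

    Mass-action propensities kf*A*B and kr*AB; the AB count is sampled at
    ``n_samples`` uniform time points.  The true mean is taken from the
    deterministic rate-equation equilibrium (the physical root of
    kf*(At - x)*(Bt - x) = kr*x) and the warm-up length is the first sample
    within 1% of it.  If all propensities vanish before the horizon the
    trajectory is padded with the last state.
    """
    if min(kf, kr) < 0 or min(a0, b0, ab0) < 0:
        raise ValueError("rates and counts must be non-negative")
    rng = np.random.default_rng(seed)
    at, bt = a0 + ab0, b0 + ab0  # conserved totals
    sample_times = np.linspace(0.0, t_end, n_samples)
    samples = np.empty(n_samples, dtype=float)
    t, a, b, ab = 0.0, a0, b0, ab0
    cursor = 0
    while cursor < n_samples:
        p_bind = kf * a * b
        p_unbind = kr * ab
        total = p_bind + p_unbind
        if total <= 0.0:
            samples[cursor:] = ab
            break
        dt = rng.exponential(1.0 / total)
        while cursor < n_samples and sample_times[cursor] < t + dt:
            samples[cursor] = ab
            cursor += 1
        t += dt
        if t > t_end:
            samples[cursor:] = ab
            break
        if rng.uniform() * total < p_bind:
            a, b, ab = a - 1, b - 1, ab + 1
        else:
            a, b, ab = a + 1, b + 1, ab - 1

    if kf == 0.0:
        equilibrium = 0.0
    else:
        c = kr / kf
        disc = (at + bt + c) ** 2 - 4 * at * bt
        equilibrium = ((at + bt + c) - np.sqrt(disc)) / 2.0
    if equilibrium > 0:
        close = np.nonzero(np.abs(samples - equilibrium) <= 0.01 * equilibrium)[0]
    else:
        close = np.nonzero(samples == 0)[0]
    warmup = int(close[0]) if close.size else n_samples - 1
    spec = GeneratorSpec(n=n_samples, bias_fraction=0.0, steady_mean=max(equilibrium, 1e-9),
                         bias_amplitude=0.0, seed=seed)
    return LabeledSeries(
        values=samples,
        true_mean=float(equilibrium),
        warmup_length=warmup,
        spec=spec,
        problem_id=f"ssa_kf{kf}_kr{kr}_A{a0}_B{b0}",
    )
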