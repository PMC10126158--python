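"""Core data containers shared across the pipeline.

A colony growth experiment produces, per colony, a time series of normalized
log-density (the ``GrowthCurve``).  Fitting the modified logistic model to a
curve yields a ``LogisticFit`` (asymptote ``A``, maximum growth rate ``mu_m``
per hour, lag time ``lam`` in hours).  Downstream, each colony is summarized
as a ``ColonyPhenotype`` (lag, growth rate, time-to-threshold, QC status).
Simulated heterogeneous populations are ``CloneSet`` objects: per-clone lag,
growth rate, and initial size sharing one carrying capacity.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

POPULATIONS = ("de_novo", "adapted")

#: Minimum number of samples for a curve to be analyzable.
MIN_CURVE_POINTS = 8


class DomainError(ValueError):
    """A mathematical precondition was violated (e.g. threshold >= A)."""


class FitConvergenceError(RuntimeError):
    """The nonlinear least-squares fit failed or the input is degenerate."""


@dataclass
class GrowthCurve:
    """One colony's time series of normalized log-density.

    times : hours, strictly increasing (typically 0-24 h at 0.25-h steps)
    values : normalized log-density, dimensionless, >= 0 (detection floor
        maps "no colony yet" to exactly 0)
    """

    colony_id: str
    population: str
    plasmid_id: str
    replicate_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have the same length")
        if len(self.times) < MIN_CURVE_POINTS:
            raise ValueError(
                f"curve {self.colony_id!r} has {len(self.times)} points; "
                f"at least {MIN_CURVE_POINTS} required"
            )
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.values)):
            raise ValueError(f"curve {self.colony_id!r} contains non-finite entries")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"curve {self.colony_id!r} times are not strictly increasing")
        if np.any(self.values < 0):
            raise ValueError(f"curve {self.colony_id!r} has negative density values")
        if self.population not in POPULATIONS:
            raise ValueError(
                f"population must be one of {POPULATIONS}, got {self.population!r}"
            )

    def with_values(self, values: np.ndarray) -> "GrowthCurve":
        """Copy of this curve with replaced values (same identity/times)."""
        return GrowthCurve(
            colony_id=self.colony_id,
            population=self.population,
            plasmid_id=self.plasmid_id,
            replicate_id=self.replicate_id,
            times=self.times.copy(),
            values=np.asarray(values, dtype=float),
        )


@dataclass
class LogisticFit:
    """Parameters of the modified logistic growth model for one curve."""

    A: float
    mu_m: float
    lam: float
    rss: float
    converged: bool


@dataclass
class ColonyPhenotype:
    """Derived per-colony phenotype: lag, growth rate, TTT, and QC status."""

    colony_id: str
    population: str
    plasmid_id: str
    lag_h: float = float("nan")
    growth_rate: float = float("nan")
    ttt_h: float = float("nan")
    qc_pass: bool = True
    qc_reason: str = ""

    def __post_init__(self) -> None:
        if not self.qc_pass and not self.qc_reason:
            raise ValueError("failed QC requires a non-empty qc_reason")


@dataclass
class CloneSet:
    """A simulated heterogeneous population of J clones.

    lags : per-clone lag time lambda_j (hours, >= 0)
    rates : per-clone maximum growth rate mu_j (per hour, >= 0; zero means
        the clone never grows, like residual parents tracked explicitly)
    n0 : per-clone initial size (cells, >= 0); may carry multiplicity
        weights when a large population is represented by fewer clones
    """

    lags: np.ndarray
    rates: np.ndarray
    n0: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.lags = np.atleast_1d(np.asarray(self.lags, dtype=float))
        self.rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        self.n0 = np.atleast_1d(np.asarray(self.n0, dtype=float))
        if not (len(self.lags) == len(self.rates) == len(self.n0)) or len(self.lags) < 1:
            raise ValueError("lags, rates, n0 must be equal-length vectors (J >= 1)")
        if np.any(self.lags < 0):
            raise ValueError("lag times must be >= 0")
        if np.any(self.rates < 0):
            raise ValueError("growth rates must be >= 0")
        if np.any(self.n0 < 0):
            raise ValueError("initial clone sizes must be >= 0")

    @property
    def j(self) -> int:
        return len(self.lags)

    @property
    def total_n0(self) -> float:
        return float(self.n0.sum())


@dataclass
class QCReport:
    """Outcome of quality-control filtering for a batch of curves."""

    passed_ids: list = field(default_factory=list)
    rejected: dict = field(default_factory=dict)  # colony_id -> reason code
    spikes_closed: dict = field(default_factory=dict)  # colony_id -> n points closed

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)
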