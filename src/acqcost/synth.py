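"""Synthetic colony data with the statistical structure the pipeline assumes.

The generator emulates a scanner experiment: per-colony (lag, growth-rate)
phenotypes drawn from lognormal distributions — independently for adapted
colonies, and with an optional positive affine lag-to-growth tradeoff for
de novo colonies — rendered into normalized log-density curves through the
modified logistic model at 15-min sampling over 24 h, with Gaussian
measurement noise, a detection floor that maps not-yet-visible colonies to
zero, and optional planted artifacts (spikes, non-plateau curves, oversized
final densities) for exercising the QC rules.

A convenience ``target_cost`` solves for the de novo lag mean that yields a
chosen acquisition-cost ratio, using deterministic Gauss-Hermite quadrature
of the expected time-to-threshold.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .bootstrap import TRUNCATION_EPS, _draw_lognormal, lognormal_from_moments
from .growth import logistic_model
from .types import GrowthCurve

__all__ = [
    "SynthConfig",
    "PlasmidPreset",
    "PRESETS",
    "gen_phenotypes",
    "render_curves",
    "inject_artifacts",
    "expected_ttt",
    "solve_lag_mean_for_cost",
    "clone_set_generator",
]

ARTIFACT_KINDS = ("spike1", "spike2", "spike_wide", "no_plateau", "size_outlier")


@dataclass
class SynthConfig:
    """Generative settings for one two-population (de novo vs adapted) study.

    Lag moments are in hours; growth moments in normalized log-density
    units per hour (the scale on which colony curves live).  ``tradeoff``
    is ``(slope, intercept, resid_sd)`` applied to de novo clones only.
    If ``target_cost`` is set and ``lag_mean_de_novo`` is None, the de novo
    lag mean is solved so the expected TTT ratio equals the target.
    """

    n_colonies: int = 100
    plasmid_id: str = "synthetic"
    replicate_id: str = "rep1"
    lag_mean_adapted: float = 4.0
    lag_sd_adapted: float = 1.0
    lag_mean_de_novo: float | None = None
    lag_sd_de_novo: float = 1.5
    growth_mean: float = 0.5
    growth_sd: float = 0.05
    tradeoff: tuple[float, float, float] | None = None
    target_cost: float | None = None
    A_jitter_sd: float = 0.02
    noise_sd: float = 0.01
    sampling_dt: float = 0.25
    t_end: float = 24.0
    detection_floor: float = 0.05
    threshold: float = 0.8
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sampling_dt <= 0 or self.t_end <= 0:
            raise ValueError("sampling_dt and t_end must be positive")
        if not (0 <= self.noise_sd < 0.2):
            raise ValueError("noise_sd must lie in [0, 0.2)")
        for v in (self.lag_mean_adapted, self.lag_sd_adapted, self.growth_mean,
                  self.growth_sd):
            if v is not None and v < 0:
                raise ValueError("moments must be non-negative")
        if self.lag_mean_de_novo is None and self.target_cost is None:
            raise ValueError("set lag_mean_de_novo or target_cost")


def _ttt_const(threshold: float, A: float = 1.0) -> float:
    """TTT = lag + _ttt_const/mu on the normalized scale."""
    return (A / 4.0) * (2.0 - np.log(A / threshold - 1.0))


def expected_ttt(lag_mean: float, lag_sd: float, growth_mean: float,
                 growth_sd: float, tradeoff=None, threshold: float = 0.8,
                 n_nodes: int = 48) -> float:
    """E[TTT] under the generative model, by Gauss-Hermite quadrature.

    Lags are lognormal; growth is either an independent lognormal or the
    affine tradeoff map of lag with Gaussian residual, truncated at the
    sampling floor.  Deterministic (no Monte Carlo), so the target-cost
    solver is reproducible independent of seeds.
    """
    c = _ttt_const(threshold)
    z, w = np.polynomial.hermite_e.hermegauss(n_nodes)
    w = w / w.sum()
    loc, shape = lognormal_from_moments(lag_mean, lag_sd)
    lags = np.exp(loc + shape * z)
    if tradeoff is None:
        gloc, gshape = lognormal_from_moments(growth_mean, growth_sd)
        rates = np.maximum(np.exp(gloc + gshape * z), TRUNCATION_EPS)
        e_inv_mu = float(np.sum(w / rates))
        e_lag = float(np.sum(w * lags))
        return e_lag + c * e_inv_mu
    slope, intercept, resid_sd = tradeoff
    ze, we = np.polynomial.hermite_e.hermegauss(24)
    we = we / we.sum()
    rates = intercept + slope * lags[:, None] + resid_sd * ze[None, :]
    rates = np.maximum(rates, TRUNCATION_EPS)
    ttt = lags[:, None] + c / rates
    return float(w @ ttt @ we)


def solve_lag_mean_for_cost(config: SynthConfig) -> float:
    """De novo lag mean achieving ``config.target_cost`` in expectation."""
    if config.target_cost is None:
        raise ValueError("config.target_cost is not set")
    ttt_ad = expected_ttt(config.lag_mean_adapted, config.lag_sd_adapted,
                          config.growth_mean, config.growth_sd,
                          tradeoff=None, threshold=config.threshold)
    target = config.target_cost * ttt_ad

    def f(lag_mean: float) -> float:
        return expected_ttt(lag_mean, config.lag_sd_de_novo, config.growth_mean,
                            config.growth_sd, tradeoff=config.tradeoff,
                            threshold=config.threshold) - target

    lo, hi = 1e-3, 10.0 * target
    return float(brentq(f, lo, hi, xtol=1e-8))


def _resolved_de_novo_lag_mean(config: SynthConfig) -> float:
    if config.lag_mean_de_novo is not None:
        return config.lag_mean_de_novo
    return solve_lag_mean_for_cost(config)


def gen_phenotypes(config: SynthConfig,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Ground-truth per-colony phenotypes for both populations.

    Returns a tidy frame with per-colony lag, growth rate, and the exact
    (closed-form) TTT each colony would show on a noiseless unit-asymptote
    curve — the generator-side oracle for downstream estimates.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lag_dn = _resolved_de_novo_lag_mean(config)
    rows = []
    for population, lag_mean, lag_sd in (
        ("adapted", config.lag_mean_adapted, config.lag_sd_adapted),
        ("de_novo", lag_dn, config.lag_sd_de_novo),
    ):
        lags = np.maximum(_draw_lognormal(rng, lag_mean, lag_sd, config.n_colonies),
                          TRUNCATION_EPS)
        if population == "de_novo" and config.tradeoff is not None:
            slope, intercept, resid_sd = config.tradeoff
            rates = intercept + slope * lags
            if resid_sd > 0:
                rates = rates + rng.normal(0.0, resid_sd, config.n_colonies)
        else:
            rates = _draw_lognormal(rng, config.growth_mean, config.growth_sd,
                                    config.n_colonies)
        rates = np.maximum(rates, TRUNCATION_EPS)
        ttt = lags + _ttt_const(config.threshold) / rates
        for i in range(config.n_colonies):
            rows.append({
                "colony_id": f"{config.plasmid_id}_{population}_{i:04d}",
                "population": population,
                "plasmid_id": config.plasmid_id,
                "replicate_id": config.replicate_id,
                "lag_h": float(lags[i]),
                "growth_rate": float(rates[i]),
                "ttt_true_h": float(ttt[i]),
            })
    return pd.DataFrame(rows)


def render_curves(phenotypes: pd.DataFrame, config: SynthConfig,
                  rng: np.random.Generator | None = None) -> list[GrowthCurve]:
    """Forward-model each phenotype into a noisy sampled growth curve.

    Per colony the asymptote is jittered around 1 (truncated positive),
    Gaussian noise is added at every 15-min sample, and values below the
    detection floor are clipped to exactly 0 (no colony visible yet).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    times = np.arange(0.0, config.t_end + 1e-9, config.sampling_dt)
    curves = []
    for row in phenotypes.itertuples(index=False):
        a = max(rng.normal(1.0, config.A_jitter_sd), 0.2) if config.A_jitter_sd > 0 else 1.0
        values = logistic_model(times, a, row.growth_rate, row.lag_h)
        if config.noise_sd > 0:
            values = values + rng.normal(0.0, config.noise_sd, len(times))
        values = np.where(values < config.detection_floor, 0.0, values)
        curves.append(GrowthCurve(
            colony_id=row.colony_id, population=row.population,
            plasmid_id=row.plasmid_id, replicate_id=row.replicate_id,
            times=times, values=np.clip(values, 0.0, None),
        ))
    return curves


def inject_artifacts(curves: list[GrowthCurve], plan: dict[str, int],
                     seed=None, rng: np.random.Generator | None = None,
                     spike_height: float = 0.3):
    """Plant named artifacts into randomly chosen curves.

    ``plan`` maps artifact kind to count: ``spike1``/``spike2``/``spike_wide``
    (1-, 2- and 4-point positive spikes), ``no_plateau`` (curve still rising
    at the end of the run) and ``size_outlier`` (final density scaled x3).
    Artifacts land on distinct curves.  Returns (curves, manifest) where the
    manifest records which colony received what — the planted-truth oracle
    for QC tests.
    """
    unknown = set(plan) - set(ARTIFACT_KINDS)
    if unknown:
        raise ValueError(f"unknown artifact kinds: {sorted(unknown)}")
    total = sum(plan.values())
    if total > len(curves):
        raise ValueError("more planned artifacts than curves")
    if rng is None:
        rng = np.random.default_rng(seed)

    chosen = rng.choice(len(curves), size=total, replace=False)
    out = list(curves)
    manifest: dict[str, str] = {}
    k = 0
    for kind in ARTIFACT_KINDS:
        for _ in range(plan.get(kind, 0)):
            idx = int(chosen[k]); k += 1
            c = out[idx]
            v = c.values.copy()
            n = len(v)
            if kind in ("spike1", "spike2", "spike_wide"):
                width = {"spike1": 1, "spike2": 2, "spike_wide": 4}[kind]
                start = int(rng.integers(5, n - 5 - width))
                v[start:start + width] += spike_height
            elif kind == "no_plateau":
                # a curve still climbing at its maximal rate when the scan ends
                v = 0.92 * c.times / c.times[-1]
            elif kind == "size_outlier":
                v = v * 3.0
            out[idx] = c.with_values(v)
            manifest[c.colony_id] = kind
    return out, manifest


# ---------------------------------------------------------------------------
# Illustrative synthetic presets (not measured values): three populations
# spanning low / intermediate / high acquisition cost, with lag/growth
# tradeoff strength increasing in cost, as costly-plasmid data show.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlasmidPreset:
    """One synthetic plasmid population, on both measurement scales.

    ``colony`` holds the curve-generation settings (normalized log-density
    scale).  The ``sim_*`` fields parameterize cell-scale competition
    simulations: lags in hours, rates in 1/h of ln cell density, and
    ``sim_tradeoff`` the de novo (slope, intercept, resid_sd) map.
    """

    name: str
    target_cost: float
    colony: SynthConfig
    sim_lag_mean_de_novo: float
    sim_lag_sd_de_novo: float
    sim_lag_mean_adapted: float
    sim_lag_sd_adapted: float
    sim_growth_mean: float
    sim_growth_sd: float
    sim_tradeoff: tuple[float, float, float]


# Cell-scale design notes.  De novo population cores sit on one shallow
# shared lag -> rate line (rate = 0.225 + 0.03 * lag, 1/h), so the 24-h
# growth-time optimum rate*(t_end - lag) peaks near the intermediate
# preset's lag: that is what lets an intermediate-cost population beat both
# a shorter-lag/slower and a longer-lag/faster rival.  Each population's
# own (within-clone) tradeoff slope is much steeper and increases with
# cost, mirroring how per-plasmid lag/growth regressions steepen with
# acquisition cost; the intermediate preset's steep slope and narrow lag
# spread place its fast long-lag clones ~3 SD deep, so they are absent
# from ~100-cell inocula but sampled by >= 10^3-10^4-cell inocula — the
# origin of its biphasic density response.  Adapted counterparts are
# plasmid-independent (chosen, as in competition experiments, for matched
# adapted growth), so ratio calibration is honest but near 1:1.

PRESETS: dict[str, PlasmidPreset] = {
    "low": PlasmidPreset(
        name="low", target_cost=1.1,
        colony=SynthConfig(plasmid_id="low-cost-R64drd-like", target_cost=1.1,
                           tradeoff=(0.010, 0.44, 0.03)),
        sim_lag_mean_de_novo=2.5, sim_lag_sd_de_novo=0.8,
        sim_lag_mean_adapted=2.0, sim_lag_sd_adapted=0.5,
        sim_growth_mean=0.60, sim_growth_sd=0.05,
        sim_tradeoff=(0.05, 0.175, 0.02),
    ),
    "intermediate": PlasmidPreset(
        name="intermediate", target_cost=1.5,
        colony=SynthConfig(plasmid_id="intermediate-cost-RP4-like", target_cost=1.5,
                           tradeoff=(0.040, 0.28, 0.03)),
        sim_lag_mean_de_novo=6.5, sim_lag_sd_de_novo=1.0,
        sim_lag_mean_adapted=2.0, sim_lag_sd_adapted=0.5,
        sim_growth_mean=0.60, sim_growth_sd=0.05,
        sim_tradeoff=(0.20, -0.88, 0.02),
    ),
    "high": PlasmidPreset(
        name="high", target_cost=1.9,
        colony=SynthConfig(plasmid_id="high-cost-pB10-like", target_cost=1.9,
                           tradeoff=(0.070, 0.12, 0.03)),
        sim_lag_mean_de_novo=10.5, sim_lag_sd_de_novo=0.8,
        sim_lag_mean_adapted=2.0, sim_lag_sd_adapted=0.5,
        sim_growth_mean=0.60, sim_growth_sd=0.05,
        sim_tradeoff=(0.22, -1.77, 0.02),
    ),
}


def clone_set_generator(preset: PlasmidPreset, population: str = "de_novo",
                        with_tradeoff: bool = True, j_max: int = 10000):
    """Callable (n_cells, rng) -> CloneSet for sweeps and competitions."""
    from .simulate import draw_clone_set

    if population == "adapted":
        lag_mean, lag_sd = preset.sim_lag_mean_adapted, preset.sim_lag_sd_adapted
        tradeoff = None
    else:
        lag_mean, lag_sd = preset.sim_lag_mean_de_novo, preset.sim_lag_sd_de_novo
        tradeoff = preset.sim_tradeoff if with_tradeoff else None

    def gen(n_cells, rng):
        return draw_clone_set(
            n_cells, lag_mean, lag_sd,
            growth_mean=preset.sim_growth_mean, growth_sd=preset.sim_growth_sd,
            tradeoff=tradeoff, j_max=j_max, label=preset.name, rng=rng,
        )

    return gen
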