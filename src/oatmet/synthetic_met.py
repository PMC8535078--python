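"""Seeded generator of synthetic multi-environment trial data.

Emulates a g-variety x e-environment x r-replicate randomised-block
trial under the same bilinear model the stability analysis assumes:

    y_ijk = mu + V_i + b_i * E_j + eps_ijk,   eps ~ N(0, sigma_eps)

with variety effects ``V_i``, sensitivities ``b_i`` re-centred to mean
exactly 1, environmental indices ``E_j`` re-centred to sum exactly 0,
optional whole-cell missingness, and per-site daily weather whose
windowed aggregate correlates with ``E_j`` at a chosen level ``rho``.
Because the generator inverts the analysis model, fitting the
generated data recovers the truth exactly at zero noise — the
package's main parameter-recovery and calibration harness.

Defaults mirror the reference winter-oat trial: 4 varieties, 22
environments, 3 replicates, grand mean 8.16 t/ha, environment spread
sigma_E = 1.6 (the standard deviation of the trial's printed
environment yield means) and replicate noise 0.3 x sigma_E.

Reproducibility: one root seed is split with
``numpy.random.SeedSequence.spawn`` into independent streams for
(truth draw, replicate noise, missingness, weather), so each
sub-experiment is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .met_core import EnvironmentRecord, MetTable
from .weather_assoc import DailyWeather, WeatherCovariate

__all__ = ["SyntheticTruth", "simulate_met", "simulate_weather", "environment_records"]


@dataclass
class SyntheticTruth:
    """Parameters (and, after realisation, values) of one scenario."""

    seed: int = 0
    n_varieties: int = 4
    n_environments: int = 22
    n_replicates: int = 3
    grand_mean: float = 8.16          # t/ha, reference-trial scale
    sigma_variety: float = 0.5        # sd of drawn variety effects
    sigma_env: float = 1.6            # sd of drawn environment indices
    sigma_slope: float = 0.2          # sd of drawn sensitivities around 1
    sigma_noise: float = 0.48         # replicate noise sd (0.3 x sigma_env)
    missing_prob: float = 0.0         # whole-cell deletion probability
    weather_rho: float = 0.0          # corr(windowed aggregate, E_j)
    trait: str = "yield"
    # optionally user-supplied; drawn when None
    variety_effects: np.ndarray | None = None
    sensitivities: np.ndarray | None = None
    env_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_varieties < 2 or self.n_environments < 3 or self.n_replicates < 1:
            raise ConfigError(
                "need >= 2 varieties, >= 3 environments, >= 1 replicate"
            )
        for name in ("sigma_variety", "sigma_env", "sigma_slope", "sigma_noise"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.missing_prob < 1.0:
            raise ConfigError("missing_prob must be in [0, 1)")
        if not -1.0 <= self.weather_rho <= 1.0:
            raise ConfigError("weather_rho must be in [-1, 1]")
        if self.seed < 0:
            raise ConfigError("seed must be non-negative")

    @property
    def varieties(self) -> list[str]:
        w = len(str(self.n_varieties))
        return [f"V{i+1:0{w}d}" for i in range(self.n_varieties)]

    @property
    def environments(self) -> list[str]:
        # zero-padded so lexicographic label order matches index order
        w = len(str(self.n_environments))
        return [f"E{j+1:0{w}d}" for j in range(self.n_environments)]

    def streams(self) -> dict[str, np.random.Generator]:
        """Independent child generators: truth, noise, missing, weather."""
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("truth", "noise", "missing", "weather")
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}

    def realize(self) -> "SyntheticTruth":
        """Draw (or re-centre supplied) V, b, E; identifiability exact.

        ``b`` is re-centred affinely to mean exactly 1 and ``E`` to sum
        exactly 0, so the truth satisfies the fit's identification
        constraints and recovery can be scored directly.
        """
        rng = self.streams()["truth"]
        g, e = self.n_varieties, self.n_environments
        V = (
            np.asarray(self.variety_effects, float)
            if self.variety_effects is not None
            else rng.normal(0.0, self.sigma_variety, g)
        )
        b = (
            np.asarray(self.sensitivities, float)
            if self.sensitivities is not None
            else rng.normal(1.0, self.sigma_slope, g)
        )
        E = (
            np.asarray(self.env_index, float)
            if self.env_index is not None
            else rng.normal(0.0, self.sigma_env, e)
        )
        if len(V) != g or len(b) != g or len(E) != e:
            raise ConfigError("supplied effect vectors have the wrong length")
        b = b - b.mean() + 1.0
        E = E - E.mean()
        return replace(self, variety_effects=V, sensitivities=b, env_index=E)


def simulate_met(truth: SyntheticTruth) -> tuple[MetTable, SyntheticTruth]:
    """Generate a replicate-level MetTable under the bilinear model.

    Returns the table and the realised truth (with the V, b, E vectors
    actually used).  Whole cells (all replicates of one variety in one
    environment) are deleted with probability ``missing_prob``, except
    where deletion would leave a row or column with fewer than two
    observed cells.  Identical seeds give bit-identical output.
    """
    truth = truth.realize()
    streams = truth.streams()
    g, e, r = truth.n_varieties, truth.n_environments, truth.n_replicates
    V, b, E = truth.variety_effects, truth.sensitivities, truth.env_index

    cell = truth.grand_mean + V[:, None] + b[:, None] * E[None, :]
    eps = streams["noise"].normal(0.0, truth.sigma_noise, size=(g, e, r))
    y = cell[:, :, None] + eps

    keep = np.ones((g, e), dtype=bool)
    if truth.missing_prob > 0:
        rng = streams["missing"]
        for i in range(g):
            for j in range(e):
                if rng.random() < truth.missing_prob:
                    # never starve a row or column below 2 observed cells
                    trial = keep.copy()
                    trial[i, j] = False
                    if trial[i].sum() >= 2 and trial[:, j].sum() >= 2:
                        keep = trial

    vi, ej, rk = np.meshgrid(np.arange(g), np.arange(e), np.arange(r), indexing="ij")
    df = pd.DataFrame(
        {
            "environment": np.asarray(truth.environments)[ej.ravel()],
            "variety": np.asarray(truth.varieties)[vi.ravel()],
            "replicate": rk.ravel() + 1,
            "trait": truth.trait,
            "value": y.ravel(),
        }
    )
    df = df[keep[vi.ravel(), ej.ravel()]].reset_index(drop=True)
    return MetTable(df), truth


def environment_records(
    truth: SyntheticTruth,
    first_harvest_year: int = 2011,
) -> list[EnvironmentRecord]:
    """Plausible site metadata for the synthetic environments.

    Harvest years cycle over four seasons from ``first_harvest_year``;
    sowing is the previous October, harvest mid-August, site
    coordinates spread over the UK oat-growing latitudes.
    """
    recs = []
    for j, env_id in enumerate(truth.environments):
        year = first_harvest_year + (j % 4)
        recs.append(
            EnvironmentRecord(
                environment_id=env_id,
                site=f"Site{j % 9 + 1}",
                latitude=50.5 + (j % 9) * 0.7,
                longitude=-4.0 + (j % 5) * 1.2,
                sowing_date=date(year - 1, 10, 10),
                harvest_date=date(year, 8, 15),
            )
        )
    return recs


def simulate_weather(
    truth: SyntheticTruth,
    covariate: WeatherCovariate,
    envs: Sequence[EnvironmentRecord] | None = None,
    mean_level: float = 200.0,
    sd_level: float = 50.0,
) -> dict[str, DailyWeather]:
    """Daily weather per environment, linked to the environment index.

    The windowed aggregate for environment *j* is constructed as

        A_j = mean_level + sd_level * (rho * z(E_j) + sqrt(1-rho^2) * eps_j)

    where ``z(E)`` is the standardised environment index, so the
    sample correlation between the aggregate and ``E_j`` converges to
    ``rho`` as the number of environments grows (and is exactly affine
    in ``E`` at ``rho = +-1``).  The aggregate is then spread uniformly
    over the window days: rainfall/radiation as equal daily amounts
    (floored at 0), temperature as a constant daily midrange with
    tmin/tmax 4 degC either side.  Days outside the window get a
    neutral filler so the series covers the whole season.

    Returns ``{environment_id: DailyWeather}`` for the realised truth.
    """
    truth = truth.realize()
    rng = truth.streams()["weather"]
    envs = list(envs) if envs is not None else environment_records(truth)
    if len(envs) != truth.n_environments:
        raise ConfigError("one EnvironmentRecord per environment required")

    E = truth.env_index
    sdE = E.std()
    z = (E - E.mean()) / sdE if sdE > 0 else np.zeros_like(E)
    rho = truth.weather_rho
    eps = rng.standard_normal(truth.n_environments)
    aggregate = mean_level + sd_level * (rho * z + np.sqrt(1.0 - rho**2) * eps)

    out: dict[str, DailyWeather] = {}
    for j, env in enumerate(envs):
        start, end = covariate.window.resolve(env.harvest_date.year)
        days = pd.date_range(start, end, freq="D")
        n = len(days)
        frame = pd.DataFrame({"date": days})
        if covariate.variable == "temperature":
            mid = aggregate[j]
            frame["tmin"] = mid - 4.0
            frame["tmax"] = mid + 4.0
            frame["rain"] = 0.0
        else:
            daily = max(aggregate[j], 0.0) / n
            col = "rain" if covariate.variable == "rain" else "radiation"
            frame[col] = daily
            frame["tmin"] = 6.0
            frame["tmax"] = 14.0
        out[env.environment_id] = DailyWeather(frame)
    return out
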