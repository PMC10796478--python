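"""Seeded predator-prey simulator for grazing-experiment datasets.

The generative model matches the assumptions behind the clearance
estimator. The predator is exogenous exponential,

    C(t) = C0 * exp(mu_c * t),

(the grazer can sustain growth on alternative food, so its dynamics are
not coupled to prey yield) and the prey is cleared in proportion to the
predator concentration,

    dB/dt = (k - F * C(t)) * B,

which integrates in closed form to

    ln B(t) = ln B0 + k*t - F*C0*(exp(mu_c*t) - 1)/mu_c,

with the limit ``F*C0*t`` as ``mu_c -> 0``. Observation noise emulates
counting error on 1-mL Lugol-fixed aliquots: multiplicative lognormal
(default sigma = 0.1, a plausible settling-chamber counting CV) or Poisson
counting statistics for a stated counted volume. Depleted Poisson counts
can hit exactly 0 and are recorded as such; the rates module excludes
zeros from log fits.

The default fixture reproduces the experimental design: three prey
strains crossed with a control and a grazed treatment, initial
concentrations of 1000 prey mL^-1 and 200 ciliates mL^-1, sampled every
second day for 20 days.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from grazerates.errors import ValidationError
from grazerates.timeseries_io import CountSeries, Experiment

#: experimental design constants: initial concentrations (cells per mL)
#: and the every-second-day, 20-day sampling grid
DEFAULT_B0 = 1000.0
DEFAULT_C0 = 200.0
DEFAULT_DAYS = tuple(float(d) for d in range(0, 21, 2))

PREY_STRAINS = ("HL3E12", "SH2A6", "SF1A8")

#: scenario parameter sets. Prey growth (0.074 day^-1) is the observed
#: monoculture mean; predator exponential rates correspond to the two
#: grazer phenotypes (ln(1+mu) of per-day multiplicative rates 0.36 and
#: 0.14); the strong clearance (1e-4 mL predator^-1 day^-1) depletes prey
#: well below 10% of start by day 20, the weak one leaves grazed prey
#: within 50-100% of the control.
SCENARIOS = {
    "strong_grazer": dict(
        k=0.074, F_true=1.0e-4, mu_c=float(np.log(100.0) / 20.0), predator="F8"
    ),
    "weak_grazer": dict(
        k=0.074, F_true=2.0e-5, mu_c=float(np.log(1.14)), predator="E8"
    ),
    "null": dict(
        k=0.074, F_true=0.0, mu_c=float(np.log(1.14)), predator="F8"
    ),
}


@dataclass(frozen=True)
class SimParams:
    """Simulator parameters.

    k : prey intrinsic growth rate, day^-1
    F_true : clearance rate, mL predator^-1 day^-1
    C0 : initial predator concentration, cells mL^-1 (0 = monoculture)
    mu_c : predator exponential growth rate, day^-1 (0 = constant predator)
    B0 : initial prey concentration, cells mL^-1
    noise : "none", "lognormal" (parameter ``sigma``), or "poisson"
        (parameter ``count_volume`` in mL)
    seed : RNG seed for the observation noise
    """

    k: float = 0.074
    F_true: float = 0.0
    C0: float = DEFAULT_C0
    mu_c: float = 0.0
    B0: float = DEFAULT_B0
    noise: str = "none"
    sigma: float = 0.1
    count_volume: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B0 <= 0:
            raise ValidationError("B0 must be positive")
        if self.C0 < 0:
            raise ValidationError("C0 must be non-negative")
        if self.noise not in ("none", "lognormal", "poisson"):
            raise ValidationError(f"unknown noise model {self.noise!r}")
        if self.noise == "lognormal" and self.sigma <= 0:
            raise ValidationError("lognormal noise needs sigma > 0")
        if self.noise == "poisson" and self.count_volume <= 0:
            raise ValidationError("poisson noise needs count_volume > 0")


def prey_trajectory(
    t: np.ndarray | float,
    k: float,
    F: float,
    C0: float,
    mu_c: float,
    B0: float,
) -> np.ndarray:
    """Noise-free prey concentration B(t) from the closed-form solution."""
    t = np.asarray(t, dtype=float)
    if mu_c == 0.0:
        grazing_integral = C0 * t
    else:
        grazing_integral = C0 * np.expm1(mu_c * t) / mu_c
    return B0 * np.exp(k * t - F * grazing_integral)


def predator_trajectory(
    t: np.ndarray | float, C0: float, mu_c: float
) -> np.ndarray:
    """Noise-free predator concentration C(t) = C0 * exp(mu_c * t)."""
    return C0 * np.exp(mu_c * np.asarray(t, dtype=float))


def _apply_noise(conc: np.ndarray, params: SimParams, rng: np.random.Generator):
    if params.noise == "none":
        return conc.copy()
    if params.noise == "lognormal":
        noisy = conc * np.exp(params.sigma * rng.standard_normal(conc.shape))
    else:  # poisson counting of a fixed aliquot volume
        noisy = rng.poisson(conc * params.count_volume) / params.count_volume
    return np.maximum(noisy, 0.0)


def simulate_grazing(
    params: SimParams,
    days: Sequence[float] = DEFAULT_DAYS,
    flask_id: str = "sim",
    prey_strain: str = "sim-prey",
    predator_strain: str | None = None,
) -> CountSeries:
    """Simulate one flask's count series under ``params``.

    Days must be strictly increasing and start at 0. Noise is applied
    independently to prey and predator at each sampling time, seeded by
    ``params.seed``; concentrations are floored at 0.
    """
    days = np.asarray(days, dtype=float)
    if len(days) == 0 or days[0] != 0.0 or np.any(np.diff(days) <= 0):
        raise ValidationError("days must be strictly increasing and start at 0")
    prey = prey_trajectory(days, params.k, params.F_true, params.C0, params.mu_c, params.B0)
    predator = predator_trajectory(days, params.C0, params.mu_c)
    rng = np.random.default_rng(params.seed)
    prey = _apply_noise(prey, params, rng)
    if params.C0 > 0:
        predator = _apply_noise(predator, params, rng)
    is_control = params.C0 == 0
    if predator_strain is None and not is_control:
        predator_strain = "sim-predator"
    return CountSeries(
        flask_id=flask_id,
        prey_strain=prey_strain,
        predator_strain=None if is_control else predator_strain,
        treatment="control" if is_control else "grazed",
        days=days,
        prey_conc=prey,
        predator_conc=predator,
    )


def simulate_monoculture(
    k: float,
    B0: float = DEFAULT_B0,
    days: Sequence[float] = DEFAULT_DAYS,
    noise: str = "none",
    seed: int = 0,
    sigma: float = 0.1,
    count_volume: float = 1.0,
    flask_id: str = "mono",
    prey_strain: str = "sim-prey",
) -> CountSeries:
    """Simulate a grazer-free control flask (``C0 = 0``)."""
    params = SimParams(
        k=k, F_true=0.0, C0=0.0, mu_c=0.0, B0=B0,
        noise=noise, sigma=sigma, count_volume=count_volume, seed=seed,
    )
    return simulate_grazing(
        params, days, flask_id=flask_id, prey_strain=prey_strain
    )


def make_fixture_experiment(
    scenario: str,
    seed: int = 0,
    n_replicates: int = 3,
    noise: str = "lognormal",
    sigma: float = 0.1,
    days: Sequence[float] = DEFAULT_DAYS,
) -> tuple[Experiment, SimParams]:
    """Full-design synthetic experiment for a named grazing scenario.

    Emits ``n_replicates`` control and grazed flasks for each of three
    prey strains on the standard sampling grid, plus the ground-truth
    :class:`SimParams` shared by the grazed flasks. Scenarios:

    * ``strong_grazer`` — prey depleted below 10% of start by day 20,
      predator up >= 50-fold (the fast-growing grazer phenotype);
    * ``weak_grazer`` — grazed prey stays within 50-100% of the control
      at day 20 (the slow grazer);
    * ``null`` — clearance 0, grazed flasks identical in distribution to
      controls.
    """
    if scenario not in SCENARIOS:
        raise ValidationError(
            f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}"
        )
    cfg = SCENARIOS[scenario]
    base = SimParams(
        k=cfg["k"], F_true=cfg["F_true"], C0=DEFAULT_C0, mu_c=cfg["mu_c"],
        B0=DEFAULT_B0, noise=noise, sigma=sigma,
    )
    flask_seeds = np.random.SeedSequence(seed).generate_state(
        2 * len(PREY_STRAINS) * n_replicates
    ) % (2**31)
    series = []
    i = 0
    for strain in PREY_STRAINS:
        for rep in range(1, n_replicates + 1):
            ctrl = replace(base, C0=0.0, F_true=0.0, mu_c=0.0, seed=int(flask_seeds[i]))
            series.append(
                simulate_grazing(
                    ctrl, days,
                    flask_id=f"{strain}-ctrl-{rep}", prey_strain=strain,
                )
            )
            i += 1
            gz = replace(base, seed=int(flask_seeds[i]))
            series.append(
                simulate_grazing(
                    gz, days,
                    flask_id=f"{strain}-{cfg['predator']}-{rep}",
                    prey_strain=strain, predator_strain=cfg["predator"],
                )
            )
            i += 1
    return Experiment(series=tuple(series)), base
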