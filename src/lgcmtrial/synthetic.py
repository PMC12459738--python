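"""Seeded generator of synthetic two-arm trials with the structure the analysis assumes.

The generator emulates a randomized waitlist-controlled trial on a mobile
multiplayer game: ~1100 participants allocated 1:1 by a Mersenne-Twister draw,
a female-majority sample, four questionnaire waves at 0/1/2/3 months (QIDS
depression, Brief LSAS social anxiety in virtual and physical contexts),
heavy-tailed monthly behaviour counts (bell rings, avatar customizations),
wave-wise questionnaire dropout, and the completion-bonus / lottery reward
scheme.

Outcomes follow the latent growth curve model generatively: each participant
draws a bivariate-normal (intercept, slope) deviation, trajectories run along
the log2(months+1) loadings, and iid residuals are added per wave.  Behaviour
counts are lognormal on the log2(count+1) scale by default (so the analysis
transform is exactly normal), with a discrete power-law (zipf) alternative.

The default configuration mirrors the magnitudes of the emulated study's
published tables (baseline QIDS ~8.2 with SD ~6, slope arm effect -0.319
implying a change-score SMD of -0.12, bell log2 baselines ~8.1); these are
defaults for realistic demos, not assertions about any real dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd

from .lgcm import LGCMParams
from .measures import TimeBasis, log2p1, time_basis

__all__ = [
    "RewardSchedule",
    "CountModel",
    "GeneratorConfig",
    "TrialDataset",
    "assign_arms",
    "generate",
    "max_total_compensation",
    "implied_change_sd",
    "implied_smd",
    "slope_effect_for_smd",
    "default_config",
    "OUTCOME_NAMES",
    "WIDE_COLUMNS",
]

OUTCOME_NAMES = ("qids", "lsas_v", "lsas_p")
BEHAVIOR_NAMES = ("bell", "custom")

WIDE_COLUMNS = (
    ["pid", "arm", "female", "age"]
    + [f"{o}_w{w}" for o in OUTCOME_NAMES for w in (1, 2, 3, 4)]
    + [f"{b}_w{w}" for b in BEHAVIOR_NAMES for w in (1, 2, 3, 4)]
    + ["bonus_months", "compensation_jpy"]
)


@dataclass(frozen=True)
class RewardSchedule:
    """Questionnaire payments and intervention-phase bonuses, in JPY.

    The emulated scheme pays 500/200/200/500 for the four questionnaire waves
    and a 500 JPY bonus per intervention month (3 months); waitlist
    participants are instead entered in a monthly lottery with probability
    ``waitlist_lottery_p``.
    """

    wave_payments: tuple[int, int, int, int] = (500, 200, 200, 500)
    completion_bonus: int = 500
    n_bonus_months: int = 3
    waitlist_lottery_p: float = 0.73

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.wave_payments) or self.completion_bonus < 0:
            raise ValueError("payments must be non-negative")
        if not 0 <= self.waitlist_lottery_p <= 1:
            raise ValueError("lottery probability must lie in [0, 1]")


def max_total_compensation(schedule: RewardSchedule) -> int:
    """Largest total payout: all wave payments plus every monthly bonus."""
    return int(sum(schedule.wave_payments)
               + schedule.completion_bonus * schedule.n_bonus_months)


@dataclass(frozen=True)
class CountModel:
    """Marginal model for one behaviour count, per arm and wave.

    ``lognormal`` draws log2(count+1) ~ Normal(mean, sd) and rounds back to an
    integer count — the analysis transform is then exactly normal.  ``zipf``
    draws a discrete power law with the given exponent (the per-wave means are
    then governed by the exponent, not ``log2_mean_*``).
    """

    log2_mean_exp: tuple[float, float, float, float]
    log2_mean_wait: tuple[float, float, float, float]
    log2_sd: float
    family: Literal["lognormal", "zipf"] = "lognormal"
    zipf_exponent: float = 2.0

    def __post_init__(self) -> None:
        if self.log2_sd <= 0:
            raise ValueError("log2_sd must be positive")
        if self.family not in ("lognormal", "zipf"):
            raise ValueError(f"unknown count family {self.family!r}")
        if self.family == "zipf" and self.zipf_exponent <= 1:
            raise ValueError("zipf exponent must exceed 1")


def _default_truth() -> dict:
    return {
        # depression: baseline SD ~6.06; slope arm effect -0.319 together with
        # these variance components implies a change-score SMD of -0.12
        "qids": LGCMParams(
            b00=7.5, b0exp=0.0, b0female=0.9, b10=-0.43, b1exp=-0.319, b1female=0.0,
            var_e0=24.6, var_e1=1.0, cov_e01=-1.0, var_e2=12.133,
        ),
        # virtual-community social anxiety: baseline SD ~19, small upward drift
        "lsas_v": LGCMParams(
            b00=28.0, b0exp=0.0, b0female=1.0, b10=0.7, b1exp=0.666, b1female=0.0,
            var_e0=300.0, var_e1=4.0, cov_e01=0.0, var_e2=60.0,
        ),
        # physical-community social anxiety: baseline SD ~23.3, flat control arm
        "lsas_p": LGCMParams(
            b00=45.5, b0exp=0.0, b0female=1.0, b10=-0.05, b1exp=0.319, b1female=0.0,
            var_e0=480.0, var_e1=4.0, cov_e01=0.0, var_e2=63.0,
        ),
    }


def _default_counts() -> dict:
    return {
        "bell": CountModel(
            log2_mean_exp=(8.07, 7.93, 7.29, 6.65),
            log2_mean_wait=(8.15, 7.80, 6.99, 6.35),
            log2_sd=2.6,
        ),
        "custom": CountModel(
            log2_mean_exp=(7.71, 7.56, 6.50, 6.13),
            log2_mean_wait=(7.65, 7.48, 6.39, 5.90),
            log2_sd=1.9,
        ),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic trial.

    Defaults reproduce the emulated study's structure: arm sizes 548/557, 75%
    female, mean age 23.68 (SD 10.44), four waves at 0/1/2/3 months,
    questionnaire dropout rising to 20% by the final wave (missing completely
    at random unless ``mar_strength`` is nonzero, in which case the dropout
    odds increase with the participant's current depression level), and a 73%
    monthly completion/lottery rate in the reward scheme.

    ``behavior_outcome_corr`` builds a target correlation between the wave-4
    minus wave-1 change of ``corr_behavior`` (log2 scale) and the change of
    ``corr_outcome``; exact for |rho| <= 1/sqrt(2), lognormal family only.
    """

    n_exp: int = 548
    n_wait: int = 557
    p_female: float = 0.748
    age_mean: float = 23.68
    age_sd: float = 10.44
    months: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    truth: dict = field(default_factory=_default_truth)
    counts: dict = field(default_factory=_default_counts)
    dropout: tuple[float, ...] = (0.0, 0.10, 0.15, 0.20)
    mar_strength: float = 0.0
    behavior_outcome_corr: float = 0.0
    corr_behavior: str = "bell"
    corr_outcome: str = "qids"
    completion_p: float = 0.73
    rewards: RewardSchedule = field(default_factory=RewardSchedule)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exp < 1 or self.n_wait < 1:
            raise ValueError("arm sizes must be >= 1")
        for name, p in (("p_female", self.p_female), ("completion_p", self.completion_p)):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if len(self.dropout) != len(self.months):
            raise ValueError("dropout needs one probability per wave")
        if any(not 0 <= q <= 1 for q in self.dropout):
            raise ValueError("dropout probabilities must lie in [0, 1]")
        if set(self.truth) != set(OUTCOME_NAMES):
            raise ValueError(f"truth must define params for {OUTCOME_NAMES}")
        if set(self.counts) != set(BEHAVIOR_NAMES):
            raise ValueError(f"counts must define models for {BEHAVIOR_NAMES}")
        if abs(self.behavior_outcome_corr) > 1 / math.sqrt(2):
            raise ValueError("behavior_outcome_corr must satisfy |rho| <= 1/sqrt(2)")
        for p in self.truth.values():
            p.validate_psd()

    @property
    def basis(self) -> TimeBasis:
        return time_basis(self.months)

    def replace(self, **kw) -> "GeneratorConfig":
        from dataclasses import replace
        return replace(self, **kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["truth"] = {k: asdict(v) for k, v in self.truth.items()}
        d["counts"] = {k: asdict(v) for k, v in self.counts.items()}
        d["rewards"] = asdict(self.rewards)
        for key in ("months", "dropout"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "truth" in d:
            d["truth"] = {k: LGCMParams(**v) for k, v in d["truth"].items()}
        if "counts" in d:
            counts = {}
            for k, v in d["counts"].items():
                v = dict(v)
                for t in ("log2_mean_exp", "log2_mean_wait"):
                    v[t] = tuple(v[t])
                counts[k] = CountModel(**v)
            d["counts"] = counts
        if "rewards" in d:
            r = dict(d["rewards"])
            r["wave_payments"] = tuple(r["wave_payments"])
            d["rewards"] = RewardSchedule(**r)
        for key in ("months", "dropout"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def default_config(**overrides) -> GeneratorConfig:
    """The study-conditions configuration, optionally with field overrides."""
    return GeneratorConfig(**overrides) if overrides else GeneratorConfig()


# --- implied-quantity helpers -------------------------------------------------

def implied_change_sd(params: LGCMParams, basis: TimeBasis) -> float:
    """SD of the latent wave-last minus wave-first change under the model.

    The change is E1 * dF + (e_last - e_first), so its variance is
    var_e1 * dF^2 + 2 var_e2 (the intercept cancels).
    """
    df = basis.loadings[-1] - basis.loadings[0]
    return math.sqrt(params.var_e1 * df**2 + 2.0 * params.var_e2)


def implied_smd(params: LGCMParams, basis: TimeBasis) -> float:
    """Change-score SMD implied by the truth: b1exp * dF / sd(change)."""
    df = basis.loadings[-1] - basis.loadings[0]
    return params.b1exp * df / implied_change_sd(params, basis)


def slope_effect_for_smd(target_smd: float, params: LGCMParams, basis: TimeBasis) -> float:
    """The slope arm effect b1exp that makes the implied change-score SMD equal the target."""
    df = basis.loadings[-1] - basis.loadings[0]
    return target_smd * implied_change_sd(params, basis) / df


# --- generation ---------------------------------------------------------------

def assign_arms(n_total: int, seed: int, p_exp: float = 0.5) -> np.ndarray:
    """Independent 1:1 (by default) randomization via a seeded Mersenne Twister.

    Returns an int array with 1 = experimental, 0 = waitlist.  Counts vary
    around n/2 across seeds, as in a true coin-flip allocation.
    """
    if n_total < 2:
        raise ValueError("need at least 2 participants")
    rng = np.random.Generator(np.random.MT19937(seed))
    return (rng.random(n_total) < p_exp).astype(int)


class TrialDataset:
    """A generated (or loaded) trial in wide form, one row per participant."""

    def __init__(self, wide: pd.DataFrame):
        missing = [c for c in WIDE_COLUMNS if c not in wide.columns]
        if missing:
            raise ValueError(f"wide table is missing columns: {missing}")
        if wide["pid"].duplicated().any():
            raise ValueError("participant ids must be unique")
        self.wide = wide.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.wide)

    @property
    def n_exp(self) -> int:
        return int((self.wide["arm"] == "exp").sum())

    @property
    def n_wait(self) -> int:
        return int((self.wide["arm"] == "wait").sum())

    def covariate_matrix(self) -> np.ndarray:
        return np.column_stack([
            (self.wide["arm"] == "exp").to_numpy(dtype=float),
            self.wide["female"].to_numpy(dtype=float),
        ])

    def outcome_matrix(self, outcome: str) -> np.ndarray:
        """(n, 4) outcome values with NaN for missing waves.

        ``bell_log2`` / ``custom_log2`` return the log2(count+1) transform of
        the behaviour counts.
        """
        if outcome in OUTCOME_NAMES:
            cols = [f"{outcome}_w{w}" for w in (1, 2, 3, 4)]
            return self.wide[cols].to_numpy(dtype=float)
        if outcome.endswith("_log2") and outcome[:-5] in BEHAVIOR_NAMES:
            stem = outcome[:-5]
            cols = [f"{stem}_w{w}" for w in (1, 2, 3, 4)]
            return log2p1(self.wide[cols].to_numpy(dtype=float))
        raise ValueError(f"unknown outcome {outcome!r}")

    def subset(self, mask) -> "TrialDataset":
        return TrialDataset(self.wide.loc[np.asarray(mask)].reset_index(drop=True))

    def to_long(self) -> pd.DataFrame:
        """One row per participant-wave, for plotting."""
        rows = []
        for w in (1, 2, 3, 4):
            block = self.wide[["pid", "arm", "female", "age"]].copy()
            block["wave"] = w
            for o in OUTCOME_NAMES:
                block[o] = self.wide[f"{o}_w{w}"]
            for b in BEHAVIOR_NAMES:
                block[b] = self.wide[f"{b}_w{w}"]
            rows.append(block)
        return pd.concat(rows, ignore_index=True).sort_values(["pid", "wave"]).reset_index(drop=True)


def _draw_counts(rng, model: CountModel, g_exp, rho, z, is_target) -> np.ndarray:
    """(n, 4) integer counts; the wave-4 log2 shock carries the built-in correlation."""
    n = len(g_exp)
    means = np.where(
        g_exp[:, None] == 1,
        np.asarray(model.log2_mean_exp)[None, :],
        np.asarray(model.log2_mean_wait)[None, :],
    )
    if model.family == "zipf":
        if is_target and rho != 0:
            raise ValueError("behavior_outcome_corr requires the lognormal count family")
        return rng.zipf(model.zipf_exponent, size=(n, 4))
    shocks = rng.standard_normal((n, 4))
    if is_target and rho != 0:
        u = rng.standard_normal(n)
        # wave-4 shock = sqrt(2) rho z + sqrt(1 - 2 rho^2) u keeps unit variance
        # and makes corr(log2 change, outcome change) exactly rho
        shocks[:, 3] = math.sqrt(2.0) * rho * z + math.sqrt(1.0 - 2.0 * rho**2) * u
    x = means + model.log2_sd * shocks
    return np.maximum(np.rint(np.exp2(x) - 1.0), 0.0).astype(np.int64)


def generate(config: GeneratorConfig, seed: int | None = None) -> TrialDataset:
    """Draw one complete synthetic trial under the configured study conditions.

    Fully reproducible given the seed (``config.seed`` unless overridden).
    Questionnaire outcomes share one dropout process per wave (a participant
    skips the whole battery); behaviour counts come from server logs and are
    never missing.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.Generator(np.random.MT19937(seed))
    basis = config.basis
    f = basis.loading_array()
    n_waves = len(f)

    n = config.n_exp + config.n_wait
    g_exp = np.concatenate([np.ones(config.n_exp, dtype=int),
                            np.zeros(config.n_wait, dtype=int)])
    female = (rng.random(n) < config.p_female).astype(int)
    age = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), 9, 82).round(1)

    latent: dict[str, np.ndarray] = {}
    zscore: dict[str, np.ndarray] = {}
    for name in OUTCOME_NAMES:
        p = config.truth[name]
        # eigh handles positive SEMIdefinite Psi (e.g. a zero-variance truth)
        re = rng.multivariate_normal(np.zeros(2), p.psi, size=n, method="eigh")
        b0 = p.b00 + p.b0exp * g_exp + p.b0female * female + re[:, 0]
        b1 = p.b10 + p.b1exp * g_exp + p.b1female * female + re[:, 1]
        resid = rng.normal(0.0, math.sqrt(p.var_e2), size=(n, n_waves)) if p.var_e2 > 0 \
            else np.zeros((n, n_waves))
        y = b0[:, None] + b1[:, None] * f[None, :] + resid
        latent[name] = y
        # standardized latent change, used to couple behaviour to outcome change
        df = f[-1] - f[0]
        sd_ch = implied_change_sd(p, basis)
        if sd_ch > 0:
            mean_ch = (p.b10 + p.b1exp * g_exp + p.b1female * female) * df
            zscore[name] = (y[:, -1] - y[:, 0] - mean_ch) / sd_ch
        else:
            zscore[name] = np.zeros(n)

    counts = {
        bname: _draw_counts(
            rng, model, g_exp, config.behavior_outcome_corr,
            zscore[config.corr_outcome], bname == config.corr_behavior,
        )
        for bname, model in config.counts.items()
    }

    # wave-wise questionnaire dropout, shared across the battery
    miss = np.zeros((n, n_waves), dtype=bool)
    ref = latent[config.corr_outcome]
    ref_sd = np.nanstd(ref) or 1.0
    for w, q in enumerate(config.dropout):
        if q <= 0:
            continue
        if config.mar_strength == 0:
            miss[:, w] = rng.random(n) < q
        else:
            logit = math.log(q / (1 - q)) if q < 1 else math.inf
            shift = config.mar_strength * (ref[:, w] - ref[:, w].mean()) / ref_sd
            prob = 1.0 / (1.0 + np.exp(-(logit + shift)))
            miss[:, w] = rng.random(n) < prob

    bonus = np.where(
        g_exp == 1,
        rng.binomial(config.rewards.n_bonus_months, config.completion_p, size=n),
        rng.binomial(config.rewards.n_bonus_months, config.rewards.waitlist_lottery_p, size=n),
    )
    payments = np.asarray(config.rewards.wave_payments)
    compensation = (~miss) @ payments + bonus * config.rewards.completion_bonus

    data = {
        "pid": np.arange(1, n + 1),
        "arm": np.where(g_exp == 1, "exp", "wait"),
        "female": female,
        "age": age,
    }
    for name in OUTCOME_NAMES:
        # outcomes stay continuous: the analysis model is Gaussian, and
        # rounding/truncating onto the instrument range would bias recovery
        y = latent[name].copy()
        y[miss] = np.nan
        for w in range(n_waves):
            data[f"{name}_w{w + 1}"] = y[:, w]
    for bname in BEHAVIOR_NAMES:
        for w in range(n_waves):
            data[f"{bname}_w{w + 1}"] = counts[bname][:, w]
    data["bonus_months"] = bonus
    data["compensation_jpy"] = compensation

    return TrialDataset(pd.DataFrame(data, columns=WIDE_COLUMNS))
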