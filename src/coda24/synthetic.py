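"""Synthetic cohorts and raw accelerometer streams with known ground truth.

The cohort generator emulates the analytic dataset of a middle-aged
population cohort stratified by urban/rural residency: each participant's
4-part 24-h composition (MVPA, LPA, ST, sleep, closed to 1440 min) is
drawn logistic-normally — a multivariate normal in pivot-ilr coordinates
with stratum-specific means — guaranteeing strictly positive parts.
Covariates follow documented marginals (57.3% female, smoking
never/former/current at 54/27/18%, ...), and the outcome is a bounded
depressive-symptom score (0-63) driven by a linear model in the ilr
coordinates and covariates.

Two outcome modes exist: ``linear_gaussian`` leaves the latent linear
predictor continuous (for exact parameter-recovery tests), and
``skewed_count`` (the default study condition) maps the standardised
latent through a Gaussian copula onto a negative-binomial marginal with
mean 5.3 and SD 6.1, clipped to [0, 63] — a right-skewed integer score
like the real instrument.

Default stratum compositional means (minutes) are urban (65, 315, 612, 448)
and rural (61, 355, 576, 448): urban residents spend relatively more time
in MVPA and ST and less in LPA, with sleep near 7.47 h in both strata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .coda import PARTS, MINUTES_PER_DAY, ilr_inverse_values, pivot_basis, pivot_ilr_values
from .regression import PART_COLUMNS

#: Stratum compositional means in minutes/day, order (MVPA, LPA, ST, sleep).
DEFAULT_STRATUM_MEANS: dict[str, tuple[float, ...]] = {
    "urban": (65.0, 315.0, 612.0, 448.0),
    "rural": (61.0, 355.0, 576.0, 448.0),
}

#: Between-person covariance of the pivot-ilr coordinates.
DEFAULT_ILR_COV = np.array([
    [0.20, 0.02, 0.00],
    [0.02, 0.06, 0.01],
    [0.00, 0.01, 0.04],
])

#: Ground-truth per-behaviour effects: the first-pivot-coordinate
#: coefficient when that behaviour leads (outcome units per unit ilr).
#: They sum to zero, as any set of pivot betas must (they are scaled clr
#: coefficients, which are centred).
DEFAULT_BEHAVIOUR_BETAS: dict[str, float] = {
    "MVPA": -0.20, "LPA": 0.68, "ST": 1.29, "sleep": -1.77,
}

#: Covariate effects on the latent outcome scale.
DEFAULT_GAMMA: dict[str, float] = {
    "sex[female]": 0.8,
    "education[vocational]": -0.3, "education[tertiary]": -0.8,
    "employment[unemployed]": 2.0, "employment[other]": 0.5,
    "marital[divorced]": 1.5, "marital[unmarried]": 1.0,
    "smoking[former]": 0.3, "smoking[current]": 1.2,
    "season[winter]": 0.3,
    "work_strenuousness": 0.10, "harm_avoidance": 0.45,
    "alcohol": 0.02, "waist": 0.02,
}

# Negative-binomial marginal for the skewed count outcome: mean 5.3, SD 6.1
# => size r = mu^2 / (var - mu), prob p = r / (r + mu).
_NB_MEAN, _NB_SD = 5.3, 6.1
_NB_R = _NB_MEAN**2 / (_NB_SD**2 - _NB_MEAN)
_NB_P = _NB_R / (_NB_R + _NB_MEAN)
OUTCOME_MAX = 63


def behaviour_betas_to_pivot(betas: dict[str, float],
                             parts_order: tuple[str, ...] = PARTS) -> np.ndarray:
    """Per-behaviour first-pivot betas to the storage-order ilr coefficient
    vector.  beta_b = (2/sqrt(3)) * a_b with a the centred clr coefficients,
    so the betas must sum to ~0."""
    b = np.array([betas[p] for p in parts_order])
    if abs(b.sum()) > 1e-8 * max(1.0, np.abs(b).max()):
        raise ValueError("per-behaviour pivot betas must sum to zero")
    a = b * np.sqrt(3.0) / 2.0  # clr coefficients
    return pivot_basis(len(parts_order)).T @ a


@dataclass(frozen=True)
class GeneratorConfig:
    n_urban: int = 2364
    n_rural: int = 1134
    stratum_means_min: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_STRATUM_MEANS))
    ilr_cov: np.ndarray = field(default_factory=lambda: DEFAULT_ILR_COV.copy())
    behaviour_betas: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BEHAVIOUR_BETAS))
    gamma: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GAMMA))
    sigma: float = 4.0
    outcome_mode: str = "skewed_count"
    intercept: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_urban < 1 or self.n_rural < 1:
            raise ValueError("need n >= 1 per stratum")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        cov = np.asarray(self.ilr_cov, dtype=float)
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ValueError("ilr covariance must be positive definite")
        if self.outcome_mode not in ("linear_gaussian", "skewed_count"):
            raise ValueError(f"unknown outcome_mode {self.outcome_mode!r}")

    @property
    def ilr_means(self) -> dict[str, np.ndarray]:
        return {s: pivot_ilr_values(np.asarray(m, dtype=float))
                for s, m in self.stratum_means_min.items()}

    @property
    def true_beta(self) -> np.ndarray:
        """Ground-truth coefficient vector on storage-order ilr coordinates."""
        return behaviour_betas_to_pivot(self.behaviour_betas)


def with_seed(cfg: GeneratorConfig, seed: int) -> GeneratorConfig:
    return replace(cfg, seed=int(seed))


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    def cat(levels, probs):
        p = np.asarray(probs, dtype=float)
        return rng.choice(levels, size=n, p=p / p.sum())

    return pd.DataFrame({
        "sex": cat(["male", "female"], [0.427, 0.573]),
        "education": cat(["comprehensive", "vocational", "tertiary"],
                         [0.034, 0.727, 0.239]),
        "employment": cat(["employed", "unemployed", "other"],
                          [0.820, 0.044, 0.120]),
        "work_strenuousness": np.clip(np.round(rng.normal(4.0, 3.0, n)), 0, 9),
        "marital": cat(["married", "divorced", "unmarried"],
                       [0.792, 0.099, 0.105]),
        "harm_avoidance": np.clip(rng.normal(13.1, 6.3, n), 0.0, None),
        "alcohol": rng.gamma(shape=(10.5 / 17.0) ** 2,
                             scale=17.0**2 / 10.5, size=n),
        "smoking": cat(["never", "former", "current"], [0.539, 0.272, 0.180]),
        "waist": np.clip(rng.normal(91.3, 13.5, n), 55.0, None),
        "season": cat(["summer", "winter"], [0.541, 0.459]),
    })


def _covariate_effect(cov: pd.DataFrame, gamma: dict[str, float]) -> np.ndarray:
    eff = np.zeros(len(cov))
    for term, g in gamma.items():
        if "[" in term:
            name, level = term[:-1].split("[")
            eff += g * (cov[name] == level).to_numpy(dtype=float)
        else:
            eff += g * cov[term].to_numpy(dtype=float)
    return eff


def generate_cohort(cfg: GeneratorConfig) -> pd.DataFrame:
    """Draw a full two-stratum cohort table; deterministic given cfg.seed.

    Columns: id, stratum, mvpa_min, lpa_min, st_min, sleep_min, the ten
    covariates, and ``bdi`` (the outcome).  In ``skewed_count`` mode the
    latent linear predictor is standardised and pushed through the
    negative-binomial quantile function, so the marginal outcome mean and
    SD match the configured instrument regardless of effect sizes.
    """
    rng = np.random.default_rng(cfg.seed)
    frames = []
    for stratum, n in (("urban", cfg.n_urban), ("rural", cfg.n_rural)):
        Z = rng.multivariate_normal(cfg.ilr_means[stratum],
                                    np.asarray(cfg.ilr_cov, dtype=float), size=n)
        comp = ilr_inverse_values(Z, MINUTES_PER_DAY)
        cov = _draw_covariates(n, rng)
        latent = (cfg.intercept + Z @ cfg.true_beta
                  + _covariate_effect(cov, cfg.gamma)
                  + rng.normal(0.0, cfg.sigma, n))
        df = pd.DataFrame({
            "stratum": stratum,
            **{PART_COLUMNS[b]: comp[:, i] for i, b in enumerate(PARTS)},
        })
        frames.append(pd.concat([df, cov], axis=1).assign(_latent=latent))
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "id", np.arange(1, len(out) + 1))

    latent = out.pop("_latent").to_numpy()
    if cfg.outcome_mode == "linear_gaussian":
        out["bdi"] = latent
    else:
        z = (latent - latent.mean()) / latent.std()
        u = np.clip(stats.norm.cdf(z), 1e-12, 1.0 - 1e-12)
        out["bdi"] = np.clip(stats.nbinom.ppf(u, _NB_R, _NB_P), 0, OUTCOME_MAX)

    if cfg.missing_rate > 0:
        for col in ("work_strenuousness", "harm_avoidance", "smoking", "waist"):
            mask = rng.random(len(out)) < cfg.missing_rate
            out.loc[mask, col] = np.nan
    return out


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.6f")


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)


# --- raw accelerometer stream generation ------------------------------------

#: Per-behaviour signal recipe: (target MAD in g, gravity direction).
_UPRIGHT = np.array([0.0, 0.0, 1.0])
_LYING = np.array([1.0, 0.0, 0.0])
SIGNAL_RECIPES: dict[str, tuple[float, np.ndarray]] = {
    # worn-but-still bouts carry small physiological movement (breathing,
    # fidgeting) that keeps them above non-wear stillness thresholds
    "sedentary": (0.010, _LYING),
    "standing": (0.010, _UPRIGHT),
    "LPA": (0.050, _UPRIGHT),
    "MVPA": (0.300, _UPRIGHT),
    "nonwear": (0.0, _UPRIGHT),
}


def generate_raw_stream(
    schedule: list[tuple[str, float]],
    rate: float = 100.0,
    seed: int = 0,
    t0: float = 8 * 3600.0,
) -> pd.DataFrame:
    """Tri-axial samples realising a bout schedule [(behaviour, minutes), ...].

    Each bout's resultant oscillates around 1 g with amplitude equal to the
    behaviour's target MAD (an alternating-sign waveform has MAD exactly
    equal to its amplitude), oriented along the behaviour's gravity
    direction; non-wear bouts are perfectly still at 1 g.  Sampling starts
    at clock time ``t0`` seconds.
    """
    rng = np.random.default_rng(seed)
    ts, axs = [], []
    t = float(t0)
    dt = 1.0 / rate
    for behaviour, minutes in schedule:
        if behaviour not in SIGNAL_RECIPES:
            raise ValueError(f"unknown behaviour {behaviour!r}")
        if minutes <= 0:
            raise ValueError("bout duration must be positive")
        mad, direction = SIGNAL_RECIPES[behaviour]
        n = int(round(minutes * 60.0 * rate))
        sign = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        mag = 1.0 + mad * sign
        if mad > 0:
            # small orientation jitter; does not change the resultant
            wobble = rng.normal(0.0, 0.01, size=(n, 3))
            dirs = direction + wobble
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        else:
            dirs = np.tile(direction, (n, 1))
        axs.append(dirs * mag[:, None])
        ts.append(t + dt * np.arange(n))
        t += n * dt
    if not ts:
        return pd.DataFrame(columns=["t", "ax", "ay", "az"])
    A = np.vstack(axs)
    return pd.DataFrame({"t": np.concatenate(ts),
                         "ax": A[:, 0], "ay": A[:, 1], "az": A[:, 2]})
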