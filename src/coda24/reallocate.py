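"""Pairwise isotemporal-substitution predictions on the 24-h simplex.

Moving t minutes from one behaviour to another at a reference composition
(the stratum's compositional mean) changes the ilr coordinates by
d = z(m') - z(m); under the fitted linear model the expected outcome
changes by delta = beta' d, with Wald standard error sqrt(d' V d) from the
ilr-block coefficient covariance (covariate terms cancel between the two
predictions).  Results are expressed as percentage change relative to a
baseline outcome level, with the baseline treated as a fixed constant.

The grid covers all 12 ordered behaviour pairs at 10-60 min in 10-min
steps, capped at 30 min whenever MVPA is involved (reallocations beyond
the sample's mean MVPA would extrapolate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coda import Composition, pivot_ilr_values
from .regression import IlrModelFit


class InfeasibleReallocationError(ValueError):
    pass


@dataclass(frozen=True)
class GridSpec:
    minutes: tuple[int, ...] = (10, 20, 30, 40, 50, 60)
    mvpa_cap: int = 30

    def steps_for(self, from_b: str, to_b: str) -> tuple[int, ...]:
        if "MVPA" in (from_b, to_b):
            return tuple(t for t in self.minutes if t <= self.mvpa_cap)
        return self.minutes


@dataclass
class ReallocationEstimate:
    stratum: str
    from_behaviour: str
    to_behaviour: str
    minutes: int
    pct_change: float
    ci_low: float
    ci_high: float
    feasible: bool = True


def reallocate(m: Composition, from_b: str, to_b: str, t: float) -> Composition:
    """Move ``t`` minutes from one behaviour to another; total is conserved."""
    if from_b == to_b:
        raise ValueError("from and to behaviours must differ")
    if not 0 < t < m[from_b]:
        raise InfeasibleReallocationError(
            f"cannot move {t} min out of {from_b} ({m[from_b]:.1f} min available)"
        )
    values = m.values.copy()
    values[m.names.index(from_b)] -= t
    values[m.names.index(to_b)] += t
    return Composition(m.names, values, m.kappa)


def predict_percent_change(
    fit: IlrModelFit,
    m: Composition,
    from_b: str,
    to_b: str,
    t: float,
    baseline_outcome: float,
    stratum: str = "",
    level: float = 0.95,
) -> ReallocationEstimate:
    """Percent change in the expected outcome for one minute transfer.

    The composition is evaluated in the fit's part order, so any fit (any
    rotation) gives the same prediction.  CI is Wald with t critical values
    at the fit's residual df; the baseline is held fixed.
    """
    if baseline_outcome <= 0:
        raise ValueError("baseline_outcome must be positive")
    m = m.reorder(fit.parts_order)
    m2 = reallocate(m, from_b, to_b, t)
    d = pivot_ilr_values(m2.values) - pivot_ilr_values(m.values)
    delta = float(fit.ilr_beta @ d)
    se = float(np.sqrt(d @ fit.ilr_cov @ d))
    tcrit = stats.t.ppf(1.0 - (1.0 - level) / 2.0, fit.df_resid)
    scale = 100.0 / baseline_outcome
    return ReallocationEstimate(
        stratum=stratum, from_behaviour=from_b, to_behaviour=to_b, minutes=int(t),
        pct_change=scale * delta,
        ci_low=scale * (delta - tcrit * se),
        ci_high=scale * (delta + tcrit * se),
    )


def reallocation_grid(
    fit: IlrModelFit,
    m: Composition,
    baseline_outcome: float,
    grid_spec: GridSpec = GridSpec(),
    stratum: str = "",
    level: float = 0.95,
) -> list[ReallocationEstimate]:
    """Complete ordered grid of pairwise reallocation estimates.

    Cells where the source behaviour holds fewer minutes than the transfer
    are flagged infeasible (NaN estimates) rather than dropped, so the grid
    shape is invariant to the reference composition.
    """
    out: list[ReallocationEstimate] = []
    for from_b in fit.parts_order:
        for to_b in fit.parts_order:
            if from_b == to_b:
                continue
            for t in grid_spec.steps_for(from_b, to_b):
                try:
                    out.append(predict_percent_change(
                        fit, m, from_b, to_b, t, baseline_outcome, stratum, level))
                except InfeasibleReallocationError:
                    out.append(ReallocationEstimate(
                        stratum=stratum, from_behaviour=from_b, to_behaviour=to_b,
                        minutes=int(t), pct_change=np.nan, ci_low=np.nan,
                        ci_high=np.nan, feasible=False))
    return out


def grid_frame(estimates: list[ReallocationEstimate]) -> pd.DataFrame:
    return pd.DataFrame([
        {"stratum": e.stratum, "from": e.from_behaviour, "to": e.to_behaviour,
         "minutes": e.minutes, "pct": e.pct_change, "ci_low": e.ci_low,
         "ci_high": e.ci_high, "feasible": e.feasible}
        for e in estimates
    ])


def plot_reallocation_grid(df: pd.DataFrame, path: str) -> None:
    """12-panel figure of percent change (with CI band) against minutes,
    one panel per ordered behaviour pair, one line per stratum."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pairs = df[["from", "to"]].drop_duplicates().itertuples(index=False)
    pairs = list(pairs)
    fig, axes = plt.subplots(4, 3, figsize=(11, 12), sharex=True)
    for ax, (fb, tb) in zip(axes.ravel(), pairs):
        sub = df[(df["from"] == fb) & (df["to"] == tb) & df["feasible"]]
        for stratum, g in sub.groupby("stratum"):
            g = g.sort_values("minutes")
            ax.plot(g["minutes"], g["pct"], marker="o", label=stratum)
            ax.fill_between(g["minutes"], g["ci_low"], g["ci_high"], alpha=0.15)
        ax.axhline(0, color="grey", lw=0.7)
        ax.set_title(f"{fb} → {tb}", fontsize=9)
    axes[0, 0].legend(fontsize=7)
    for ax in axes[-1]:
        ax.set_xlabel("minutes reallocated")
    for ax in axes[:, 0]:
        ax.set_ylabel("% change in outcome")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
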