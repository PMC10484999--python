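"""Dose-response and drug-combination mathematics.

Four-parameter logistic (4PL) fitting of viability curves on the
inhibitory-effect scale, closed-form EC-f extraction (EC50, EC33, ...),
Bliss-independence synergy scoring of combination grids, and the
viability-reduction screen filter.

The Bliss independence null says two non-interacting drugs with
inhibitory-effect fractions e1 and e2 combine to ``e1 + e2 - e1*e2``;
the Bliss score of an observation is the excess over that expectation
(positive = synergy, negative = antagonism).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseCurve",
    "FourPLFit",
    "CombinationGrid",
    "four_pl",
    "bliss_score",
    "fit_4pl",
    "effect_concentration",
    "screen_hits",
    "bliss_grid",
    "load_dose_response",
]


def four_pl(x, bottom: float, top: float, ec50: float, hill: float):
    """4PL inhibitory effect at concentration(s) ``x``:

    effect(x) = bottom + (top - bottom) / (1 + (ec50 / x)^hill)
    """
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / x) ** hill)


@dataclass
class DoseResponseCurve:
    """Replicated viability fractions measured over increasing doses (nM)."""

    concentrations: np.ndarray    # strictly increasing, positive, nM
    viability: np.ndarray         # replicates x concentrations, in [0, 1.5]
    drug: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viability = np.atleast_2d(np.asarray(self.viability, dtype=float))
        c = self.concentrations
        if c.ndim != 1 or (c <= 0).any():
            raise ValueError("concentrations must be a 1-D positive vector")
        if not (np.diff(c) > 0).all():
            raise ValueError("concentrations must be strictly increasing")
        if self.viability.shape[1] != c.size:
            raise ValueError("viability columns must match concentration count")
        if self.viability.min() < 0 or self.viability.max() > 1.5:
            raise ValueError("viability fractions must lie in [0, 1.5]")

    @property
    def n_replicates(self) -> int:
        return self.viability.shape[0]

    def effects(self):
        """Inhibitory effects (1 - viability) per replicate, clipped to [0, 1]."""
        return np.clip(1.0 - self.viability, 0.0, 1.0)


@dataclass
class FourPLFit:
    """Fitted 4PL parameters on the inhibitory-effect scale."""

    bottom: float
    top: float
    ec50_nM: float
    hill: float
    residual_sse: float
    converged: bool = True
    degenerate: bool = False
    message: str = ""

    def effect_at(self, x):
        return four_pl(x, self.bottom, self.top, self.ec50_nM, self.hill)


@dataclass
class CombinationGrid:
    """Inhibitory-effect vectors of two drugs and their observed combination."""

    effects_drug1: np.ndarray
    effects_drug2: np.ndarray
    observed_combined: np.ndarray
    bliss_excess: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.effects_drug1 = np.asarray(self.effects_drug1, dtype=float)
        self.effects_drug2 = np.asarray(self.effects_drug2, dtype=float)
        self.observed_combined = np.asarray(self.observed_combined, dtype=float)
        expected_shape = (self.effects_drug1.size, self.effects_drug2.size)
        if self.observed_combined.shape != expected_shape:
            raise ValueError(
                f"observed matrix shape {self.observed_combined.shape} does not match "
                f"effect vectors {expected_shape}"
            )

    @property
    def mean_excess(self) -> float:
        if self.bliss_excess is None:
            raise ValueError("bliss_excess not computed yet; call bliss_grid")
        return float(np.mean(self.bliss_excess))


def bliss_score(e1: float, e2: float, observed: float) -> float:
    """Bliss excess of an observed combined inhibitory effect.

    Returns observed - (e1 + e2 - e1*e2).  All arguments are effect
    fractions in [0, 1].
    """
    for name, v in (("e1", e1), ("e2", e2), ("observed", observed)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be an effect fraction in [0, 1], got {v}")
    expected = e1 + e2 - e1 * e2
    return observed - expected


def bliss_grid(grid: CombinationGrid) -> CombinationGrid:
    """Fill the Bliss-excess matrix of a combination grid elementwise."""
    e1 = grid.effects_drug1
    e2 = grid.effects_drug2
    for name, e in (("effects_drug1", e1), ("effects_drug2", e2)):
        if e.min() < 0 or e.max() > 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    obs = grid.observed_combined
    if obs.min() < 0 or obs.max() > 1:
        raise ValueError("observed_combined must lie in [0, 1]")
    expected = e1[:, None] + e2[None, :] - e1[:, None] * e2[None, :]
    grid.bliss_excess = obs - expected
    return grid


def fit_4pl(curve: DoseResponseCurve, min_span: float = 0.1) -> FourPLFit:
    """Least-squares 4PL fit of a dose-response curve on the effect scale.

    All replicate points are fitted jointly.  Initialization is
    multi-start over a grid of Hill slopes and EC50 guesses spanning the
    dose range; the best SSE wins, so the fit is deterministic given the
    data.  A fitted span (top - bottom) below ``min_span`` means the curve
    carries no usable dose signal and is flagged degenerate (no EC50
    should be trusted).
    """
    x = curve.concentrations
    if x.size < 4:
        raise ValueError("4PL fitting needs at least 4 distinct concentrations")
    effects = curve.effects()
    x_rep = np.tile(x, curve.n_replicates)
    y = effects.ravel()

    def residuals(theta):
        bottom, top, log_ec50, log_hill = theta
        return four_pl(x_rep, bottom, top, np.exp(log_ec50), np.exp(log_hill)) - y

    lo = [-0.5, 0.0, np.log(x.min() / 100.0), np.log(0.05)]
    hi = [1.0, 1.5, np.log(x.max() * 100.0), np.log(10.0)]
    best = None
    for hill0 in (0.5, 1.0, 2.0, 4.0):
        for ec0 in np.geomspace(x.min(), x.max(), 4):
            theta0 = [max(lo[0], min(hi[0], y.min())),
                      max(lo[1], min(hi[1], y.max())),
                      np.log(ec0), np.log(hill0)]
            try:
                sol = least_squares(residuals, theta0, bounds=(lo, hi), method="trf")
            except Exception:  # pragma: no cover - defensive
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        return FourPLFit(0, 0, 1.0, 1.0, np.inf, converged=False,
                         degenerate=True, message="all starts failed")
    bottom, top, log_ec50, log_hill = best.x
    sse = float(2 * best.cost)
    fit = FourPLFit(
        bottom=float(bottom),
        top=float(top),
        ec50_nM=float(np.exp(log_ec50)),
        hill=float(np.exp(log_hill)),
        residual_sse=sse,
        converged=bool(best.success),
    )
    if top - bottom < min_span:
        fit.degenerate = True
        fit.message = f"fitted span {top - bottom:.3g} below {min_span}; EC50 unidentifiable"
    return fit


def effect_concentration(fit: FourPLFit, percent_effect: float) -> float:
    """Closed-form EC-f: concentration giving ``percent_effect``% of the span.

    EC_f = ec50 * (p / (1 - p))^(1/hill) with p = percent_effect / 100 on
    the bottom -> top span; EC50 is recovered exactly at 50.
    """
    if not 0.0 < percent_effect < 100.0:
        raise ValueError("percent_effect must be strictly between 0 and 100")
    if fit.degenerate or not fit.converged:
        raise ValueError("cannot invert a degenerate or non-converged fit")
    p = percent_effect / 100.0
    return float(fit.ec50_nM * (p / (1.0 - p)) ** (1.0 / fit.hill))


def screen_hits(viability_reduction: dict, cutoff_percent: float = 10.0):
    """Inhibitors whose viability reduction meets the cutoff (inclusive).

    ``viability_reduction`` maps inhibitor name -> percent reduction versus
    vehicle control.  Returns hits sorted by reduction, largest first
    (name breaks ties for determinism).
    """
    for name, v in viability_reduction.items():
        if not np.isfinite(v):
            raise ValueError(f"non-finite reduction for {name!r}")
    hits = [(name, v) for name, v in viability_reduction.items() if v >= cutoff_percent]
    hits.sort(key=lambda kv: (-kv[1], kv[0]))
    return [name for name, _ in hits]


def load_dose_response(path, drug: str | None = None) -> DoseResponseCurve:
    """Read a long-format CSV (drug, concentration_nM, replicate, viability)."""
    df = pd.read_csv(path)
    required = {"drug", "concentration_nM", "replicate", "viability"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dose-response CSV missing columns: {sorted(missing)}")
    if drug is not None:
        df = df[df["drug"] == drug]
        if df.empty:
            raise ValueError(f"no rows for drug {drug!r}")
    elif df["drug"].nunique() > 1:
        raise ValueError("CSV holds several drugs; pass drug=...")
    wide = df.pivot(index="replicate", columns="concentration_nM", values="viability")
    wide = wide.sort_index(axis=1)
    return DoseResponseCurve(
        concentrations=wide.columns.to_numpy(dtype=float),
        viability=wide.to_numpy(dtype=float),
        drug=str(df["drug"].iloc[0]),
    )
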