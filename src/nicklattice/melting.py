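"""Gel quantification and melting-curve analysis.

Survival rates are defined gel-side: the target-band intensity of a
sample incubated at temperature ``T`` is normalized by the intensity of
an untreated (4 °C) control band, giving ``S(T)``; yields are deduced by
linear intensity–mass correlation against a standard band of known mass
(e.g. the 1500-bp band of a 1-kb ladder).

Melting curves fit the replicate survival points to a Boltzmann sigmoid

    S(T) = S_bot + (S_top - S_bot) / (1 + exp((T - T_half) / w))

or, for two-stage melting (e.g. a lattice whose 6-bp stems denature well
before its 13-bp roots), a double Boltzmann

    S(T) = S_bot + (S_top - S_bot) * [ phi / (1 + exp((T - T1)/w1))
                                     + (1-phi) / (1 + exp((T - T2)/w2)) ]

with ``T1 < T2`` enforced by parameterizing the second transition as an
offset.  The melting temperature Tm is defined as the incubation
temperature at which the *fitted* curve crosses a survival rate of 0.5 —
not the inflection parameter; the two differ whenever the plateaus are
not exactly {0, 1}.  Fits use raw replicate points and unweighted least
squares; replicate means are for display only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import FitError, TmUndefinedError

__all__ = [
    "SurvivalDataset",
    "MeltFit",
    "boltzmann",
    "double_boltzmann",
    "yield_from_standard",
    "survival_rates",
    "fit_boltzmann",
    "fit_double_boltzmann",
    "delta_tm",
    "compare_fits",
]


@dataclass
class SurvivalDataset:
    """Replicate survival rates vs incubation temperature.

    ``table`` columns: temperature_C, replicate, survival.  Values may
    exceed 1 (densitometry noise) and are never clipped.
    """

    table: pd.DataFrame
    control: str = "untreated sample stored at 4 C"

    def __post_init__(self) -> None:
        required = {"temperature_C", "replicate", "survival"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"survival table missing columns {sorted(missing)}")

    @property
    def temperatures(self) -> np.ndarray:
        return np.sort(self.table.temperature_C.unique())

    @property
    def n_replicates(self) -> int:
        return int(self.table.replicate.nunique())

    def means(self) -> pd.DataFrame:
        return (
            self.table.groupby("temperature_C", as_index=False)
            .agg(survival_mean=("survival", "mean"), survival_sd=("survival", "std"))
        )


@dataclass
class MeltFit:
    """A fitted melting curve and its Tm (fitted S = 0.5 crossing)."""

    model: str
    params: dict[str, float]
    tm: float
    rss: float
    n_obs: int
    converged: bool = True

    @property
    def n_params(self) -> int:
        return len(self.params)

    def aic(self) -> float:
        return self.n_obs * float(np.log(self.rss / self.n_obs)) + 2 * self.n_params

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        p = self.params
        if self.model == "single":
            return boltzmann(t, p["s_bottom"], p["s_top"], p["t_half"], p["w"])
        return double_boltzmann(
            t, p["s_bottom"], p["s_top"], p["phi"], p["t1"], p["t2"], p["w1"], p["w2"]
        )


def boltzmann(t, s_bottom, s_top, t_half, w):
    """Descending Boltzmann sigmoid: S_top at low T, S_bottom at high T."""
    t = np.asarray(t, dtype=float)
    return s_bottom + (s_top - s_bottom) / (1.0 + np.exp((t - t_half) / w))


def double_boltzmann(t, s_bottom, s_top, phi, t1, t2, w1, w2):
    """Two-transition Boltzmann mixture with mixing fraction ``phi``."""
    t = np.asarray(t, dtype=float)
    stage1 = phi / (1.0 + np.exp((t - t1) / w1))
    stage2 = (1.0 - phi) / (1.0 + np.exp((t - t2) / w2))
    return s_bottom + (s_top - s_bottom) * (stage1 + stage2)


# ---------------------------------------------------------------------------
# Gel quantification
# ---------------------------------------------------------------------------


def yield_from_standard(
    bands: pd.DataFrame,
    target_lane,
    target_band,
    input_mass: float | None = None,
) -> dict[str, float]:
    """Deduce a target band's mass from the standard band's intensity–mass ratio.

    ``bands`` columns: lane, band, intensity, role, known_mass.  Exactly
    one row must have role ``standard`` with ``known_mass > 0``; then
    ``mass = intensity_target * known_mass / intensity_standard`` and,
    when the loaded input mass is supplied, ``yield = mass / input_mass``.
    """
    std = bands[bands.role == "standard"]
    if len(std) != 1:
        raise ValueError(f"expected exactly one standard band, found {len(std)}")
    std = std.iloc[0]
    if not std.known_mass > 0:
        raise ValueError("standard band needs known_mass > 0")
    if std.intensity <= 0:
        raise ZeroDivisionError("standard band intensity must be positive")
    row = bands[(bands.lane == target_lane) & (bands.band == target_band)]
    if len(row) != 1:
        raise KeyError(f"target band ({target_lane}, {target_band}) not found uniquely")
    mass = float(row.iloc[0].intensity) * float(std.known_mass) / float(std.intensity)
    out = {"mass": mass}
    if input_mass is not None:
        out["yield"] = mass / input_mass
    return out


def survival_rates(bands: pd.DataFrame, control_band="control") -> SurvivalDataset:
    """Normalize per-temperature target bands by each replicate's control band.

    ``bands`` columns: lane, band, intensity, role plus temperature_C and
    replicate for target rows.  For every replicate,
    ``S(T) = I_target(T) / I_control``; values are not clipped.
    """
    out = []
    for rep, grp in bands.groupby("replicate"):
        ctrl = grp[grp.role == "control"]
        if len(ctrl) != 1:
            raise ValueError(f"replicate {rep}: expected one control band, found {len(ctrl)}")
        c = float(ctrl.iloc[0].intensity)
        if c <= 0:
            raise ZeroDivisionError(f"replicate {rep}: control intensity must be positive")
        for _, row in grp[grp.role == "target"].iterrows():
            out.append(
                {
                    "temperature_C": float(row.temperature_C),
                    "replicate": rep,
                    "survival": float(row.intensity) / c,
                }
            )
    return SurvivalDataset(pd.DataFrame(out))


# ---------------------------------------------------------------------------
# Boltzmann fits
# ---------------------------------------------------------------------------


def _as_points(data) -> tuple[np.ndarray, np.ndarray]:
    table = data.table if isinstance(data, SurvivalDataset) else data
    t = table.temperature_C.to_numpy(dtype=float)
    s = table.survival.to_numpy(dtype=float)
    return t, s


def _tm_from_curve(fit_fn, lo: float, hi: float) -> float:
    """Locate the 0.5 crossing of a fitted monotone-by-parts curve."""
    grid = np.linspace(lo - 20.0, hi + 20.0, 2001)
    vals = fit_fn(grid) - 0.5
    sign = np.sign(vals)
    crossings = np.nonzero(np.diff(sign) != 0)[0]
    if len(crossings) == 0:
        raise TmUndefinedError("fitted curve never crosses survival 0.5")
    i = crossings[0]
    return float(optimize.brentq(lambda x: fit_fn(np.array([x]))[0] - 0.5, grid[i], grid[i + 1]))


def fit_boltzmann(data) -> MeltFit:
    """Least-squares single-Boltzmann fit of replicate survival points.

    Initializer: plateaus at the extreme replicate means, ``T_half`` at
    the temperature nearest the means' 0.5 crossing, ``w`` at a tenth of
    the temperature span.  Deterministic given the data.
    """
    t, s = _as_points(data)
    temps = np.unique(t)
    if len(temps) < 4:
        raise FitError("single-Boltzmann fit needs >= 4 distinct temperatures")
    if np.allclose(s, s[0]):
        raise FitError("survival data are constant; nothing to fit")
    means = np.array([s[t == ti].mean() for ti in temps])
    s_top0, s_bot0 = float(means.max()), float(means.min())
    t_half0 = float(temps[np.argmin(np.abs(means - 0.5))])
    w0 = max((t.max() - t.min()) / 10.0, 0.5)
    try:
        popt, _ = optimize.curve_fit(
            boltzmann,
            t,
            s,
            p0=[s_bot0, s_top0, t_half0, w0],
            bounds=([-np.inf, -np.inf, t.min() - 50, 1e-3], [np.inf, np.inf, t.max() + 50, np.inf]),
            maxfev=20_000,
        )
    except RuntimeError as exc:
        raise FitError(f"single-Boltzmann fit did not converge: {exc}") from exc
    s_bot, s_top, t_half, w = map(float, popt)
    params = {"s_bottom": s_bot, "s_top": s_top, "t_half": t_half, "w": w}
    fit = MeltFit("single", params, tm=np.nan, rss=float(np.sum((boltzmann(t, *popt) - s) ** 2)), n_obs=len(s))
    fit.tm = _tm_from_curve(fit.predict, float(t.min()), float(t.max()))
    return fit


def _double_init(t: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    """Seed the two transition temperatures at the steepest descents of the
    smoothed replicate-mean curve."""
    temps = np.unique(t)
    means = np.array([s[t == ti].mean() for ti in temps])
    if len(temps) >= 5:
        kernel = np.array([0.25, 0.5, 0.25])
        means = np.convolve(np.pad(means, 1, mode="edge"), kernel, mode="valid")
    grad = np.gradient(means, temps)
    order = np.argsort(grad)  # most negative first
    t1 = float(temps[order[0]])
    span = temps.max() - temps.min()
    for idx in order[1:]:
        if abs(float(temps[idx]) - t1) >= span / 5:
            t2 = float(temps[idx])
            break
    else:
        t2 = t1 + span / 3
    return (t1, t2) if t1 < t2 else (t2, t1)


def fit_double_boltzmann(data) -> MeltFit:
    """Least-squares double-Boltzmann fit; ``T1 < T2`` by construction."""
    t, s = _as_points(data)
    temps = np.unique(t)
    if len(temps) < 6:
        raise FitError("double-Boltzmann fit needs >= 6 distinct temperatures")
    if np.allclose(s, s[0]):
        raise FitError("survival data are constant; nothing to fit")
    means = np.array([s[t == ti].mean() for ti in temps])
    t1_0, t2_0 = _double_init(t, s)
    w0 = max((t.max() - t.min()) / 20.0, 0.5)

    def model(tt, s_bot, s_top, phi, t1, dt, w1, w2):
        return double_boltzmann(tt, s_bot, s_top, phi, t1, t1 + dt, w1, w2)

    p0 = [float(means.min()), float(means.max()), 0.5, t1_0, max(t2_0 - t1_0, 1.0), w0, w0]
    try:
        popt, _ = optimize.curve_fit(
            model,
            t,
            s,
            p0=p0,
            bounds=(
                [-np.inf, -np.inf, 0.0, t.min() - 50, 0.1, 1e-3, 1e-3],
                [np.inf, np.inf, 1.0, t.max() + 50, 200.0, np.inf, np.inf],
            ),
            maxfev=40_000,
        )
    except RuntimeError as exc:
        raise FitError(f"double-Boltzmann fit did not converge: {exc}") from exc
    s_bot, s_top, phi, t1, dt, w1, w2 = map(float, popt)
    params = {
        "s_bottom": s_bot,
        "s_top": s_top,
        "phi": phi,
        "t1": t1,
        "t2": t1 + dt,
        "w1": w1,
        "w2": w2,
    }
    rss = float(np.sum((model(t, *popt) - s) ** 2))
    fit = MeltFit("double", params, tm=np.nan, rss=rss, n_obs=len(s))
    fit.tm = _tm_from_curve(fit.predict, float(t.min()), float(t.max()))
    return fit


def delta_tm(fit_ligated: MeltFit, fit_unligated: MeltFit) -> float:
    """Tm increment after ligation: ligated minus unligated (°C)."""
    for f in (fit_ligated, fit_unligated):
        if not np.isfinite(f.tm):
            raise TmUndefinedError("delta_tm requires both fits to have a defined Tm")
    return float(fit_ligated.tm - fit_unligated.tm)


def compare_fits(single: MeltFit, double: MeltFit) -> dict:
    """Advisory residual-based comparison (AIC); the caller chooses."""
    return {
        "aic_single": single.aic(),
        "aic_double": double.aic(),
        "preferred": "double" if double.aic() < single.aic() else "single",
    }
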