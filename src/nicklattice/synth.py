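"""Synthetic-data generators for closed-loop recovery tests.

The wet-lab inputs of the analysis pipeline — triplicate survival-rate
curves from thermal denaturation series and gel band-intensity tables —
are emulated here from declared ground truth, so every analysis stage can
be tested for parameter recovery without any downloads.

Noise model (conventional densitometry choices): additive Gaussian noise
on survival rates (default sd 0.05, matching the scale of triplicate
scatter; values are not clipped, so rates slightly above 1 occur as they
do on gels) and multiplicative lognormal noise on band intensities
(default sd 0.1), with intensity strictly linear in loaded mass at zero
noise.  Default temperature grid 30–95 °C in 3 °C steps, inside the
study's incubation range; the study's per-sample windows (35–75 °C
unligated, 55–95 °C ligated) are available as presets.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .builtin import BUILTIN_DESIGNS, BUILTIN_MASKS
from .melting import SurvivalDataset, boltzmann, double_boltzmann

__all__ = [
    "GroundTruth",
    "gen_survival_dataset",
    "gen_band_table",
    "gen_fixture_designs",
    "TEMPERATURE_GRIDS",
]

TEMPERATURE_GRIDS = {
    "default": tuple(range(30, 96, 3)),
    "unligated": tuple(range(35, 76, 3)),
    "ligated": tuple(range(55, 96, 3)),
}


@dataclass(frozen=True)
class GroundTruth:
    """Declared truth for the survival-curve generator.

    Single model: ``S(T) = s_bottom + (s_top-s_bottom)/(1+exp((T-t_half)/w))``.
    Double model uses ``(phi, t1, t2, w1, w2)`` instead of ``(t_half, w)``.
    """

    model: str = "single"
    s_top: float = 1.0
    s_bottom: float = 0.0
    t_half: float = 53.0
    w: float = 3.0
    phi: float = 0.5
    t1: float = 45.0
    t2: float = 65.0
    w1: float = 2.5
    w2: float = 2.5
    noise_sd: float = 0.05
    intensity_sd: float = 0.1
    replicates: int = 3
    temperatures: tuple[float, ...] = TEMPERATURE_GRIDS["default"]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("single", "double"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.noise_sd < 0 or self.intensity_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        temps = np.asarray(self.temperatures, dtype=float)
        if len(temps) < 2 or not np.all(np.diff(temps) > 0):
            raise ValueError("temperature grid must be strictly increasing")

    def curve(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.model == "single":
            return boltzmann(t, self.s_bottom, self.s_top, self.t_half, self.w)
        return double_boltzmann(
            t, self.s_bottom, self.s_top, self.phi, self.t1, self.t2, self.w1, self.w2
        )

    def true_tm(self) -> float:
        """0.5 crossing of the noiseless truth curve."""
        from scipy.optimize import brentq

        lo, hi = min(self.temperatures) - 30, max(self.temperatures) + 30
        grid = np.linspace(lo, hi, 4001)
        vals = self.curve(grid) - 0.5
        idx = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
        if len(idx) == 0:
            raise ValueError("truth curve never crosses 0.5")
        i = idx[0]
        return float(brentq(lambda x: float(self.curve([x])[0]) - 0.5, grid[i], grid[i + 1]))


def gen_survival_dataset(
    truth: GroundTruth, seed: int | None = None
) -> tuple[SurvivalDataset, GroundTruth]:
    """Draw replicate survival rates ``S_ij = model(T_i) + N(0, sd)``.

    Returns the dataset together with its truth record for recovery
    tests.  Fully deterministic under the seed (``truth.seed`` unless
    overridden)."""
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    temps = np.asarray(truth.temperatures, dtype=float)
    clean = truth.curve(temps)
    rows = []
    for rep in range(truth.replicates):
        noisy = clean + rng.normal(0.0, truth.noise_sd, size=len(temps))
        for t, s in zip(temps, noisy):
            rows.append({"temperature_C": float(t), "replicate": rep, "survival": float(s)})
    return SurvivalDataset(pd.DataFrame(rows)), truth


def gen_band_table(
    masses: dict | None = None,
    truth: GroundTruth | None = None,
    standard_mass: float = 10.0,
    gain: float = 100.0,
    noise_sd: float | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate a gel band-intensity table, linear in mass.

    Two modes.  *Mass mode*: ``masses`` maps (lane, band) → loaded mass;
    one standard band of ``standard_mass`` is added and every intensity
    is ``mass * gain * lognormal(0, sd)``.  *Survival mode*: given a
    ``truth`` record, emits per-temperature target bands for each
    replicate whose underlying masses follow the truth curve, plus one
    4 °C control band per replicate — the input shape expected by
    ``melting.survival_rates``.
    """
    rng = np.random.default_rng(seed)

    def intensity(mass: float, sd: float) -> float:
        noise = rng.lognormal(0.0, sd) if sd > 0 else 1.0
        return mass * gain * noise

    rows = []
    if masses is not None:
        sd = noise_sd if noise_sd is not None else 0.1
        for (lane, band), mass in masses.items():
            if mass < 0:
                raise ValueError("band masses must be >= 0")
            rows.append(
                {
                    "lane": lane,
                    "band": band,
                    "intensity": intensity(mass, sd),
                    "role": "target",
                    "known_mass": np.nan,
                }
            )
        rows.append(
            {
                "lane": "ladder",
                "band": "standard",
                "intensity": intensity(standard_mass, sd),
                "role": "standard",
                "known_mass": standard_mass,
            }
        )
        return pd.DataFrame(rows)
    if truth is None:
        raise ValueError("provide either masses or a truth record")
    sd = noise_sd if noise_sd is not None else truth.intensity_sd
    temps = np.asarray(truth.temperatures, dtype=float)
    control_mass = 1.0
    clean = truth.curve(temps) * control_mass
    for rep in range(truth.replicates):
        rows.append(
            {
                "lane": f"rep{rep}_control",
                "band": "target",
                "intensity": intensity(control_mass, sd),
                "role": "control",
                "known_mass": np.nan,
                "replicate": rep,
                "temperature_C": 4.0,
            }
        )
        for t, mass in zip(temps, clean):
            rows.append(
                {
                    "lane": f"rep{rep}_T{t:g}",
                    "band": "target",
                    "intensity": intensity(max(mass, 0.0), sd),
                    "role": "target",
                    "known_mass": np.nan,
                    "replicate": rep,
                    "temperature_C": float(t),
                }
            )
    return pd.DataFrame(rows)


def gen_fixture_designs(outdir: str | Path) -> dict[str, str]:
    """Write every built-in design and mask config as JSON fixtures.

    Serialization is canonical (sorted keys, fixed indentation), so
    regeneration is byte-identical; returns path → sha256 checksums.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    checksums: dict[str, str] = {}
    for name, cfg in list(BUILTIN_DESIGNS.items()) + list(BUILTIN_MASKS.items()):
        path = outdir / f"{name}.json"
        text = json.dumps(cfg, indent=2, sort_keys=True, default=list) + "\n"
        path.write_text(text)
        checksums[path.name] = hashlib.sha256(text.encode()).hexdigest()
    return checksums
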