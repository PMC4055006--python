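"""Synthetic inputs with the statistical structure the analysis assumes.

Two kinds of input are generated here. First, cell populations matching the
characterization of the labeled MSCs: hydrodynamic diameter from a truncated
normal with mean 19.3 um on the observed [6, 36] um range (the study reports
only the range and mean; an SD of 5 um is adopted as a configurable default
and no claim is made of matching the true, unreported shape), and per-cell
elemental iron from a truncated normal with mean 21.77 pg, SD 3.62 pg,
truncated at zero. Second, per-group replicate measurements regenerated from
printed mean +/- SD summaries at the stated n — the inverse of how group
results are reported — including a retention experiment with a configurable
fold effect and lognormal animal-level noise.

A small set of read-only fixture tables transcribing the in-text summary
values (capture efficiency vs velocity, fluorescence photon counts,
Prussian-blue cell counts, relative MRI signal intensities, capillary
densities, retention fold, echocardiographic parameter labels) ships with the
package; they are verified against SHA-256 checksums at load time. Fixtures
transcribe printed numbers only — nothing is read off figures.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cell_magnetics import CellPopulation, CellSpec

__all__ = [
    "PopulationParams",
    "ExperimentDesign",
    "sample_cell_population",
    "sample_group_replicates",
    "generate_retention_experiment",
    "list_fixtures",
    "load_fixture",
    "FixtureChecksumError",
]


# ---------------------------------------------------------------------------
# cell populations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationParams:
    """Distributional model of the labeled-cell population (SI units)."""

    diameter_mean_m: float = 19.3e-6
    diameter_sd_m: float = 5.0e-6
    diameter_low_m: float = 6.0e-6
    diameter_high_m: float = 36.0e-6
    iron_mean_kg: float = 21.77e-15
    iron_sd_kg: float = 3.62e-15
    iron_low_kg: float = 0.0
    moment_model: str = "saturated"

    def __post_init__(self):
        if self.diameter_low_m >= self.diameter_high_m:
            raise ValueError("infeasible diameter bounds")
        if self.diameter_sd_m < 0 or self.iron_sd_kg < 0:
            raise ValueError("negative SD")


def _truncnorm_draw(rng, mean, sd, low, high, n):
    if sd == 0:
        return np.full(n, float(np.clip(mean, low, high)))
    a = (low - mean) / sd
    b = (high - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def sample_cell_population(params: PopulationParams = PopulationParams(),
                           n: int = 1000, seed: int = 0) -> CellPopulation:
    """Draw ``n`` cells with truncated-normal diameter and iron load."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    d = _truncnorm_draw(rng, params.diameter_mean_m, params.diameter_sd_m,
                        params.diameter_low_m, params.diameter_high_m, n)
    fe = _truncnorm_draw(rng, params.iron_mean_kg, params.iron_sd_kg,
                         params.iron_low_kg, np.inf, n)
    cells = [CellSpec(diameter_m=float(di), iron_mass_kg=float(fi),
                      moment_model=params.moment_model, label=f"cell{i:06d}")
             for i, (di, fi) in enumerate(zip(d, fe))]
    return CellPopulation(cells)


# ---------------------------------------------------------------------------
# group replicates from summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentDesign:
    """Per-group (label, mean, sd, n) design for replicate regeneration.

    ``nonnegative`` truncates draws at zero, appropriate for count-like
    measures (photon counts, cell counts, densities).
    """

    labels: tuple
    means: tuple
    sds: tuple
    ns: tuple
    measurement: str = ""
    unit: str = ""
    nonnegative: bool = False
    seed: int = 0

    def __post_init__(self):
        k = len(self.labels)
        if not (len(self.means) == len(self.sds) == len(self.ns) == k):
            raise ValueError("labels/means/sds/ns length mismatch")
        if any(n < 2 for n in self.ns):
            raise ValueError("each group needs n >= 2")
        if any(s < 0 for s in self.sds):
            raise ValueError("negative SD")

    @classmethod
    def from_summary_frame(cls, df: pd.DataFrame, mean_col: str, sd_col: str,
                           n_col: str = "n", label_col: str = "group",
                           **kwargs) -> "ExperimentDesign":
        return cls(labels=tuple(df[label_col]), means=tuple(df[mean_col]),
                   sds=tuple(df[sd_col]), ns=tuple(int(v) for v in df[n_col]),
                   **kwargs)


def sample_group_replicates(design: ExperimentDesign,
                            seed: int | None = None) -> pd.DataFrame:
    """Regenerate per-group replicates from summary statistics.

    Draws normal(mean, sd) per group (truncated at zero when the design is
    ``nonnegative``); fully determined by the seed. Returns a tidy frame with
    columns group, replicate, value.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    rows = []
    for label, mean, sd, n in zip(design.labels, design.means, design.sds,
                                  design.ns):
        if design.nonnegative:
            vals = _truncnorm_draw(rng, mean, sd, 0.0, np.inf, n)
        elif sd == 0:
            vals = np.full(n, float(mean))
        else:
            vals = rng.normal(mean, sd, size=n)
        rows.extend({"group": label, "replicate": i, "value": float(v)}
                    for i, v in enumerate(vals))
    return pd.DataFrame(rows)


def generate_retention_experiment(fold: float = 2.87,
                                  base_retention: float = 0.05,
                                  n_per_group: int = 6,
                                  seed: int = 0,
                                  cv: float = 0.3,
                                  infused: float = 1e6) -> pd.DataFrame:
    """Per-animal detected/infused counts for a two-group retention study.

    The magnet group's expected retention is ``base_retention * fold``;
    animal-level noise is lognormal with unit mean and coefficient of
    variation ``cv`` (counts are positive and right-skewed). ``infused`` is
    fixed at the delivered dose of 1e6 cells.
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    rng = np.random.default_rng(seed)
    sigma2 = np.log1p(cv ** 2)
    mu = -0.5 * sigma2
    rows = []
    for group, retention in (("NonMag", base_retention),
                             ("Mag", base_retention * fold)):
        if cv == 0:
            noise = np.ones(n_per_group)
        else:
            noise = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2),
                                  size=n_per_group)
        detected = infused * retention * noise
        rows.extend({"group": group, "animal": i, "detected": float(d),
                     "infused": float(infused)}
                    for i, d in enumerate(detected))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

class FixtureChecksumError(RuntimeError):
    """A packaged fixture does not match its recorded SHA-256 checksum."""


#: name -> sha256 of the packaged CSV
FIXTURE_CHECKSUMS = {
    "ce_velocity": "63c0e42fe727ac9ba77d0b479961d18f424b18f345d866b0b6ac7df0de44eb98",
    "fluorescence": "3ee1ef1712683628bee0fd231e80ba540dc08a7c460f6173d6c1c7a2fb5c2894",
    "prussian_blue": "69d8bd7978def07f4a76a3b78d8e653348fa8a4c6ad819a38a13c160abb0ddd8",
    "relative_si": "b5f77b8fdf1a551a516e4e1584d5d941af33c39905f69f16223b80f820b6d972",
    "capillary_density": "803a65edf3faf7a9997028de04633d38ae288a350eff50c44d11f31c070dc936",
    "retention": "ae0a6c1b469e3c0c80e774a28c8ec9aba516d8d3c920fdaaad03df0aac080f34",
    "cell_population": "30c74ccc8fedeb7852d333b44a10d7f74caed07caa92e20398ce7d2bb48e0bb7",
    "echo_parameters": "a787dd5a33cac7697658665ab5ed9936cd97ecd73cbd733a0b09060e3e1c3785",
}


def list_fixtures() -> list:
    """Names of the packaged summary-value tables."""
    return sorted(FIXTURE_CHECKSUMS)


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged fixture CSV, verifying its checksum."""
    if name not in FIXTURE_CHECKSUMS:
        raise KeyError(f"unknown fixture {name!r}; known: {list_fixtures()}")
    ref = resources.files("magtarget") / "fixtures" / f"{name}.csv"
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != FIXTURE_CHECKSUMS[name]:
        raise FixtureChecksumError(
            f"fixture {name!r} checksum mismatch: {digest}")
    import io
    return pd.read_csv(io.BytesIO(raw))
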