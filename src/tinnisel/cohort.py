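"""Synthetic patient/control cohort generation.

The clinical cohort behind the published group statistics is not
deposited, so this module simulates feature tables with the statistical
structure the downstream analysis assumes: a small set of *signal*
regions whose per-group Gaussian volume distributions are taken from the
published means/SDs, plus *null* nuisance regions drawn identically for
both groups.  Severity (THI) scores can be attached with a controlled
correlation to a named region's volume inside one severity band.

Generation is a pure function of the configuration (including its
seed): identical configs give byte-identical tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .evaluation import SEVERITY_BANDS, get_band
from .tables import (  # noqa: F401  (read/write re-exported here)
    GROUP_CONTROL,
    GROUP_PATIENT,
    FeatureTable,
    read_table,
    write_table,
)
from .util import derive_seed

logger = logging.getLogger(__name__)

#: generated volumes are floored here (mm^3) to keep physical positivity
VOLUME_FLOOR = 1.0


@dataclass(frozen=True)
class RegionDistribution:
    """Per-group Gaussian volume parameters for one signal region."""

    region_name: str
    mean_patient: float
    sd_patient: float
    mean_control: float
    sd_control: float

    def __post_init__(self) -> None:
        if self.sd_patient <= 0 or self.sd_control <= 0:
            raise ValueError(f"{self.region_name}: SDs must be positive")
        if self.mean_patient <= 0 or self.mean_control <= 0:
            raise ValueError(f"{self.region_name}: means must be positive")


@dataclass(frozen=True)
class ThiModel:
    """How THI scores are attached to patients.

    Each patient is assigned a severity band (probabilities
    ``band_weights``, default uniform over the five bands) and an even
    THI score within it.  If ``region`` and ``band`` are set, the scores
    of patients in that band correlate with that region's volume at
    ``target_r`` in expectation; all other scores are independent of the
    volumes.
    """

    region: str | None = None
    band: str | None = None
    target_r: float = 0.0
    band_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if abs(self.target_r) >= 1.0:
            raise ValueError("target correlation must satisfy |r| < 1")
        if self.target_r != 0.0 and (self.region is None or self.band is None):
            raise ValueError("a nonzero target_r needs region and band")
        if self.band_weights is not None:
            w = np.asarray(self.band_weights, dtype=float)
            if len(w) != len(SEVERITY_BANDS) or (w < 0).any() or w.sum() <= 0:
                raise ValueError("band_weights must be 5 non-negative weights")


def _default_signal_regions() -> tuple[RegionDistribution, ...]:
    from .reference import SIGNAL_REGIONS  # deferred: reference imports us

    return SIGNAL_REGIONS


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic cohort.

    Defaults reproduce the reference study conditions: 46 patients and
    56 controls over 61 regions — the 13 published signal regions at
    their printed group means/SDs plus 48 group-identical null regions
    whose means span the same volume scale (uniform on
    ``null_mean_range``, SD = ``null_cv`` x mean).

    ``effect_scale`` multiplies each signal region's patient-control
    mean difference about its midpoint (0 = no signal, 1 = as printed).
    ``correlation`` adds an exchangeable inter-region correlation rho.
    """

    n_patients: int = 46
    n_controls: int = 56
    signal_regions: tuple[RegionDistribution, ...] = field(
        default_factory=_default_signal_regions
    )
    n_null_regions: int = 48
    null_region_names: tuple[str, ...] | None = None
    null_mean_range: tuple[float, float] = (80.0, 550.0)
    null_cv: float = 0.13
    effect_scale: float = 1.0
    correlation: float = 0.0
    age_range: tuple[int, int] = (22, 64)
    male_fraction: float = 0.4
    thi_model: ThiModel | None = field(default_factory=ThiModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients + self.n_controls < 10:
            raise ValueError("cohort must have at least 10 subjects")
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError("both groups must be non-empty")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError(
                "inter-region correlation must lie in [0, 1) to keep the "
                "covariance positive-definite"
            )
        lo, hi = self.null_mean_range
        if not 0 < lo <= hi:
            raise ValueError("null_mean_range must be positive and ordered")
        if self.null_cv <= 0:
            raise ValueError("null_cv must be positive")
        if self.null_region_names is not None and (
            len(self.null_region_names) != self.n_null_regions
        ):
            raise ValueError("null_region_names length != n_null_regions")

    @property
    def region_names(self) -> list[str]:
        signal = [r.region_name for r in self.signal_regions]
        if self.null_region_names is not None:
            null = list(self.null_region_names)
        else:
            null = [f"null_{i + 1:02d}" for i in range(self.n_null_regions)]
        names = signal + null
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        return names

    @property
    def n_regions(self) -> int:
        return len(self.signal_regions) + self.n_null_regions


def generate_cohort(config: CohortConfig) -> FeatureTable:
    """Draw a synthetic cohort feature table.

    Signal-region volumes are independent per-group Gaussians (optionally
    sharing an exchangeable correlation ``rho``); null regions use one
    Gaussian for both groups.  Volumes are floored at
    :data:`VOLUME_FLOOR`; flooring events are logged.  Patients come
    first (``TP``), controls after (``HC``).
    """
    rng = np.random.default_rng(derive_seed(config.seed, "cohort"))
    n = config.n_patients + config.n_controls
    p = config.n_regions
    names = config.region_names
    is_patient = np.zeros(n, dtype=bool)
    is_patient[: config.n_patients] = True

    # null-region parameters (uniform raw draws so that scaling the range
    # scales the means without touching the random stream)
    raw = rng.random(config.n_null_regions)
    lo, hi = config.null_mean_range
    null_means = lo + raw * (hi - lo)
    null_sds = config.null_cv * null_means

    # per-region group means/SDs, with the mean difference scaled about
    # the midpoint of the two printed means
    mean_pat = np.empty(p)
    mean_ctl = np.empty(p)
    sd_pat = np.empty(p)
    sd_ctl = np.empty(p)
    for j, reg in enumerate(config.signal_regions):
        mid = 0.5 * (reg.mean_patient + reg.mean_control)
        mean_pat[j] = mid + config.effect_scale * (reg.mean_patient - mid)
        mean_ctl[j] = mid + config.effect_scale * (reg.mean_control - mid)
        sd_pat[j] = reg.sd_patient
        sd_ctl[j] = reg.sd_control
    k = len(config.signal_regions)
    mean_pat[k:] = mean_ctl[k:] = null_means
    sd_pat[k:] = sd_ctl[k:] = null_sds

    # standardized draws with optional exchangeable correlation
    common = rng.standard_normal(n)
    eps = rng.standard_normal((n, p))
    rho = config.correlation
    z = np.sqrt(rho) * common[:, None] + np.sqrt(1.0 - rho) * eps

    means = np.where(is_patient[:, None], mean_pat, mean_ctl)
    sds = np.where(is_patient[:, None], sd_pat, sd_ctl)
    volumes = means + sds * z
    n_floored = int((volumes < VOLUME_FLOOR).sum())
    if n_floored:
        logger.warning(
            "floored %d generated volumes at %.1f mm^3", n_floored, VOLUME_FLOOR
        )
        volumes = np.maximum(volumes, VOLUME_FLOOR)

    ages = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)
    sexes = np.where(
        rng.random(n) < config.male_fraction, "male", "female"
    )
    ids = [f"TP{i + 1:03d}" for i in range(config.n_patients)] + [
        f"HC{i + 1:03d}" for i in range(config.n_controls)
    ]
    df = pd.DataFrame(
        {
            "subject_id": ids,
            "group": np.where(is_patient, GROUP_PATIENT, GROUP_CONTROL),
            "age": ages,
            "sex": sexes,
            "thi": np.nan,
        }
    )
    for j, name in enumerate(names):
        df[name] = volumes[:, j]
    table = FeatureTable(df, names, provenance="synthetic")
    if config.thi_model is not None:
        table = attach_thi(
            table, config.thi_model, derive_seed(config.seed, "thi")
        )
    return table


def attach_thi(
    table: FeatureTable, thi_model: ThiModel, seed: int
) -> FeatureTable:
    """Attach even THI scores in [0, 100] to the patients of a table.

    Patients are distributed over the five severity bands; inside the
    model's focus band the score tracks the named region's standardized
    volume at the target correlation (a bivariate-Gaussian construction,
    then clipped to the band and rounded to the even grid).  Controls
    are unchanged.
    """
    if table.n_patients == 0:
        raise ValueError("table has no patients to score")
    if thi_model.region is not None and (
        thi_model.region not in table.region_names
    ):
        raise KeyError(f"unknown region {thi_model.region!r}")
    rng = np.random.default_rng(seed)
    pat_mask = table.data["group"].to_numpy() == GROUP_PATIENT
    n_pat = int(pat_mask.sum())

    weights = (
        np.asarray(thi_model.band_weights, dtype=float)
        if thi_model.band_weights is not None
        else np.ones(len(SEVERITY_BANDS))
    )
    weights = weights / weights.sum()
    band_idx = rng.choice(len(SEVERITY_BANDS), size=n_pat, p=weights)

    focus = get_band(thi_model.band) if thi_model.band is not None else None
    thi = np.full(n_pat, np.nan)
    for bi, band in enumerate(SEVERITY_BANDS):
        members = np.flatnonzero(band_idx == bi)
        if len(members) == 0:
            continue
        latent = rng.standard_normal(len(members))
        if focus is not None and band.name == focus.name and (
            thi_model.region is not None
        ):
            vols = table.data.loc[pat_mask, thi_model.region].to_numpy(
                dtype=np.float64
            )[members]
            sd = vols.std()
            if sd > 0 and len(members) > 1:
                z_vol = (vols - vols.mean()) / sd
                r = thi_model.target_r
                latent = r * z_vol + np.sqrt(1.0 - r * r) * latent
        grid = band.even_scores()
        center = 0.5 * (grid[0] + grid[-1])
        spread = (grid[-1] - grid[0]) / 5.0
        scores = np.clip(center + spread * latent, grid[0], grid[-1])
        thi[members] = 2.0 * np.round(scores / 2.0)

    df = table.data.copy()
    df.loc[pat_mask, "thi"] = thi
    return FeatureTable(df, list(table.region_names), table.provenance)


def with_effect_scale(config: CohortConfig, effect_scale: float) -> CohortConfig:
    """Copy of a config with a different signal effect multiplier."""
    return replace(config, effect_scale=effect_scale)
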