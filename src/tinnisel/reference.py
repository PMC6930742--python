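"""Reference study conditions.

The published group statistics for the 13 brain regions that the
original analysis retained, keyed to the shipped ROI catalogue, plus a
factory for the default synthetic cohort configuration (46 tinnitus
patients, 56 healthy controls, 61 regions).

Note: the printed statistics for the left rostral middle frontal gyrus
are identical in both groups (372.7 +/- 99.23); they are reproduced as
printed, so that region carries no group signal in synthetic cohorts.
"""

from __future__ import annotations

from .cohort import CohortConfig, RegionDistribution, ThiModel
from .roi import default_catalogue

#: group volume statistics (mm^3, mean / SD) of the 13 selected regions
SIGNAL_REGIONS: tuple[RegionDistribution, ...] = (
    RegionDistribution("R_hypothalamus_5_-5_-11", 349.0, 45.5, 383.5, 56.1),
    RegionDistribution("L_hypothalamus_-4_-10_-6", 89.4, 7.4, 95.9, 10.0),
    RegionDistribution("R_insula_36_3_1", 306.9, 32.5, 328.0, 39.9),
    RegionDistribution(
        "R_superior_temporal_gyrus_52_-41_13", 414.2, 65.3, 438.8, 69.8
    ),
    RegionDistribution(
        "L_rostral_middle_frontal_gyrus_-20_56_-2", 372.7, 99.23, 372.7, 99.23
    ),
    RegionDistribution(
        "R_inferior_temporal_gyrus_55_-23_-24", 313.4, 51.2, 330.8, 49.0
    ),
    RegionDistribution(
        "R_inferior_parietal_lobule_43_-66_25", 503.8, 77.0, 469.9, 54.5
    ),
    RegionDistribution(
        "L_superior_temporal_gyrus_-47_8_-26", 317.7, 33.4, 310.4, 39.2
    ),
    RegionDistribution(
        "L_inferior_temporal_gyrus_-62_-12_-26", 207.0, 28.2, 214.2, 22.2
    ),
    RegionDistribution(
        "R_transverse_temporal_gyrus_43_-24_3", 382.8, 43.3, 400.5, 48.7
    ),
    RegionDistribution(
        "R_middle_temporal_gyrus_49_-70_13", 280.7, 28.5, 267.4, 50.1
    ),
    RegionDistribution("R_cingulate_gyrus_10_30_22", 370.0, 61.8, 392.7, 66.6),
    RegionDistribution(
        "L_superior_frontal_gyrus_-11_63_19", 347.4, 66.8, 364.0, 67.5
    ),
)

#: signal regions whose printed group means actually differ (12 of 13)
EFFECTIVE_SIGNAL_REGIONS: tuple[str, ...] = tuple(
    r.region_name
    for r in SIGNAL_REGIONS
    if r.mean_patient != r.mean_control
)

N_PATIENTS = 46
N_CONTROLS = 56
MAJORITY_RATE = N_CONTROLS / (N_PATIENTS + N_CONTROLS)


def null_region_names() -> tuple[str, ...]:
    """Feature ids of the 48 catalogue regions with no published effect."""
    signal = {r.region_name for r in SIGNAL_REGIONS}
    names = tuple(
        fid for fid in default_catalogue().feature_ids() if fid not in signal
    )
    assert len(names) == 48, "catalogue/signal mismatch"
    return names


def default_cohort_config(
    seed: int = 0,
    effect_scale: float = 1.0,
    thi_model: ThiModel | None = ThiModel(),
    correlation: float = 0.0,
) -> CohortConfig:
    """The reference synthetic cohort: 46/56 subjects, 61 named regions."""
    return CohortConfig(
        n_patients=N_PATIENTS,
        n_controls=N_CONTROLS,
        signal_regions=SIGNAL_REGIONS,
        n_null_regions=48,
        null_region_names=null_region_names(),
        effect_scale=effect_scale,
        correlation=correlation,
        thi_model=thi_model,
        seed=seed,
    )
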