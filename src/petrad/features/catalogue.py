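"""The 110-feature catalogue: 12 shape, 43 first-order, 23 GLCM, 11 GLRLM,
5 NGTDM and 16 GLSZM features, keyed by their IBSI identifier codes.

Emitted feature names follow ``family.code.human_name`` (e.g.
``glcm.GYBY.joint_maximum``) so each value stays traceable to its IBSI
definition. One first-order code appears twice upstream (median and 50th
percentile share a definition); the second occurrence is disambiguated as
``Y12H1``.
"""

from __future__ import annotations

__all__ = [
    "SHAPE_FEATURES",
    "FIRSTORDER_FEATURES",
    "GLCM_FEATURES",
    "GLRLM_FEATURES",
    "NGTDM_FEATURES",
    "GLSZM_FEATURES",
    "FAMILIES",
    "FAMILY_COUNTS",
    "ALL_FEATURE_NAMES",
    "KEY_FEATURE_CODES",
    "feature_name",
    "N_FEATURES",
]

# (IBSI code, human name) in catalogue order
SHAPE_FEATURES = [
    ("RNU0", "volume"),
    ("YEKZ", "approximate_volume"),
    ("C0JK", "surface_area"),
    ("2PR5", "surface_to_volume_ratio"),
    ("SKGS", "compactness_1"),
    ("BQWJ", "compactness_2"),
    ("KRCK", "spherical_disproportion"),
    ("QCFX", "sphericity"),
    ("25C7", "asphericity"),
    ("KLMA", "centre_of_mass_shift"),
    ("L0JK", "maximum_3d_diameter"),
    ("99N0", "integrated_intensity"),
]

FIRSTORDER_FEATURES = [
    ("Q4LE", "mean"),
    ("ECT3", "variance"),
    ("KE2A", "skewness"),
    ("IPH6", "kurtosis"),
    ("Y12H", "median"),
    ("1GSF", "minimum"),
    ("QG58", "percentile_10"),
    ("Y12H1", "percentile_50"),
    ("8DWT", "percentile_90"),
    ("84IY", "maximum"),
    ("SALO", "interquartile_range"),
    ("2OJQ", "range"),
    ("4FUA", "mean_absolute_deviation"),
    ("1128", "robust_mean_absolute_deviation"),
    ("N72L", "median_absolute_deviation"),
    ("7TET", "coefficient_of_variation"),
    ("9S40", "quartile_coefficient_of_dispersion"),
    ("N8CA", "energy"),
    ("5ZWQ", "root_mean_square"),
    ("0F91", "global_intensity_peak"),
    ("X6K6", "ih_mean"),
    ("CH89", "ih_variance"),
    ("88K1", "ih_skewness"),
    ("C3I7", "ih_kurtosis"),
    ("WIFQ", "ih_median"),
    ("1PR8", "ih_minimum"),
    ("GPMT", "ih_percentile_10"),
    ("OZ0C", "ih_percentile_90"),
    ("3NCY", "ih_maximum"),
    ("AMMC", "ih_mode"),
    ("WR0O", "ih_interquartile_range"),
    ("5Z3W", "ih_range"),
    ("D2ZX", "ih_mean_absolute_deviation"),
    ("WRZB", "ih_robust_mean_absolute_deviation"),
    ("4RNL", "ih_median_absolute_deviation"),
    ("CWYJ", "ih_coefficient_of_variation"),
    ("SLWD", "ih_quartile_coefficient_of_dispersion"),
    ("TLU2", "ih_entropy_log2"),
    ("BJ5W", "ih_uniformity"),
    ("12CE", "max_histogram_gradient"),
    ("8E6O", "max_histogram_gradient_grey_level"),
    ("VQB3", "min_histogram_gradient"),
    ("RHQZ", "min_histogram_gradient_grey_level"),
]

GLCM_FEATURES = [
    ("GYBY", "joint_maximum"),
    ("60VM", "joint_average"),
    ("UR99", "joint_variance"),
    ("TU9B", "joint_entropy_log2"),
    ("TF7R", "difference_average"),
    ("D3YU", "difference_variance"),
    ("NTRS", "difference_entropy"),
    ("ZGXS", "sum_average"),
    ("OEEB", "sum_variance"),
    ("P6QZ", "sum_entropy"),
    ("8ZQL", "angular_second_moment"),
    ("ACUI", "contrast"),
    ("8S9J", "dissimilarity"),
    ("IB1Z", "inverse_difference"),
    ("NDRX", "normalised_inverse_difference"),
    ("WF0Z", "inverse_difference_moment"),
    ("1QCO", "normalised_inverse_difference_moment"),
    ("E8JP", "inverse_variance"),
    ("NI2N", "correlation"),
    ("QWB0", "autocorrelation"),
    ("DG8W", "cluster_tendency"),
    ("7NFM", "cluster_shade"),
    ("AE86", "cluster_prominence"),
]

GLRLM_FEATURES = [
    ("22OV", "short_runs_emphasis"),
    ("W4KF", "long_runs_emphasis"),
    ("V3SW", "low_grey_level_run_emphasis"),
    ("G3QZ", "high_grey_level_run_emphasis"),
    ("HTZT", "short_run_low_grey_level_emphasis"),
    ("GD3A", "short_run_high_grey_level_emphasis"),
    ("IVPO", "long_run_low_grey_level_emphasis"),
    ("3KUM", "long_run_high_grey_level_emphasis"),
    ("R5YN", "grey_level_non_uniformity"),
    ("W92Y", "run_length_non_uniformity"),
    ("9ZK5", "run_percentage"),
]

NGTDM_FEATURES = [
    ("QCDE", "coarseness"),
    ("65HE", "contrast"),
    ("NQ30", "busyness"),
    ("HDEZ", "complexity"),
    ("1X9X", "strength"),
]

GLSZM_FEATURES = [
    ("5QRC", "small_zone_emphasis"),
    ("48P8", "large_zone_emphasis"),
    ("XMSY", "low_grey_level_zone_emphasis"),
    ("5GN9", "high_grey_level_zone_emphasis"),
    ("5RAI", "small_zone_low_grey_level_emphasis"),
    ("HW1V", "small_zone_high_grey_level_emphasis"),
    ("YH51", "large_zone_low_grey_level_emphasis"),
    ("J17V", "large_zone_high_grey_level_emphasis"),
    ("JNSA", "grey_level_non_uniformity"),
    ("Y1RO", "normalised_grey_level_non_uniformity"),
    ("4JP3", "zone_size_non_uniformity"),
    ("VB3A", "normalised_zone_size_non_uniformity"),
    ("P30P", "zone_percentage"),
    ("BYLV", "grey_level_variance"),
    ("3NSA", "zone_size_variance"),
    ("GU8N", "zone_size_entropy"),
]

FAMILIES = {
    "shape": SHAPE_FEATURES,
    "firstorder": FIRSTORDER_FEATURES,
    "glcm": GLCM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "ngtdm": NGTDM_FEATURES,
    "glszm": GLSZM_FEATURES,
}

FAMILY_COUNTS = {fam: len(feats) for fam, feats in FAMILIES.items()}
N_FEATURES = sum(FAMILY_COUNTS.values())  # 110

#: The starred key features elected upstream for the RadScore
KEY_FEATURE_CODES = [
    "C0JK", "QG58", "0F91", "OZ0C", "8E6O", "VQB3",
    "GYBY", "TF7R", "WF0Z", "DG8W", "AE86",
]


def feature_name(family: str, code: str, human: str) -> str:
    return f"{family}.{code}.{human}"


ALL_FEATURE_NAMES = [
    feature_name(fam, code, human)
    for fam, feats in FAMILIES.items()
    for code, human in feats
]
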