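"""Analytical constants and default configuration values.

These are the fixed quantities of the analysis: the trophic-position
transform constants, the collagen preservation screen, the measured
amino-acid set and its default nitrogen-fraction composition. Everything
here is overridable through the relevant config objects; this module is
the single machine-readable source of the defaults.
"""

from __future__ import annotations

# Trophic-position transform: TP = (Y - PP_OFFSET) / TEF + 1, where Y is a
# trophic-minus-source proxy (e.g. Glx - Phe) in per mil and TEF is the
# trophic enrichment factor with a truncated-normal prior.
PP_OFFSET: float = 2.9  # per mil; primary-producer trophic-source offset
TEF_PRIOR_MEAN: float = 6.6  # per mil per trophic level
TEF_PRIOR_SD: float = 1.7  # per mil

# Atomic C:N screen for acceptable collagen preservation (closed interval).
CN_RATIO_MIN: float = 3.0
CN_RATIO_MAX: float = 3.6

# The 13 proteinogenic amino acids measured by GC-C-IRMS.
TROPHIC_AAS: tuple[str, ...] = ("Glx", "Ala", "Asx", "Pro", "Hyp", "Val", "Leu", "Ile")
SOURCE_AAS: tuple[str, ...] = ("Phe", "Gly", "Ser", "Lys")
METABOLIC_AAS: tuple[str, ...] = ("Thr",)  # depletes with trophic level
ALL_AAS: tuple[str, ...] = TROPHIC_AAS + SOURCE_AAS + METABOLIC_AAS

# Default nitrogen fraction of bulk collagen contributed by each AA.
# Gly dominates fish collagen (~30% of total N); the set sums to 0.807,
# the fraction of collagen nitrogen captured by the AA measurements.
NITROGEN_FRACTIONS: dict[str, float] = {
    "Gly": 0.300,
    "Pro": 0.100,
    "Ala": 0.080,
    "Hyp": 0.080,
    "Glx": 0.070,
    "Asx": 0.050,
    "Ser": 0.030,
    "Leu": 0.025,
    "Lys": 0.025,
    "Val": 0.020,
    "Ile": 0.010,
    "Phe": 0.010,
    "Thr": 0.007,
}

#: Machine-readable bundle of the analytical defaults.
DEFAULTS: dict[str, object] = {
    "pp_offset": PP_OFFSET,
    "tef_prior_mean": TEF_PRIOR_MEAN,
    "tef_prior_sd": TEF_PRIOR_SD,
    "cn_ratio_bounds": (CN_RATIO_MIN, CN_RATIO_MAX),
    "amino_acids": ALL_AAS,
    "nitrogen_fractions": NITROGEN_FRACTIONS,
}


def aa_column(aa: str) -> str:
    """Wide-table column name for an amino acid's delta-15N value."""
    return f"d15N_{aa}"


def aa_sd_column(aa: str) -> str:
    """Wide-table column name for an amino acid's replicate/analytical sd."""
    return f"d15N_{aa}_sd"
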