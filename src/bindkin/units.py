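"""Unit system and physical constants.

Everything internal is in ns (time), nm (length), kcal/mol (energy).
Rates cross the ns/s boundary only in user-facing summaries.
"""

#: Boltzmann constant, kcal/mol/K (equals the molar gas constant R in these units).
KB_KCAL_MOL_K = 0.0019872041

#: Default absolute temperature, K (simulation temperature of the benzene/T4L study).
DEFAULT_TEMPERATURE_K = 303.0

#: Exact thermochemical calorie conversion.
KJ_PER_KCAL = 4.184

NS_PER_S = 1e9


def kt_kcal(temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Thermal energy k_B*T in kcal/mol."""
    if temperature_k <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_k}")
    return KB_KCAL_MOL_K * temperature_k


def kj_to_kcal(x: float) -> float:
    return x / KJ_PER_KCAL


def kcal_to_kj(x: float) -> float:
    return x * KJ_PER_KCAL
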