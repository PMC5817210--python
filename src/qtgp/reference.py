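"""Published reference constants for the terfenadine virtual-trial analysis.

Everything downstream is calibrated against the published summary of the
10,360-record virtual-trial data set: per-variable six-number summaries
(min, Q25, median, mean, Q75, max) for the 48 covariates and the dQTc
output, the eight trial arms (terfenadine alone plus seven metabolic
inhibitors), the X-label mapping of the eight inputs used by the white-box
dQTc equation, its four fitted constants, and the five quantile scenarios
used in the response analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "VariableSpec",
    "VARIABLE_SUMMARIES",
    "OUTPUT_SUMMARY",
    "ARM_LABELS",
    "N_PATIENTS",
    "TOTAL_RECORDS",
    "EQUATION_INPUTS",
    "MODEL_CONSTANTS",
    "RESPONSE_SCENARIOS",
    "SCALE_LO",
    "SCALE_HI",
]


@dataclass(frozen=True)
class VariableSpec:
    """Six-number summary of one covariate on its raw scale.

    ``vclass`` distinguishes ordinary continuous covariates from columns
    that are identically zero in the data set (several CYP isoforms absent
    from the simulated population) and from the binary sex code.
    """

    name: str
    units: str
    vmin: float
    q25: float
    median: float
    mean: float
    q75: float
    vmax: float
    vclass: str = "continuous"  # continuous | constant | binary

    @property
    def knots(self) -> tuple[float, float, float, float, float]:
        """The five quantile knots (min, Q25, median, Q75, max)."""
        return (self.vmin, self.q25, self.median, self.q75, self.vmax)

    @property
    def monotone(self) -> bool:
        k = self.knots
        return all(a <= b for a, b in zip(k, k[1:]))

    def validate(self) -> None:
        if self.vclass == "constant":
            if any(k != self.vmin for k in (*self.knots, self.mean)):
                raise ValueError(f"{self.name}: constant variable with unequal knots")
            return
        if self.vclass == "binary":
            if not (0.0 <= self.mean <= 1.0):
                raise ValueError(f"{self.name}: binary mean outside [0, 1]")
            if not {self.vmin, self.vmax} <= {0.0, 1.0}:
                raise ValueError(f"{self.name}: binary bounds outside {{0, 1}}")
            return
        if not self.monotone:
            raise ValueError(f"{self.name}: non-monotone quantile knots {self.knots}")


def _v(name, units, vmin, q25, median, mean, q75, vmax, vclass="continuous"):
    return VariableSpec(name, units, float(vmin), float(q25), float(median),
                        float(mean), float(q75), float(vmax), vclass)


# The 48 covariates, in published column order.  Liver CYP abundances in
# pmol/mg protein, gut CYPs in nmol/small intestine; several isoforms are
# identically zero across the simulated population (vclass="constant").
# Note: the Gut_CYP2C9 row is transcribed exactly as printed even though its
# Min exceeds its Q25; the sampler layer deals with the inconsistency.
VARIABLE_SUMMARIES: tuple[VariableSpec, ...] = (
    _v("CYP1A2", "pmol/mg protein", 0, 0, 0, 695159, 0, 11963910),
    _v("CYP2A6", "pmol/mg protein", 0, 0, 0, 0, 0, 0, "constant"),
    _v("CYP2B6", "pmol/mg protein", 0, 0, 0, 86155, 0, 9129915),
    _v("CYP2C8", "pmol/mg protein", 0, 0, 0, 0, 0, 0, "constant"),
    _v("CYP2C9", "pmol/mg protein", 0, 0, 0, 347459, 0, 16469809),
    _v("CYP2C18", "pmol/mg protein", 0, 0, 0, 0, 0, 0, "constant"),
    _v("CYP2C19", "pmol/mg protein", 0, 0, 0, 179400, 0, 5511004),
    _v("CYP2D6", "pmol/mg protein", 0, 252231, 399478, 506695, 676312, 2185456),
    _v("CYP2E1", "pmol/mg protein", 0, 0, 0, 0, 0, 0, "constant"),
    _v("CYP2J2", "pmol/mg protein", 0, 0, 0, 0, 0, 0, "constant"),
    _v("CYP3A4", "pmol/mg protein", 1552693, 5716140, 8459929, 9833766, 12016781, 32307836),
    _v("CYP3A5", "pmol/mg protein", 0, 0, 0, 272853, 0, 13728653),
    _v("CYP3A7", "pmol/mg protein", 0, 0, 0, 0, 0, 0, "constant"),
    _v("Gut_CYP2C9", "nmol/small intestine", 8210, 1430, 10037.216, 10089.122, 10148.391, 10388.032),
    _v("Gut_CYP2C19", "nmol/small intestine", 0, 0, 0, 299, 0, 7330),
    _v("Gut_CYP2D6", "nmol/small intestine", 0, 484.7, 674.4, 818.4, 994.5, 3156),
    _v("Gut_CYP2J2", "nmol/small intestine", 0, 0, 0, 0, 0, 0, "constant"),
    _v("Gut_CYP3A4", "nmol/small intestine", 11214, 35540, 55975, 62911, 80376, 217447),
    _v("Gut_CYP3A5", "nmol/small intestine", 0, 0, 0, 807.2, 0, 55106.1),
    _v("Sex_Code", "male=0/female=1", 0, 1, 1, 0.7718, 1, 1, "binary"),
    _v("Age", "years", 19, 25, 28, 28.39, 32, 52),
    _v("Weight", "kg", 44.52, 69.43, 78.31, 79.04, 89.17, 127),
    _v("Height", "cm", 149.4, 168.6, 174.3, 173.6, 179.7, 200.5),
    _v("BSA", "m^2", 1.422, 1.802, 1.937, 1.929, 2.048, 2.432),
    _v("Brain_Weight", "g", 1040, 1230, 1354, 1388, 1524, 2057),
    _v("Kidney_Weight", "g", 164.1, 269.1, 325, 329.1, 382.6, 752),
    _v("Liver_Weight", "g", 1052, 1544, 1700, 1740, 1938, 2699),
    _v("BMI", "kg/m^2", 16.13, 22.87, 26.22, 26.19, 28.8, 45.31),
    _v("Cardiac_Output", "L/h", 249.7, 315.1, 339.4, 337.5, 357.2, 424.5),
    _v("Haematocrit", "%", 32.12, 38.99, 41.73, 41.46, 43.68, 51.05),
    _v("HSA", "g/L", 35.11, 42.88, 45.74, 45.75, 48.57, 58.08),
    _v("AGP", "g/L", 0.3971, 0.7137, 0.8035, 0.7982, 0.8851, 1.207),
    _v("Serum_Creatinine", "umol/L", 33.64, 62.09, 73.26, 72.61, 81.2, 122.95),
    _v("GFR", "mL/min/1.73m^2", 70.97, 112.12, 129.74, 133.34, 153.5, 243.16),
    _v("Renal_Function", "ratio", 0.59, 0.92, 1.079, 1.089, 1.271, 1.87),
    _v("Cardiomyocyte_area", "um^2", 652.5, 1384.3, 1701.1, 1824.4, 2146.8, 5353.7),
    _v("Cardiomyocyte_volume", "um^3", 1852, 4494, 5630, 6217, 7346, 20339),
    _v("Sarcoplasmic_reticulum_volume", "um^3", 111.1, 269.6, 337.8, 373, 440.7, 1220.3),
    _v("Capacitance", "pF", 17.33, 36.77, 45.18, 48.46, 57.02, 142.2),
    _v("String_length", "cm", 0.8772, 1.1814, 1.293, 1.2878, 1.4064, 1.8619),
    _v("K", "mM", 3.053, 4.079, 4.268, 4.261, 4.451, 5.363),
    _v("Na", "mM", 135.1, 139.6, 140.4, 140.3, 141.1, 143.3),
    _v("Ca2", "mM", 2.007, 2.237, 2.388, 2.394, 2.546, 2.789),
    _v("IKr_inhibition", "fraction", 0.0047, 0.0484, 0.1172, 0.2378, 0.3841, 1),
    _v("IKs_inhibition", "fraction", 0, 1e-4, 1e-4, 0.0002684, 0.0003, 0.008),
    _v("INa_inhibition", "fraction", 0, 0.0003, 0.0007, 0.001493, 0.0016, 0.0353),
    _v("ICa_inhibition", "fraction", 0, 0.0009, 0.0022, 0.01782, 0.0061, 0.5217),
    _v("Stimulation_Period", "ms", 432, 735, 825, 836.1, 925, 1570),
)

#: Summary row for the dQTc output (ms).
OUTPUT_SUMMARY = _v("dQTc", "ms", -15.707, 1.713, 6.591, 10.572, 14.69, 78.142)

#: Eight trial arms: terfenadine alone plus seven interacting drugs.
ARM_LABELS: tuple[str, ...] = (
    "terfenadine_alone",
    "clarithromycin",
    "erythromycin",
    "itraconazole",
    "ketoconazole",
    "fluconazole",
    "fluoxetine",
    "paroxetine",
)

N_PATIENTS = 63
TOTAL_RECORDS = 10360

#: X-label -> covariate name for the eight inputs retained by the white-box
#: dQTc equation (gender, weight, liver/gut CYPs and cardiac output were
#: eliminated during the evolutionary search).
EQUATION_INPUTS: dict[str, str] = {
    "X6": "BSA",
    "X8": "K",
    "X9": "Na",
    "X10": "Ca2",
    "X11": "IKr_inhibition",
    "X12": "IKs_inhibition",
    "X13": "INa_inhibition",
    "X14": "ICa_inhibition",
}

#: Fitted adjustable constants (C1, C2, C3, C4) of the white-box equation.
MODEL_CONSTANTS: tuple[float, float, float, float] = (
    -14.09525,
    7.706551,
    46.69071192,
    4.587024,
)

#: Quantile scenarios of the response analysis: raw values at which the
#: seven non-swept equation inputs are held for Q1 (0%) ... Q5 (100%).
RESPONSE_SCENARIOS: dict[str, dict[str, float]] = {
    "Q1": {"BSA": 1.422, "K": 3.053, "Na": 135.144, "Ca2": 2.007,
           "IKr_inhibition": 0.005, "IKs_inhibition": 0.0,
           "INa_inhibition": 0.0, "ICa_inhibition": 0.0},
    "Q2": {"BSA": 1.802, "K": 4.079, "Na": 139.578, "Ca2": 2.237,
           "IKr_inhibition": 0.048, "IKs_inhibition": 0.0,
           "INa_inhibition": 0.0, "ICa_inhibition": 0.001},
    "Q3": {"BSA": 1.937, "K": 4.268, "Na": 140.445, "Ca2": 2.388,
           "IKr_inhibition": 0.117, "IKs_inhibition": 0.0,
           "INa_inhibition": 0.001, "ICa_inhibition": 0.002},
    "Q4": {"BSA": 2.048, "K": 4.451, "Na": 141.094, "Ca2": 2.546,
           "IKr_inhibition": 0.384, "IKs_inhibition": 0.0,
           "INa_inhibition": 0.002, "ICa_inhibition": 0.006},
    "Q5": {"BSA": 2.432, "K": 5.363, "Na": 143.332, "Ca2": 2.789,
           "IKr_inhibition": 1.0, "IKs_inhibition": 0.008,
           "INa_inhibition": 0.035, "ICa_inhibition": 0.522},
}

#: Target interval of the linear feature scaling.
SCALE_LO = 0.1
SCALE_HI = 0.9


def variable_names() -> list[str]:
    """Names of the 48 covariates in published column order."""
    return [v.name for v in VARIABLE_SUMMARIES]


def get_spec(name: str) -> VariableSpec:
    """Look up one covariate summary (or the dQTc output row) by name."""
    if name == OUTPUT_SUMMARY.name:
        return OUTPUT_SUMMARY
    for v in VARIABLE_SUMMARIES:
        if v.name == name:
            return v
    raise KeyError(name)
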