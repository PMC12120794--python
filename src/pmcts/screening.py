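"""Reference screening panel for dual EGFR/HER2 inhibitor candidates.

Threshold criteria for an eight-property panel (predicted pIC50 against
EGFR and HER2, aqueous solubility logS, Caco-2 permeability, metabolic
stability, toxicity class, QED and SAScore), together with ten example
property records for generated candidate molecules.  The thresholds
encode minimum pharmaceutical requirements: activities above 5.5,
solubility above -3.5 log mol/L, permeability above 0.4, metabolic
stability above 45%, toxicity class below 3, QED above 0.6 and SAScore
below 4.
"""

from pmcts.pareto import SuccessCriterion

__all__ = ["DUAL_INHIBITOR_CRITERIA", "EXAMPLE_CANDIDATE_RECORDS"]

DUAL_INHIBITOR_CRITERIA = [
    SuccessCriterion("EGFR", 5.5, "gt"),
    SuccessCriterion("HER2", 5.5, "gt"),
    SuccessCriterion("Solubility", -3.5, "gt"),
    SuccessCriterion("Permeability", 0.4, "gt"),
    SuccessCriterion("Metabolic_stability", 45.0, "gt"),
    SuccessCriterion("Toxicity", 3.0, "lt"),
    SuccessCriterion("QED", 0.6, "gt"),
    SuccessCriterion("SAScore", 4.0, "lt"),
]

_FIELDS = (
    "EGFR", "HER2", "Solubility", "Permeability",
    "Metabolic_stability", "Toxicity", "QED", "SAScore",
)

_ROWS = [
    (7.57, 6.73, -2.17, 0.91, 63.70, 2.45, 0.64, 3.26),
    (7.64, 6.43, -3.45, 1.19, 70.02, 2.94, 0.73, 2.81),
    (7.48, 6.75, -3.42, 1.48, 67.38, 2.82, 0.71, 2.85),
    (7.69, 5.82, -2.29, 1.36, 66.47, 2.21, 0.81, 3.24),
    (7.04, 7.01, -2.55, 0.87, 74.66, 2.57, 0.71, 2.56),
    (7.12, 6.88, -2.59, 0.42, 71.20, 2.99, 0.78, 2.86),
    (6.60, 7.10, -2.62, 0.45, 63.46, 2.18, 0.67, 2.62),
    (6.87, 6.62, -2.09, 1.23, 64.55, 2.44, 0.74, 3.17),
    (6.01, 7.26, -2.50, 0.80, 58.30, 2.30, 0.70, 2.49),
    (7.20, 6.17, -1.90, 1.10, 61.18, 2.85, 0.76, 3.36),
]

EXAMPLE_CANDIDATE_RECORDS = [dict(zip(_FIELDS, row)) for row in _ROWS]
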