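"""Chemical category vocabulary and mass-transformation constants.

The ten category codes cover the mother-nucleus classes of rhubarb
(Rheum) chemistry; ``Others`` collects components that match no class.
Neutral-loss masses are monoisotopic residue masses in Da: attaching a
hexose to an aglycone adds C6H10O5, attaching a galloyl group adds C7H4O4
(gallic acid minus water).
"""

from __future__ import annotations

#: proton mass used for [M-H]-/[M+H]+ adduct arithmetic; the electron mass
#: (~0.5 mDa) is neglected, far below any ppm tolerance used here.
PROTON = 1.00728

#: monoisotopic mass of a hexose residue (C6H10O5)
HEXOSE = 162.052824

#: monoisotopic mass of a galloyl residue (C7H4O4)
GALLOYL = 152.010959

#: registered neutral-loss transformations, extensible by the caller
DEFAULT_LOSSES: dict[str, float] = {"hexose": HEXOSE, "galloyl": GALLOYL}

#: category code -> human description, in conventional order
CATEGORIES: dict[str, str] = {
    "Rh-01": "free anthraquinones",
    "Rh-02": "combined anthraquinones",
    "Rh-03": "anthranones and their dimers",
    "Rh-04": "flavanols and their polymers",
    "Rh-05": "gallic acid and gallotannins",
    "Rh-06": "stilbene glycosides",
    "Rh-07": "naphthalene glycosides",
    "Rh-08": "butyrylbenzenes and their glycosides",
    "Rh-09": "chromones",
    "Rh-10": "flavonoid (flavonol) glycosides",
    "Others": "unassigned",
}

CATEGORY_CODES: list[str] = [c for c in CATEGORIES if c != "Others"]

#: category that a neutral-loss product belongs to, keyed by the matched
#: aglycone's category.  Losing a hexose from a combined anthraquinone
#: yields a free anthraquinone, so an unknown whose stripped mass matches a
#: free anthraquinone is a combined one; for the remaining classes the
#: glycoside and its aglycone share a category.
GLYCOSIDE_CATEGORY: dict[str, str] = {"Rh-01": "Rh-02"}


def glycoside_category(aglycone_category: str) -> str:
    """Category assigned to a component that sheds a registered loss down to
    a reference in *aglycone_category*."""
    return GLYCOSIDE_CATEGORY.get(aglycone_category, aglycone_category)
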