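"""Small published reference tables bundled for worked examples and checks."""

from __future__ import annotations

import pandas as pd

from .categories import CATEGORY_CODES

__all__ = ["rhubarb_category_contributions", "rhubarb_group_labels"]

# Published per-efficacy category contribution sums (decision weights > 0.01)
# for the five classical rhubarb efficacies E1-E5.  Used as the worked
# aggregation example: grand totals and ranks are *recomputed* from these
# per-effect values, never stored.
_CONTRIB = {
    #            E1       E2       E3       E4       E5
    "Rh-01": (0.04255, 0.01052, 0.01023, 0.02507, 0.03212),
    "Rh-02": (0.05621, 0.06679, 0.11795, 0.09344, 0.10226),
    "Rh-03": (0.02866, 0.01069, 0.03469, 0.03579, 0.01110),
    "Rh-04": (0.05001, 0.06684, 0.04032, 0.04748, 0.06193),
    "Rh-05": (0.01059, 0.01060, 0.05335, 0.02418, 0.01423),
    "Rh-06": (0.01966, 0.03350, 0.02689, 0.02719, 0.03299),
    "Rh-07": (0.01925, 0.01101, 0.01243, 0.02694, 0.01023),
    "Rh-08": (0.01014, 0.02084, 0.02138, 0.03495, 0.02452),
    "Rh-09": (0.03611, 0.02220, 0.02266, 0.02550, 0.01157),
    "Rh-10": (0.00000, 0.01005, 0.01060, 0.01113, 0.00000),
}


def rhubarb_category_contributions() -> pd.DataFrame:
    """Published per-effect category contribution values (categories x E1-E5)."""
    df = pd.DataFrame.from_dict(_CONTRIB, orient="index",
                                columns=["E1", "E2", "E3", "E4", "E5"])
    df.index.name = "category"
    return df.loc[CATEGORY_CODES]


def rhubarb_group_labels() -> list[str]:
    """The 18 extraction-group labels of the standard design."""
    from .simulate import default_conditions

    return [c.group_label for c in default_conditions()]
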