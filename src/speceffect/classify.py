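"""Fuzzy chemical classification of LC-MS components by mass rules.

Components are assigned to chemical category groups without confirming
exact structures.  The decision cascade per component:

1. exact reference match — the neutral mass (from the observed adduct m/z)
   matches a reference compound within the ppm tolerance;
2. neutral-loss rule — the neutral mass minus a registered loss (hexose
   162.0528, galloyl 152.0110; chains of up to two units) matches a
   reference aglycone, in which case the component is placed in the
   conjugate category paired to the aglycone's class;
3. category-network node — the mass sits on a node of a compound-group
   network within tolerance;
4. otherwise ``Others`` with evidence ``unassigned``.

Ties within a rule are broken by smallest absolute ppm error, then by
confirmed-reference status, then lexically by name.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .categories import DEFAULT_LOSSES, PROTON, glycoside_category

__all__ = [
    "ppm_error",
    "classify_component",
    "classify_peak_table",
    "build_category_network",
    "summarize_classification",
    "FuzzyCategoryClassifier",
    "CategoryNetwork",
]

ADDUCT_SHIFT = {"[M-H]-": -PROTON, "[M+H]+": +PROTON}


def ppm_error(observed_mz: float, ref_mass: float, adduct: str = "[M-H]-") -> float:
    """Signed ppm deviation of an observed adduct m/z from theory.

    ``ref_mass`` is the neutral monoisotopic mass; the theoretical m/z is
    ``ref_mass +- 1.00728`` depending on the adduct.
    """
    if observed_mz <= 0 or ref_mass <= 0:
        raise ValueError("masses must be positive")
    if adduct not in ADDUCT_SHIFT:
        raise ValueError(f"unknown adduct {adduct!r}")
    theo = ref_mass + ADDUCT_SHIFT[adduct]
    return (observed_mz - theo) / theo * 1e6


def _neutral_mass(feature) -> float:
    """Neutral monoisotopic mass from whichever ion mode is observed.

    Negative mode is preferred when both are present (the classic mode for
    the phenolics this pipeline targets)."""
    mz_neg = feature.get("mz_neg")
    if mz_neg is not None and np.isfinite(mz_neg):
        return float(mz_neg) + PROTON
    mz_pos = feature.get("mz_pos")
    if mz_pos is not None and np.isfinite(mz_pos):
        return float(mz_pos) - PROTON
    raise ValueError("feature has no observed m/z")


def _loss_combinations(losses: dict[str, float], max_chain: int = 2):
    """All nonempty loss multisets up to the chain limit, largest first."""
    out = []
    names = sorted(losses)
    for k in range(1, max_chain + 1):
        for combo in itertools.combinations_with_replacement(names, k):
            out.append(("+".join(combo), sum(losses[c] for c in combo)))
    return out


def _best_match(mass: float, refset: pd.DataFrame, tol_ppm: float):
    """Reference row with the smallest |ppm| within tolerance, or None."""
    ref_mass = refset["monoisotopic_mass"].to_numpy(dtype=float)
    ppm = (mass - ref_mass) / ref_mass * 1e6
    ok = np.abs(ppm) <= tol_ppm
    if not ok.any():
        return None, np.nan
    cand = refset.loc[ok].copy()
    cand["_ppm"] = ppm[ok]
    confirmed = cand.get("is_confirmed_reference", pd.Series(False, index=cand.index))
    cand["_key_abs"] = np.abs(cand["_ppm"])
    cand = cand.assign(_conf=~confirmed.astype(bool))
    cand = cand.sort_values(["_key_abs", "_conf", "name"], kind="mergesort")
    best = cand.iloc[0]
    return best, float(best["_ppm"])


@dataclass
class CategoryNetwork:
    """Mass-difference graph of one compound category."""

    category: str
    nodes: pd.DataFrame  # name, mass
    edges: list[tuple[str, str, str, float]] = field(default_factory=list)  # (a, b, loss, Da)

    @property
    def node_masses(self) -> np.ndarray:
        return self.nodes["mass"].to_numpy(dtype=float)


def build_category_network(
    refset: pd.DataFrame, losses: dict[str, float] | None = None, tol: float = 0.01
) -> list[CategoryNetwork]:
    """Per-category graphs whose edges connect member masses differing by a
    registered transformation within ``tol`` Da."""
    if refset is None or len(refset) == 0:
        raise ValueError("empty reference set")
    losses = DEFAULT_LOSSES if losses is None else losses
    nets = []
    for cat, grp in refset.groupby("category", sort=True):
        nodes = grp[["name", "monoisotopic_mass"]].rename(
            columns={"monoisotopic_mass": "mass"}).reset_index(drop=True)
        edges = []
        m = nodes["mass"].to_numpy(dtype=float)
        for a in range(len(nodes)):
            for b in range(len(nodes)):
                if a == b:
                    continue
                diff = m[b] - m[a]
                for loss_name, loss_mass in losses.items():
                    if abs(diff - loss_mass) <= tol:
                        edges.append((nodes["name"][a], nodes["name"][b], loss_name, diff))
        nets.append(CategoryNetwork(category=cat, nodes=nodes, edges=edges))
    return nets


def classify_component(
    feature,
    refset: pd.DataFrame,
    tol_ppm: float = 10.0,
    losses: dict[str, float] | None = None,
    networks: list[CategoryNetwork] | None = None,
) -> dict:
    """Assign one component to a category via the fuzzy decision cascade.

    ``feature`` is a mapping with ``component_id`` and at least one of
    ``mz_neg``/``mz_pos``.  Returns a dict with ``component_id, category,
    evidence, matched_reference, ppm_error``.
    """
    if refset is None or len(refset) == 0:
        raise ValueError("empty reference set")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    losses = DEFAULT_LOSSES if losses is None else losses
    mass = _neutral_mass(feature)
    cid = feature.get("component_id", "")

    # (1) exact reference match
    best, ppm = _best_match(mass, refset, tol_ppm)
    if best is not None:
        return {"component_id": cid, "category": best["category"],
                "evidence": "exact_reference_match",
                "matched_reference": best["name"], "ppm_error": ppm}

    # (2) neutral-loss rule, shortest chains first
    for loss_label, loss_mass in _loss_combinations(losses):
        stripped = mass - loss_mass
        if stripped <= 0:
            continue
        best, ppm = _best_match(stripped, refset, tol_ppm)
        if best is not None:
            return {"component_id": cid,
                    "category": glycoside_category(best["category"]),
                    "evidence": "neutral_loss_rule",
                    "matched_reference": f"{best['name']} (-{loss_label})",
                    "ppm_error": ppm}

    # (3) category-network node
    if networks:
        hits = []
        for net in networks:
            node_mass = net.node_masses
            if node_mass.size == 0:
                continue
            ppm_all = (mass - node_mass) / node_mass * 1e6
            j = int(np.argmin(np.abs(ppm_all)))
            if abs(ppm_all[j]) <= tol_ppm:
                hits.append((abs(ppm_all[j]), net.category,
                             str(net.nodes["name"][j]), float(ppm_all[j])))
        if hits:
            hits.sort()
            _, cat, name, ppm = hits[0]
            return {"component_id": cid, "category": cat,
                    "evidence": "mass_network_link",
                    "matched_reference": name, "ppm_error": ppm}

    return {"component_id": cid, "category": "Others", "evidence": "unassigned",
            "matched_reference": "", "ppm_error": np.nan}


class FuzzyCategoryClassifier(BaseEstimator):
    """Rule-based component classifier over a reference compound set.

    Follows the scikit-learn estimator protocol: ``fit`` ingests the
    reference database and builds the category networks, ``predict`` maps a
    feature table (DataFrame with ``component_id, mz_neg``/``mz_pos``) to an
    assignments DataFrame.

    Parameters
    ----------
    tol_ppm : mass-match tolerance in parts per million (default 10).
    losses : registered neutral-loss table ``{name: Da}``; hexose and
        galloyl by default, chains of up to two units are tried.
    rt_window : optional retention-time window (min); when set, exact
        matches are additionally required to fall within this window of a
        same-category confirmed reference RT if reference RTs are present.
    """

    def __init__(self, tol_ppm: float = 10.0, losses: dict[str, float] | None = None,
                 rt_window: float | None = None):
        self.tol_ppm = tol_ppm
        self.losses = losses
        self.rt_window = rt_window

    def fit(self, refset: pd.DataFrame, y=None):
        if refset is None or len(refset) == 0:
            raise ValueError("empty reference set")
        if self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be positive")
        self.refset_ = refset.reset_index(drop=True)
        self.networks_ = build_category_network(
            self.refset_, DEFAULT_LOSSES if self.losses is None else self.losses)
        return self

    def predict(self, features: pd.DataFrame) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "refset_")
        rows = []
        for _, feat in features.iterrows():
            rec = classify_component(feat, self.refset_, tol_ppm=self.tol_ppm,
                                     losses=self.losses, networks=self.networks_)
            if (self.rt_window is not None and rec["evidence"] != "unassigned"
                    and "rt" in features.columns and "rt" in self.refset_.columns):
                cat_rts = self.refset_.loc[
                    self.refset_["category"] == rec["category"], "rt"].dropna()
                if len(cat_rts) and np.min(np.abs(cat_rts - feat["rt"])) > self.rt_window:
                    rec = {**rec, "category": "Others", "evidence": "unassigned",
                           "matched_reference": "", "ppm_error": np.nan}
            rows.append(rec)
        return pd.DataFrame(rows)


def classify_peak_table(features: pd.DataFrame, refset: pd.DataFrame,
                        tol_ppm: float = 10.0,
                        losses: dict[str, float] | None = None) -> pd.DataFrame:
    """Classify every component of a feature table (functional wrapper)."""
    return FuzzyCategoryClassifier(tol_ppm=tol_ppm, losses=losses).fit(refset).predict(features)


def summarize_classification(assignments: pd.DataFrame) -> pd.Series:
    """Per-category component counts (all vocabulary categories included)."""
    from .categories import CATEGORIES

    counts = pd.Series(0, index=pd.Index(list(CATEGORIES), name="category"), dtype=int)
    if len(assignments):
        got = assignments["category"].value_counts()
        for cat, n in got.items():
            if cat not in counts.index:
                counts.loc[cat] = 0
            counts.loc[cat] += int(n)
    return counts
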