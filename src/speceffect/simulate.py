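"""Synthetic data generators with planted ground truth.

Every downstream stage of the pipeline (fuzzy classification, effect
integration, quantity-effect network, decision-weight attribution) is
exercised against data produced here, so each generator records the truth
it planted: category labels for reference compounds and peak-table
components, latent group scores for index panels, and driver identities
for effect tables.

All generators are pure functions of their arguments including ``seed``.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics.mass import calculate_mass

from .categories import CATEGORY_CODES, GALLOYL, HEXOSE, PROTON

__all__ = [
    "ExtractionCondition",
    "PlantedModel",
    "IndexPanelSpec",
    "PeakTable",
    "EffectTable",
    "IndexPanel",
    "default_conditions",
    "generate_reference_db",
    "generate_peak_table",
    "generate_component_samples",
    "generate_index_panel",
    "generate_planted_effects",
]

# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ExtractionCondition:
    """One extraction group: an ethanol-water fraction and a decoction length."""

    ethanol_fraction: float
    duration_class: str  # "short" | "long"
    group_label: str

    def __post_init__(self):
        if not 0.0 <= self.ethanol_fraction <= 1.0:
            raise ValueError(f"ethanol_fraction must be in [0,1], got {self.ethanol_fraction}")
        if self.duration_class not in ("short", "long"):
            raise ValueError(f"duration_class must be 'short' or 'long', got {self.duration_class!r}")


#: the nine ethanol-water fractions of the standard 18-group design
DEFAULT_FRACTIONS = (0.0, 0.10, 0.20, 0.35, 0.50, 0.65, 0.80, 0.90, 1.0)


def _fraction_label(f: float) -> str:
    if f == 0.0:
        return "water"
    if f == 1.0:
        return "ethanol"
    return f"{int(round(f * 100))}% EW"


def default_conditions() -> list[ExtractionCondition]:
    """The 18 standard extraction groups: 9 ethanol fractions x {short, long}."""
    out = []
    for f in DEFAULT_FRACTIONS:
        for dur, tag in (("short", "S"), ("long", "L")):
            out.append(ExtractionCondition(f, dur, f"{_fraction_label(f)}-{tag}"))
    return out


@dataclass(frozen=True)
class PlantedModel:
    """Sparse ground-truth quantity-effect model.

    The effect is ``link(sum_d w_d * z_d) + N(0, noise_sd)`` where ``z_d`` is
    the min-max normalized content of driver component ``d``.
    """

    driver_indices: tuple[int, ...]
    driver_weights: tuple[float, ...]
    noise_sd: float = 0.0
    link: str = "linear"  # "linear" | "saturating"

    def __post_init__(self):
        if len(self.driver_indices) != len(self.driver_weights):
            raise ValueError("driver_indices and driver_weights must have equal length")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.link not in ("linear", "saturating"):
            raise ValueError(f"unknown link {self.link!r}")


@dataclass(frozen=True)
class IndexPanelSpec:
    """Shape and noise model of a multi-indicator pharmacodynamic panel."""

    loading_matrix: np.ndarray  # indicators x factors
    n_animals_per_group: int = 8
    factor_variance_props: np.ndarray | None = None  # per-factor, in (0,1]
    direction: np.ndarray | None = None  # per-indicator +-1
    noise_sd: float = 0.1
    effect_label: str = "E1"

    @property
    def n_indicators(self) -> int:
        return int(np.asarray(self.loading_matrix).shape[0])

    @property
    def n_factors(self) -> int:
        return int(np.asarray(self.loading_matrix).shape[1])

    def validate(self) -> None:
        L = np.asarray(self.loading_matrix, dtype=float)
        if L.ndim != 2 or L.shape[0] < 2:
            raise ValueError("loading_matrix must be 2-D with >= 2 indicators")
        if np.any(np.all(L == 0, axis=1)):
            raise ValueError("every indicator must load on at least one factor")
        if self.n_animals_per_group < 1:
            raise ValueError("n_animals_per_group must be >= 1")
        if self.factor_variance_props is not None:
            p = np.asarray(self.factor_variance_props, dtype=float)
            if p.shape != (L.shape[1],) or np.any(p <= 0) or np.any(p > 1):
                raise ValueError("factor_variance_props must be per-factor proportions in (0,1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


# ---------------------------------------------------------------------------
# reference compound database

# Per-category construction recipe: aglycone scaffolds as elemental formulas
# plus the residue (if any) attached to build the category's conjugates.
# Scaffolds are the classic high-content constituents of each class, so the
# mass arithmetic of the synthetic database mirrors real rhubarb chemistry.
_CH2 = Counter({"C": 1, "H": 2})
_O = Counter({"O": 1})
_HEXOSE_RES = Counter({"C": 6, "H": 10, "O": 5})
_GALLOYL_RES = Counter({"C": 7, "H": 4, "O": 4})

_SCAFFOLDS: dict[str, dict] = {
    "Rh-01": {"bases": [("emodin", "C15H10O5"), ("chrysophanol", "C15H10O4"),
                        ("rhein", "C15H8O6"), ("physcion", "C16H12O5")],
              "attach": None},
    # combined anthraquinones are hexosides of the free ones (Rh-01 members)
    "Rh-02": {"bases": [], "attach": "hexose", "aglycone_source": "Rh-01"},
    "Rh-03": {"bases": [("sennoside-like dianthrone", "C42H38O20")], "attach": None},
    "Rh-04": {"bases": [("catechin", "C15H14O6"), ("procyanidin-dimer", "C30H26O12")],
              "attach": "galloyl"},
    "Rh-05": {"bases": [("gallic acid", "C7H6O5")], "attach": "hexose"},
    "Rh-06": {"bases": [("resveratrol", "C14H12O3")], "attach": "hexose"},
    "Rh-07": {"bases": [("torachrysone", "C14H12O4")], "attach": "hexose"},
    "Rh-08": {"bases": [("hydroxyphenylbutanone", "C10H12O2")], "attach": "hexose"},
    "Rh-09": {"bases": [("acetylhydroxymethylchromone", "C12H10O4")], "attach": None},
    "Rh-10": {"bases": [("quercetin", "C15H10O7")], "attach": "hexose"},
}

_RESIDUES = {"hexose": (_HEXOSE_RES, HEXOSE), "galloyl": (_GALLOYL_RES, GALLOYL)}


def _parse_formula(s: str) -> Counter:
    import re

    out: Counter = Counter()
    for el, n in re.findall(r"([A-Z][a-z]?)(\d*)", s):
        if el:
            out[el] += int(n) if n else 1
    return out


def _format_formula(c: Counter) -> str:
    order = ["C", "H"] + sorted(k for k in c if k not in ("C", "H"))
    return "".join(f"{el}{c[el] if c[el] != 1 else ''}" for el in order if c[el])


def _mono_mass(c: Counter) -> float:
    return float(calculate_mass(formula=_format_formula(c)))


#: deterministic formula tweaks used to resolve cross-category isomer
#: collisions while keeping chemistry plausible (hydrogenation / oxidation)
_H2 = Counter({"H": 2})
_TWEAKS = [Counter()] + [Counter({"H": 2 * k}) for k in (1, 2, 3)] \
    + [_O + Counter({"H": 2 * k}) for k in (0, 1, 2)] \
    + [_CH2 + Counter({"H": 2 * k}) for k in (1, 2, 3)]

#: minimum cross-category mass separation enforced at construction; several
#: times the default 10 ppm matching tolerance so fuzzy classification of
#: clean masses is unambiguous by design
_MIN_SEP_PPM = 30.0


def generate_reference_db(n_per_category: int = 3, seed: int = 0) -> pd.DataFrame:
    """Generate a categorized reference compound set.

    Returns a DataFrame with columns ``name, formula, monoisotopic_mass,
    category, signature_losses, is_confirmed_reference, aglycone_name`` and
    exactly ``n_per_category`` compounds in each of the ten categories.
    Conjugates (hexosides, galloyl esters) are built by attaching residue
    formulas to aglycones that are themselves in the set, so every
    neutral-loss rule is satisfiable by construction: a hexoside's mass is
    its aglycone's mass + 162.0528 exactly.  Compounds of different
    categories are kept >= 30 ppm apart in mass (isomers are allowed within
    a category); colliding variants are nudged by H2/O/CH2 units.
    """
    if n_per_category < 1:
        raise ValueError("n_per_category must be >= 1")
    rng = np.random.default_rng(seed)
    from .categories import glycoside_category

    rows: list[dict] = []
    members: dict[str, list[dict]] = {}
    occupied: list[tuple[float, str]] = []  # (mass, category) incl. projections

    def conflicts(implied) -> bool:
        for m, c in implied:
            for mo, co in occupied:
                if c != co and abs(m - mo) / mo * 1e6 < _MIN_SEP_PPM:
                    return True
        return False

    def implied_set(cat, formula, project_residues):
        m = _mono_mass(formula)
        out = [(m, cat)]
        conj_cat = glycoside_category(cat)
        for res in project_residues:
            rm = _RESIDUES[res][1]
            out.append((m + rm, conj_cat))
            out.append((m + 2 * rm, conj_cat))
        return out

    def place_aglycone(cat, formula, project_residues):
        """Resolve cross-category collisions by trying formula tweaks."""
        for tweak in _TWEAKS:
            f = formula + tweak if tweak else formula
            implied = implied_set(cat, f, project_residues)
            if not conflicts(implied):
                occupied.extend(implied)
                return f
        # give up on separation; register as-is (classification tests audit)
        occupied.extend(implied_set(cat, formula, project_residues))
        return formula

    def add(cat, name, formula, aglycone=None, attach=None, n_units=0):
        losses = [_RESIDUES[attach][1]] * n_units if attach else []
        rows.append({
            "name": name,
            "formula": _format_formula(formula),
            "monoisotopic_mass": _mono_mass(formula),
            "category": cat,
            "signature_losses": ";".join(f"{m:.6f}" for m in losses),
            "is_confirmed_reference": bool(rng.random() < 0.3),
            "aglycone_name": aglycone or "",
        })
        members.setdefault(cat, []).append({"formula": formula, "name": name})

    # pass 1: aglycone variants for every category with its own bases
    for cat in CATEGORY_CODES:
        recipe = _SCAFFOLDS[cat]
        bases = recipe["bases"]
        if not bases:
            continue
        attach = recipe["attach"]
        projections = ["hexose"] if cat == "Rh-01" else ([attach] if attach else [])
        # split the quota between aglycones and conjugates when attachable
        n_conj = n_per_category // 2 if attach else 0
        n_agly = n_per_category - n_conj
        agly_list = []
        for i in range(n_agly):
            base_name, base_formula = bases[i % len(bases)]
            f = _parse_formula(base_formula)
            for k in range(i // len(bases)):
                f = f + (_CH2 if rng.random() < 0.6 else _O)
            f = place_aglycone(cat, f, projections)
            name = base_name if i < len(bases) else f"{base_name} analog {i}"
            add(cat, name, f)
            agly_list.append((name, f))
        if attach:
            res_formula = _RESIDUES[attach][0]
            for i in range(n_conj):
                agly_name, agly_f = agly_list[i % len(agly_list)]
                n_units = min(1 + i // len(agly_list), 2)  # chains <= 2
                f = agly_f.copy()
                for _ in range(n_units):
                    f = f + res_formula
                suffix = attach if n_units == 1 else f"di{attach}"
                add(cat, f"{agly_name} {suffix}", f,
                    aglycone=agly_name, attach=attach, n_units=n_units)

    # pass 2: categories whose conjugates borrow aglycones from another class
    for cat in CATEGORY_CODES:
        recipe = _SCAFFOLDS[cat]
        if recipe["bases"]:
            continue
        src = recipe["aglycone_source"]
        res_name = recipe["attach"]
        res_formula = _RESIDUES[res_name][0]
        src_members = members[src]
        for i in range(n_per_category):
            agly = src_members[i % len(src_members)]
            n_units = min(1 + i // len(src_members), 2)
            f = agly["formula"].copy()
            for _ in range(n_units):
                f = f + res_formula
            suffix = f"{n_units}x{res_name}" if n_units > 1 else res_name
            add(cat, f"{agly['name']} {suffix}", f,
                aglycone=agly["name"], attach=res_name, n_units=n_units)

    return pd.DataFrame(rows).reset_index(drop=True)


# ---------------------------------------------------------------------------
# peak table

#: typical polarity optimum (ethanol fraction of maximal extraction yield)
#: per category; polar tannins elute best in water, anthraquinone aglycones
#: in strong ethanol.
_CATEGORY_OPTIMUM = {
    "Rh-01": 0.90, "Rh-02": 0.50, "Rh-03": 0.35, "Rh-04": 0.20, "Rh-05": 0.10,
    "Rh-06": 0.55, "Rh-07": 0.60, "Rh-08": 0.40, "Rh-09": 0.70, "Rh-10": 0.45,
    "Others": 0.50,
}


@dataclass
class PeakTable:
    """Components x samples relative-content matrix with m/z metadata.

    ``features`` carries one row per component (id, RT, observed m/z in both
    ion modes, and the planted truth columns ``true_category`` and
    ``monoisotopic_mass``).  ``contents`` is indexed by component id with one
    column per injection, labelled ``"<group>:r<k>"``.
    """

    features: pd.DataFrame
    contents: pd.DataFrame
    conditions: list[ExtractionCondition] = field(default_factory=list)

    @property
    def group_labels(self) -> list[str]:
        return [c.group_label for c in self.conditions]

    def group_means(self) -> pd.DataFrame:
        """Average replicate injections: groups x components matrix."""
        groups = self.contents.columns.str.rsplit(":", n=1).str[0]
        return self.contents.T.groupby(groups, sort=False).mean()

    def to_csv(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.features.to_csv(d / "features.csv", index=False)
        self.contents.to_csv(d / "contents.csv")
        meta = [{"ethanol_fraction": c.ethanol_fraction,
                 "duration_class": c.duration_class,
                 "group_label": c.group_label} for c in self.conditions]
        (d / "conditions.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, directory: str | Path) -> "PeakTable":
        d = Path(directory)
        features = pd.read_csv(d / "features.csv")
        contents = pd.read_csv(d / "contents.csv", index_col=0)
        conds = [ExtractionCondition(**m) for m in json.loads((d / "conditions.json").read_text())]
        return cls(features, contents, conds)


def generate_peak_table(
    conditions: list[ExtractionCondition],
    refset: pd.DataFrame,
    n_replicates: int = 3,
    seed: int = 0,
    noise_sd: float = 0.1,
    mz_ppm_sd: float = 2.0,
    n_components: int | None = None,
    optimum_jitter_sd: float = 0.15,
) -> PeakTable:
    """Simulate an LC-MS peak table over extraction conditions.

    Each component derives from one reference compound; its content is a
    Gaussian bump over ethanol fraction (optimum = the category's polarity
    optimum plus per-component jitter), scaled by a per-component long-
    decoction factor, with multiplicative lognormal replicate noise of
    sigma ``noise_sd``.  Observed m/z values are the theoretical [M+H]+ /
    [M-H]- adduct masses perturbed by ``mz_ppm_sd`` ppm of Gaussian mass
    error (0 gives exact adduct masses).  Contents are nonnegative by
    construction.
    """
    if len(conditions) < 2:
        raise ValueError("need at least 2 extraction conditions")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if refset is None or len(refset) == 0:
        raise ValueError("empty reference set")
    rng = np.random.default_rng(seed)

    if n_components is not None and n_components < len(refset):
        pick = rng.choice(len(refset), size=n_components, replace=False)
        pick.sort()
        src = refset.iloc[pick].reset_index(drop=True)
    elif n_components is not None and n_components > len(refset):
        # sample with replacement: repeated compounds model in-source variants
        pick = np.sort(rng.choice(len(refset), size=n_components, replace=True))
        src = refset.iloc[pick].reset_index(drop=True)
    else:
        src = refset.reset_index(drop=True)

    n = len(src)
    ids = [f"C{i + 1:03d}" for i in range(n)]
    mass = src["monoisotopic_mass"].to_numpy(dtype=float)
    ppm_err = rng.normal(0.0, mz_ppm_sd, size=(n, 2)) * 1e-6 if mz_ppm_sd > 0 else np.zeros((n, 2))
    mz_neg = (mass - PROTON) * (1.0 + ppm_err[:, 0])
    mz_pos = (mass + PROTON) * (1.0 + ppm_err[:, 1])

    cat = src["category"].to_numpy()
    mu = np.array([_CATEGORY_OPTIMUM.get(c, 0.5) for c in cat])
    mu = np.clip(mu + rng.normal(0.0, optimum_jitter_sd, n), 0.0, 1.0)
    width = rng.uniform(0.15, 0.35, n)
    amp = 10.0 ** rng.uniform(4.0, 6.0, n)  # peak-area scale
    long_mult = np.exp(rng.normal(np.log(1.2), 0.3, n))

    features = pd.DataFrame({
        "component_id": ids,
        "name": src["name"].to_numpy(),
        "rt": np.round(rng.uniform(0.5, 25.0, n), 2),
        "mz_pos": mz_pos,
        "mz_neg": mz_neg,
        "true_category": cat,
        "monoisotopic_mass": mass,
    })

    cols, data = [], []
    for cond in conditions:
        base = amp * np.exp(-0.5 * ((cond.ethanol_fraction - mu) / width) ** 2)
        if cond.duration_class == "long":
            base = base * long_mult
        for r in range(1, n_replicates + 1):
            noise = np.exp(rng.normal(0.0, noise_sd, n)) if noise_sd > 0 else 1.0
            cols.append(f"{cond.group_label}:r{r}")
            data.append(base * noise)
    contents = pd.DataFrame(np.column_stack(data), index=pd.Index(ids, name="component_id"),
                            columns=cols)
    return PeakTable(features=features, contents=contents, conditions=list(conditions))


# ---------------------------------------------------------------------------
# pharmacodynamic index panels


@dataclass
class IndexPanel:
    """Animals x indicators pharmacodynamic panel for one efficacy."""

    effect_label: str
    values: pd.DataFrame  # animals x indicators
    group_labels: pd.Series  # per animal
    indicator_directions: np.ndarray  # per indicator, +-1
    truth: dict = field(default_factory=dict)

    @property
    def indicator_names(self) -> list[str]:
        return list(self.values.columns)

    def to_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "group", self.group_labels.to_numpy())
        out.to_csv(path, index=False)
        sidecar = Path(path).with_suffix(".directions.json")
        sidecar.write_text(json.dumps({
            "effect_label": self.effect_label,
            "directions": np.asarray(self.indicator_directions).tolist(),
            "truth": {k: (np.asarray(v).tolist() if not np.isscalar(v) else v)
                      for k, v in self.truth.items()},
        }, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "IndexPanel":
        df = pd.read_csv(path)
        sidecar = json.loads(Path(path).with_suffix(".directions.json").read_text())
        groups = df.pop("group")
        return cls(sidecar["effect_label"], df, groups,
                   np.asarray(sidecar["directions"], dtype=float), sidecar.get("truth", {}))


def generate_index_panel(
    spec: IndexPanelSpec,
    group_latent_scores: np.ndarray,
    seed: int = 0,
    group_names: list[str] | None = None,
) -> IndexPanel:
    """Simulate a per-animal indicator panel from group-level latent scores.

    ``group_latent_scores`` is either ``(n_groups,)`` (the score of factor 1;
    remaining factors have mean 0) or ``(n_groups, n_factors)``.  Every
    animal's factor-score vector equals its group's latent vector; indicator
    values are ``direction * (loadings @ scores) + N(0, noise_sd)``, so in
    the zero-noise single-factor unit-loading case every indicator equals
    the group latent score exactly.

    The planted per-group composite (variance-proportion-weighted mean of
    the latent factors) is stored in ``truth["group_composite"]``.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    L = np.asarray(spec.loading_matrix, dtype=float)
    p, q = L.shape

    latent = np.asarray(group_latent_scores, dtype=float)
    if latent.ndim == 1:
        full = np.zeros((latent.shape[0], q))
        full[:, 0] = latent
        latent = full
    if latent.ndim != 2 or latent.shape[1] != q:
        raise ValueError("group_latent_scores must be (n_groups,) or (n_groups, n_factors)")
    G = latent.shape[0]
    if group_names is None:
        group_names = [f"G{g + 1:02d}" for g in range(G)]
    if len(group_names) != G:
        raise ValueError("group_names length must match the number of groups")

    direction = (np.ones(p) if spec.direction is None
                 else np.asarray(spec.direction, dtype=float))
    if direction.shape != (p,):
        raise ValueError("direction must have one sign per indicator")

    n = spec.n_animals_per_group
    scores = np.repeat(latent, n, axis=0)  # (G*n, q)
    vals = scores @ L.T
    if spec.noise_sd > 0:
        vals = vals + rng.normal(0.0, spec.noise_sd, vals.shape)
    vals = vals * direction

    props = (np.ones(q) / q if spec.factor_variance_props is None
             else np.asarray(spec.factor_variance_props, dtype=float))
    truth_composite = latent @ (props / props.sum())

    values = pd.DataFrame(vals, columns=[f"ind{j + 1:02d}" for j in range(p)])
    groups = pd.Series(np.repeat(group_names, n), name="group")
    return IndexPanel(
        effect_label=spec.effect_label,
        values=values,
        group_labels=groups,
        indicator_directions=direction,
        truth={"group_composite": truth_composite, "latent": latent,
               "group_names": list(group_names)},
    )


# ---------------------------------------------------------------------------
# planted quantity-effect models


@dataclass
class EffectTable:
    """Per-group effect values with the planted model that produced them."""

    effect_label: str
    values: pd.Series  # indexed by group label
    planted: PlantedModel | None = None

    def to_csv(self, path: str | Path) -> None:
        self.values.rename("effect").to_csv(path, index_label="group")
        if self.planted is not None:
            Path(path).with_suffix(".planted.json").write_text(json.dumps({
                "effect_label": self.effect_label,
                "driver_indices": list(self.planted.driver_indices),
                "driver_weights": list(self.planted.driver_weights),
                "noise_sd": self.planted.noise_sd,
                "link": self.planted.link,
            }, indent=1))


def generate_component_samples(n_samples: int = 200, n_components: int = 108,
                               seed: int = 0, dispersion: float = 0.5) -> pd.DataFrame:
    """Samples x components content matrix with independent variation.

    Each component's content is lognormal around its own median (median
    drawn over the peak-area scale, sigma = ``dispersion``), independently
    across samples and components.  This is the design used for importance-
    recovery experiments: unlike the extraction-condition-driven peak table,
    every component varies independently, so a planted driver is
    identifiable in principle.  (Under the condition-structured design,
    components of one category are nearly collinear and no importance
    measure can separate them; see the package methods notes.)
    """
    if n_samples < 2 or n_components < 1:
        raise ValueError("need >= 2 samples and >= 1 component")
    rng = np.random.default_rng(seed)
    median = 10.0 ** rng.uniform(4.0, 6.0, n_components)
    contents = median * np.exp(rng.normal(0.0, dispersion, (n_samples, n_components)))
    return pd.DataFrame(contents,
                        index=pd.Index([f"S{i + 1:03d}" for i in range(n_samples)], name="sample"),
                        columns=[f"C{i + 1:03d}" for i in range(n_components)])


def _minmax_columns(X: np.ndarray) -> np.ndarray:
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    Z = (X - lo) / span
    Z[:, hi == lo] = 0.5
    return Z


def generate_planted_effects(
    table: "PeakTable | pd.DataFrame", model: PlantedModel, seed: int = 0,
    effect_label: str = "E1"
) -> EffectTable:
    """Generate per-group effect values from a sparse planted model.

    ``table`` is a :class:`PeakTable` (replicates are averaged per group) or
    a plain samples x components content DataFrame (e.g. from
    :func:`generate_component_samples`).
    """
    contents = table.group_means() if isinstance(table, PeakTable) else table
    index = contents.index
    X = contents.to_numpy(dtype=float)
    n_comp = X.shape[1]
    idx = np.asarray(model.driver_indices, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= n_comp):
        raise ValueError("driver_indices outside the table's component range")
    rng = np.random.default_rng(seed)
    Z = _minmax_columns(X)
    eta = Z[:, idx] @ np.asarray(model.driver_weights, dtype=float) if idx.size else np.zeros(X.shape[0])
    if model.link == "saturating":
        eta = np.tanh(eta)
    if model.noise_sd > 0:
        eta = eta + rng.normal(0.0, model.noise_sd, eta.shape)
    values = pd.Series(eta, index=pd.Index(index, name="group"), name="effect")
    return EffectTable(effect_label=effect_label, values=values, planted=model)
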