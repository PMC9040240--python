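"""Connection-weight decision weights and category contribution tables.

For a trained network with weight matrices ``W^(1) ... W^(L)`` (biases
excluded), each layer is converted to a share matrix

    F = |W| / sum(|W|)          (grand sum over all entries),

and the impact of input *i* on the output accumulates over every hidden
path, i.e. the matrix product of the share matrices.  The decision weight
of input *i* is the path-sum renormalized over inputs:

    S_i = F_ik / sum_i F_ik,     sum_i S_i = 1.

For a single hidden layer this reduces to the grand-sum (connection-
weights) variant of Garson's importance, S_i proportional to
``sum_j |w_ij| |v_j|``.  The decomposition is invariant to per-layer sign
flips and scalar rescalings of the weights.

Decision weights depend on the random initialization of the training run;
``averaged_decision_weights`` therefore repeats training over independent
seeds and averages S (single-seed mode reproduces a single-run analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, DivergenceError
from .network import QuantityEffectRegressor

__all__ = [
    "layer_share",
    "decision_weights",
    "DecisionWeights",
    "averaged_decision_weights",
    "select_contributors",
    "category_totals",
    "aggregate_contribution_table",
    "CategoryContributionTable",
    "universal_individual",
    "CharacterClassification",
]


def layer_share(W) -> np.ndarray:
    """Entrywise ``|w|`` over the grand sum of ``|w|``; sums to one."""
    W = np.asarray(W, dtype=float)
    total = np.abs(W).sum()
    if total == 0:
        raise DegenerateDataError("all-zero weight matrix has no shares")
    return np.abs(W) / total


@dataclass
class DecisionWeights:
    """Per-input normalized importances for one efficacy."""

    s: pd.Series  # per input, sums to 1
    f_ik: np.ndarray  # inputs x outputs path sums (pre-normalization)
    effect_label: str = ""
    n_seeds: int = 1
    sd: pd.Series | None = None


def decision_weights(net: QuantityEffectRegressor | list[np.ndarray],
                     feature_names=None, effect_label: str = "") -> DecisionWeights:
    """Decision weights of a trained network (or a raw weight-matrix list).

    Works for 1-3 hidden layers; with one hidden layer the middle share
    factor is simply absent.  Biases never enter.
    """
    Ws = net.weights_ if hasattr(net, "weights_") else list(net)
    if not 2 <= len(Ws) <= 4:
        raise ValueError("expected a network with 1-3 hidden layers")
    shares = [layer_share(W) for W in Ws]
    M = shares[0]
    for F in shares[1:]:
        M = M @ F
    f_ik = M
    totals = f_ik.sum()
    if totals == 0:
        raise DegenerateDataError("zero path-share total")
    s = f_ik.sum(axis=1) / totals
    if feature_names is None:
        feature_names = [f"C{i + 1:03d}" for i in range(len(s))]
    series = pd.Series(s, index=pd.Index(feature_names, name="component_id"), name="S")
    return DecisionWeights(s=series, f_ik=f_ik, effect_label=effect_label)


def averaged_decision_weights(X, y, n_seeds: int = 20, seed: int = 0,
                              feature_names=None, effect_label: str = "",
                              **estimator_params) -> DecisionWeights:
    """Mean decision weights over independent training runs.

    ``n_seeds`` networks are trained with seeds derived from ``seed``;
    divergent runs are recorded and excluded (an error is raised only if
    every run diverges).  The mean S still sums to one by linearity.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    seeds = np.random.SeedSequence(seed).generate_state(n_seeds) % (2 ** 31)
    runs = []
    failures = 0
    for s in seeds:
        try:
            net = QuantityEffectRegressor(random_state=int(s), **estimator_params).fit(X, y)
        except DivergenceError:
            failures += 1
            continue
        runs.append(decision_weights(net, feature_names=feature_names).s)
    if not runs:
        raise DivergenceError(0, f"all {n_seeds} training runs diverged")
    mat = pd.concat(runs, axis=1)
    mean = mat.mean(axis=1).rename("S")
    sd = mat.std(axis=1, ddof=1).rename("S_sd") if len(runs) > 1 else None
    return DecisionWeights(s=mean, f_ik=np.asarray(mean).reshape(-1, 1),
                           effect_label=effect_label, n_seeds=len(runs), sd=sd)


def select_contributors(dw: DecisionWeights | pd.Series, threshold: float = 0.01) -> pd.Series:
    """Components with ``S > threshold``, sorted descending (ties by id)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    s = dw.s if isinstance(dw, DecisionWeights) else pd.Series(dw)
    sel = s[s > threshold]
    order = sorted(sel.index, key=lambda i: (-sel[i], i))
    return sel.loc[order]


@dataclass
class CategoryContributionTable:
    """Per-category summed decision weights with per-efficacy ranks."""

    contributions: pd.DataFrame  # categories x effects
    ranks: pd.DataFrame  # categories x effects, 1 = largest
    total: pd.Series = field(default=None)  # per-category grand total

    @property
    def effects(self) -> list[str]:
        return list(self.contributions.columns)

    def to_frame(self) -> pd.DataFrame:
        out = self.contributions.copy()
        for e in self.effects:
            out[f"{e}_rank"] = self.ranks[e]
        out["Total"] = self.total
        return out


def aggregate_contribution_table(per_effect: pd.DataFrame) -> CategoryContributionTable:
    """Grand totals and per-efficacy ranks from per-effect category sums.

    The grand total of a category is the sum of its per-effect values; rank
    1 marks the largest contribution within an effect, ties broken by the
    larger grand total and then by category code.
    """
    contrib = per_effect.astype(float)
    total = contrib.sum(axis=1).rename("Total")
    ranks = pd.DataFrame(index=contrib.index, columns=contrib.columns, dtype=int)
    for e in contrib.columns:
        order = sorted(contrib.index, key=lambda c: (-contrib.loc[c, e], -total[c], c))
        for r, c in enumerate(order, start=1):
            ranks.loc[c, e] = r
    return CategoryContributionTable(contributions=contrib, ranks=ranks, total=total)


def category_totals(dw_per_effect: dict[str, DecisionWeights | pd.Series],
                    assignments: pd.DataFrame,
                    threshold: float = 0.01) -> CategoryContributionTable:
    """Sum above-threshold decision weights into category totals per effect.

    ``assignments`` maps ``component_id`` to ``category`` (every component
    must be assigned).  Only components with ``S > threshold`` count.
    """
    amap = assignments.set_index("component_id")["category"]
    cats = sorted(set(amap) - {"Others"}) + (["Others"] if "Others" in set(amap) else [])
    per_effect = {}
    for effect, dw in dw_per_effect.items():
        s = dw.s if isinstance(dw, DecisionWeights) else pd.Series(dw)
        missing = s.index.difference(amap.index)
        if len(missing):
            raise ValueError(f"unassigned component(s): {list(missing)[:5]}")
        kept = s[s > threshold]
        sums = kept.groupby(amap.loc[kept.index].to_numpy()).sum()
        per_effect[effect] = sums.reindex(cats, fill_value=0.0)
    table = pd.DataFrame(per_effect, index=pd.Index(cats, name="category")).fillna(0.0)
    return aggregate_contribution_table(table)


@dataclass
class CharacterClassification:
    """Universal vs individual categories across efficacies."""

    universal: set
    individual: dict  # effect -> set of categories
    background: set
    top_m: int


def universal_individual(table: CategoryContributionTable, top_m: int = 3) -> CharacterClassification:
    """Split categories into universal / individual / background characters.

    A category is *universal* when it ranks in the top ``top_m`` of every
    efficacy; it is *individual* to each efficacy where it reaches the top
    ``top_m`` without doing so everywhere; categories never in any top
    ``top_m`` are background.
    """
    n_cat = len(table.contributions.index)
    if top_m < 1 or top_m > n_cat:
        raise ValueError(f"top_m must be in [1, {n_cat}]")
    effects = table.effects
    in_top = {e: set(table.ranks.index[table.ranks[e] <= top_m]) for e in effects}
    universal = set.intersection(*in_top.values()) if effects else set()
    individual = {e: in_top[e] - universal for e in effects}
    background = set(table.contributions.index) - universal - set().union(*in_top.values())
    return CharacterClassification(universal=universal, individual=individual,
                                   background=background, top_m=top_m)
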