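"""Nonparametric statistical layer over the per-particle feature table.

All hypothesis tests operate at particle granularity (epoch features are
averaged per particle first): a 4-group Kruskal-Wallis per variable,
post-hoc pairwise Mann-Whitney tests over the six class pairs,
Bhattacharyya class-separability distances, and the Spearman rank
correlation of per-class mean discriminant score against the physical
driver dn*d.  Raw p-values are reported with significance flags at 0.05
and 0.001 (no multiple-testing correction, matching exploratory
screening practice).
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .synth_signals import CLASS_LABELS

ALPHA = 0.05
ALPHA_STRICT = 0.001


def _ordered_classes(labels) -> list:
    uniq = list(pd.unique(np.asarray(labels)))
    if set(uniq) <= set(CLASS_LABELS):
        return [c for c in CLASS_LABELS if c in uniq]
    return sorted(uniq)


def _groups(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = _ordered_classes(labels)
    return classes, [values[labels == c] for c in classes]


def kruskal_4way(values, labels) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p over the groups.

    All-identical data is a degenerate no-separation case: H=0, p=1.
    """
    classes, groups = _groups(values, labels)
    if len(classes) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >=2 non-empty groups")
    if np.ptp(np.concatenate(groups)) == 0:
        return 0.0, 1.0
    h, p = spstats.kruskal(*groups)
    return float(h), float(p)


def pairwise_mann_whitney(values, labels) -> dict[tuple, float]:
    """Two-sided Mann-Whitney p-value for every class pair.

    Exact enumeration when both groups are small (<8) and tie-free;
    otherwise the tie-corrected normal approximation.  Pairs are keyed
    (class_a, class_b) in study order: 1-2, 1-3, 1-4, 2-3, 2-4, 3-4.
    """
    classes, groups = _groups(values, labels)
    out: dict[tuple, float] = {}
    for (i, a), (j, b) in itertools.combinations(enumerate(classes), 2):
        ga, gb = groups[i], groups[j]
        if len(ga) == 0 or len(gb) == 0:
            raise ValueError(f"empty group in pair {(a, b)}")
        pooled = np.concatenate([ga, gb])
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (max(len(ga), len(gb)) < 8 and not has_ties) \
            else "asymptotic"
        _, p = spstats.mannwhitneyu(ga, gb, alternative="two-sided",
                                    method=method)
        out[(a, b)] = float(p)
    return out


def bhattacharyya_pair(X_a, X_b, mode: str = "univariate") -> float:
    """Gaussian Bhattacharyya distance between two class samples.

    ``univariate`` (default): the closed form
    D_j = (mu_a-mu_b)^2 / (4*(s_a^2+s_b^2)) + 0.5*ln((s_a^2+s_b^2)/(2*s_a*s_b))
    per feature, averaged over features.  ``multivariate``: the full
    Gaussian form with pooled covariance (Sigma_a+Sigma_b)/2.
    """
    X_a = np.atleast_2d(np.asarray(X_a, dtype=float).T).T
    X_b = np.atleast_2d(np.asarray(X_b, dtype=float).T).T
    if len(X_a) < 2 or len(X_b) < 2:
        raise ValueError("need >=2 rows per class")
    if mode == "univariate":
        mu_a, mu_b = X_a.mean(0), X_b.mean(0)
        va, vb = X_a.var(0, ddof=1), X_b.var(0, ddof=1)
        if np.any(va == 0) or np.any(vb == 0):
            raise ValueError("zero-variance feature")
        d = (mu_a - mu_b) ** 2 / (4 * (va + vb)) \
            + 0.5 * np.log((va + vb) / (2 * np.sqrt(va * vb)))
        return float(d.mean())
    if mode == "multivariate":
        mu = X_a.mean(0) - X_b.mean(0)
        ca = np.cov(X_a, rowvar=False, ddof=1)
        cb = np.cov(X_b, rowvar=False, ddof=1)
        ca, cb = np.atleast_2d(ca), np.atleast_2d(cb)
        c = (ca + cb) / 2
        sign, logdet_c = np.linalg.slogdet(c)
        if sign <= 0:
            raise ValueError("pooled covariance not positive definite")
        term1 = float(mu @ np.linalg.solve(c, mu)) / 8
        term2 = 0.5 * (logdet_c
                       - 0.5 * (np.linalg.slogdet(ca)[1]
                                + np.linalg.slogdet(cb)[1]))
        return term1 + term2
    raise ValueError("mode must be 'univariate' or 'multivariate'")


@dataclass
class PairwiseDistanceSet:
    """Bhattacharyya distance per class pair plus the grand mean."""

    distances: dict = field(default_factory=dict)

    @property
    def mean(self) -> float:
        if not self.distances:
            return float("nan")
        return float(np.mean(list(self.distances.values())))

    def as_matrix(self, classes) -> pd.DataFrame:
        m = pd.DataFrame(0.0, index=classes, columns=classes)
        for (a, b), d in self.distances.items():
            m.loc[a, b] = m.loc[b, a] = d
        return m


def separability_report(table: pd.DataFrame, labels, feature_subset,
                        mode: str = "univariate") -> PairwiseDistanceSet:
    """Pairwise Bhattacharyya distances over a chosen feature subset.

    Supports comparing e.g. the 3 top-LDA-weighted features against the
    3 bottom ones to confirm the weighting picks separable axes.
    """
    feature_subset = list(feature_subset)
    if not feature_subset:
        raise ValueError("feature subset must be non-empty")
    labels = np.asarray(labels)
    X = table[feature_subset].to_numpy(dtype=float)
    classes = _ordered_classes(labels)
    out = PairwiseDistanceSet()
    for a, b in itertools.combinations(classes, 2):
        out.distances[(a, b)] = bhattacharyya_pair(
            X[labels == a], X[labels == b], mode=mode)
    return out


def spearman_vs_dnd(class_mean_scores: dict, class_specs) -> tuple[float, float]:
    """Spearman correlation of per-class mean score against dn*d.

    ``class_specs`` supplies each class's refractive-index contrast x
    diameter (0 for the empty trap).  Two-sided p-value.
    """
    spec_by_label = {s.label: s for s in class_specs}
    labels = [lb for lb in class_mean_scores if lb in spec_by_label]
    if len(labels) < 3:
        raise ValueError("need >=3 classes with known dn*d")
    dnd = np.array([spec_by_label[lb].dnd for lb in labels])
    scores = np.array([class_mean_scores[lb] for lb in labels])
    if len(np.unique(dnd)) < len(dnd):
        warnings.warn("ties in dn*d; tie-corrected rho reported")
    rho, p = spstats.spearmanr(scores, dnd)
    return float(rho), float(p)


def feature_screen(particle_table: pd.DataFrame,
                   variables=None, label_col: str = "class_label",
                   ) -> pd.DataFrame:
    """Kruskal-Wallis + 6 pairwise Mann-Whitney tests per variable.

    One row per screened variable (the 45 features, plus the
    discriminant score when a ``score`` column is present) with H, the
    7 p-values, and */** significance flags at 0.05 / 0.001.
    """
    labels = particle_table[label_col].to_numpy()
    if variables is None:
        variables = [c for c in particle_table.columns
                     if c not in (label_col, "particle_id")]
    rows = []
    for var in variables:
        values = particle_table[var].to_numpy(dtype=float)
        h, p = kruskal_4way(values, labels)
        row = {"variable": var, "kw_H": h, "kw_p": p,
               "kw_sig": "**" if p < ALPHA_STRICT else
                         ("*" if p < ALPHA else "")}
        for pair, mw_p in pairwise_mann_whitney(values, labels).items():
            key = f"mw_{pair[0]}_vs_{pair[1]}"
            row[key] = mw_p
            row[key + "_sig"] = "**" if mw_p < ALPHA_STRICT else \
                ("*" if mw_p < ALPHA else "")
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


@dataclass
class StatReport:
    """Complete statistical report for one pipeline run."""

    screen: pd.DataFrame
    score_kruskal: tuple[float, float]
    score_mann_whitney: dict
    bhattacharyya_top: PairwiseDistanceSet
    bhattacharyya_bottom: PairwiseDistanceSet
    spearman: tuple[float, float]
    top_features: list[str]
    bottom_features: list[str]

    def to_json(self, path=None) -> str:
        payload = {
            "score_kruskal": {"H": self.score_kruskal[0],
                              "p": self.score_kruskal[1]},
            "score_mann_whitney": {f"{a}_vs_{b}": p for (a, b), p
                                   in self.score_mann_whitney.items()},
            "bhattacharyya_top": {
                "pairs": {f"{a}_vs_{b}": d for (a, b), d
                          in self.bhattacharyya_top.distances.items()},
                "mean": self.bhattacharyya_top.mean},
            "bhattacharyya_bottom": {
                "pairs": {f"{a}_vs_{b}": d for (a, b), d
                          in self.bhattacharyya_bottom.distances.items()},
                "mean": self.bhattacharyya_bottom.mean},
            "spearman_vs_dnd": {"rho": self.spearman[0],
                                "p": self.spearman[1]},
            "top_features": self.top_features,
            "bottom_features": self.bottom_features,
            "screen": json.loads(self.screen.to_json(orient="index")),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text
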