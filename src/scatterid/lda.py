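"""Fisher linear discriminant fitted via the generalized eigenproblem.

The discriminant direction phi maximizes the Rayleigh quotient
phi' S_B phi / phi' S_W phi, where S_W is the pooled within-class
scatter (sum over classes of per-class scatter matrices) and S_B the
between-class scatter sum_c p_c (m_c - m)(m_c - m)' with p_c the class
row-proportions.  It is found as the eigenvector of the largest
eigenvalue of S_B phi = lambda (S_W + ridge) phi; all features are
z-standardized before fitting so the entries of phi are comparable
contribution weights.  The projection to the single discriminant score
is score = phi' z(x).

API follows the Model/Results convention: build a
:class:`LinearDiscriminant` from data (or ``from_dataframe``), call
``fit()``, and use the returned :class:`LinearDiscriminantResults` for
projection, contribution weights, serialization and ``summary()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as spla

DEFAULT_EXCLUDED = ("RMS", "omega_nakagami")

_META_COLS = ("particle_id", "class_label", "epoch_index")


def exclude_features(table: pd.DataFrame,
                     names=DEFAULT_EXCLUDED) -> pd.DataFrame:
    """Drop the named feature columns (default: RMS, redundant with SD,
    and the outlier-prone Nakagami scale)."""
    missing = [n for n in names if n not in table.columns]
    if missing:
        raise KeyError(f"unknown feature columns: {missing}")
    return table.drop(columns=list(names))


@dataclass
class StandardizationParams:
    """Per-feature training means and SDs for out-of-sample projection."""

    feature_names: list[str]
    means: np.ndarray
    sds: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.means) / self.sds


def standardize(table: pd.DataFrame,
                ) -> tuple[pd.DataFrame, StandardizationParams]:
    """Z-score each column (n-1 SD); returns the table and stored params."""
    if len(table) < 2:
        raise ValueError("need at least 2 rows to standardize")
    means = table.mean(axis=0).to_numpy()
    sds = table.std(axis=0, ddof=1).to_numpy()
    zero = [c for c, s in zip(table.columns, sds) if s == 0]
    if zero:
        raise ValueError(f"zero-variance feature(s): {zero}")
    params = StandardizationParams(list(table.columns), means, sds)
    return (table - means) / sds, params


def scatter_matrices(X: np.ndarray, labels,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Between-class and within-class scatter matrices.

    S_within is the sum of per-class scatter matrices
    sum_{x in c} (x - m_c)(x - m_c)'; S_between uses class
    row-proportions p_c as weights on (m_c - m)(m_c - m)'.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    n, d = X.shape
    grand = X.mean(axis=0)
    s_within = np.zeros((d, d))
    s_between = np.zeros((d, d))
    for c in classes:
        Xc = X[labels == c]
        if len(Xc) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 rows")
        mc = Xc.mean(axis=0)
        dev = Xc - mc
        s_within += dev.T @ dev
        diff = (mc - grand)[:, None]
        s_between += (len(Xc) / n) * (diff @ diff.T)
    return s_between, s_within


class LinearDiscriminant:
    """Single-direction Fisher LDA model.

    Parameters
    ----------
    X : array-like, shape (n, d)
        Raw (unstandardized) feature rows.
    labels : array-like, shape (n,)
        Class label per row.
    feature_names : sequence of str, optional
    ridge : float
        Relative Tikhonov term added to S_within,
        ``ridge * tr(S_W)/d * I``, guarding near-singular cases.
    """

    def __init__(self, X, labels, feature_names=None, ridge: float = 1e-6):
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        self.labels = np.asarray(labels)
        if len(self.labels) != len(self.X):
            raise ValueError("X and labels length mismatch")
        if feature_names is None:
            feature_names = [f"x{i}" for i in range(self.X.shape[1])]
        if len(feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length mismatch")
        self.feature_names = list(feature_names)
        self.ridge = ridge
        self.excluded_features: list[str] = []

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, label_col: str = "class_label",
                       exclude=DEFAULT_EXCLUDED, ridge: float = 1e-6,
                       ) -> "LinearDiscriminant":
        """Build from a feature table; metadata columns are ignored and
        the default exclusions (RMS, omega_nakagami) applied."""
        exclude = [n for n in exclude if n in table.columns]
        feats = table.drop(columns=[c for c in _META_COLS if c in table.columns])
        feats = feats.drop(columns=[label_col], errors="ignore")
        feats = exclude_features(feats, exclude) if exclude else feats
        model = cls(feats.to_numpy(), table[label_col].to_numpy(),
                    feature_names=list(feats.columns), ridge=ridge)
        model.excluded_features = list(exclude)
        return model

    def fit(self, orient_reference: str | None = None,
            ) -> "LinearDiscriminantResults":
        """Solve the generalized eigenproblem and return results.

        The eigenvector of the LARGEST generalized eigenvalue is taken
        (the Rayleigh-quotient maximizer).  The sign of phi is fixed so
        the largest-|component| weight is positive; if
        ``orient_reference`` names a class present in the data, the sign
        is instead fixed so that class's mean score lies at or below the
        mean of the remaining class means (the weak-scatterer reference
        anchors the low end of the score axis).
        """
        Z_df, params = standardize(
            pd.DataFrame(self.X, columns=self.feature_names))
        Z = Z_df.to_numpy()
        s_between, s_within = scatter_matrices(Z, self.labels)
        d = Z.shape[1]
        trace = np.trace(s_within)
        reg = self.ridge * (trace / d if trace > 0 else 1.0)
        s_within_reg = s_within + reg * np.eye(d)
        try:
            eigvals, eigvecs = spla.eigh(s_between, s_within_reg)
        except spla.LinAlgError as err:
            raise ArithmeticError(
                "generalized eigenproblem failed; cond(S_W)="
                f"{np.linalg.cond(s_within_reg):.3e}") from err
        if not np.all(np.isfinite(eigvals)):
            raise ArithmeticError(
                "non-finite eigenvalues; cond(S_W)="
                f"{np.linalg.cond(s_within_reg):.3e}")
        idx = int(np.argmax(eigvals))
        lam = float(eigvals[idx])
        phi = eigvecs[:, idx]
        phi = phi / np.linalg.norm(phi)
        if phi[np.argmax(np.abs(phi))] < 0:
            phi = -phi
        scores = Z @ phi
        classes = np.unique(self.labels)
        class_means = {str(c): float(scores[self.labels == c].mean())
                       for c in classes}
        if orient_reference is not None and str(orient_reference) in class_means:
            ref = class_means[str(orient_reference)]
            others = [m for c, m in class_means.items()
                      if c != str(orient_reference)]
            if others and ref > float(np.mean(others)):
                phi = -phi
                class_means = {c: -m for c, m in class_means.items()}
        return LinearDiscriminantResults(
            model=self, phi=phi, eigenvalue=lam, standardization=params,
            class_means_projected=class_means,
            s_between=s_between, s_within_reg=s_within_reg)


class LinearDiscriminantResults:
    """Fitted discriminant: direction, eigenvalue, projection machinery."""

    def __init__(self, model, phi, eigenvalue, standardization,
                 class_means_projected, s_between=None, s_within_reg=None):
        self.model = model
        self.phi = np.asarray(phi, dtype=float)
        self.eigenvalue = float(eigenvalue)
        self.standardization = standardization
        self.class_means_projected = dict(class_means_projected)
        self.s_between = s_between
        self.s_within_reg = s_within_reg
        self.feature_names = standardization.feature_names
        self.excluded_features = list(getattr(model, "excluded_features", []))

    def rayleigh_quotient(self, direction=None) -> float:
        v = self.phi if direction is None else np.asarray(direction, float)
        return float((v @ self.s_between @ v) / (v @ self.s_within_reg @ v))

    def _feature_matrix(self, table: pd.DataFrame) -> np.ndarray:
        cols = [c for c in table.columns
                if c not in _META_COLS and c != "score"]
        if set(cols) != set(self.feature_names):
            missing = sorted(set(self.feature_names) - set(cols))
            extra = sorted(set(cols) - set(self.feature_names))
            raise ValueError(
                f"feature columns mismatch: missing={missing}, extra={extra}")
        return table[self.feature_names].to_numpy(dtype=float)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        """Project rows to the discriminant score.

        Returns the metadata columns of ``table`` plus a ``score``
        column, score = phi' z(x) under the stored training
        standardization.
        """
        X = self._feature_matrix(table)
        scores = self.standardization.apply(X) @ self.phi
        meta = [c for c in _META_COLS if c in table.columns]
        out = table[meta].copy() if meta else pd.DataFrame(index=table.index)
        out["score"] = scores
        return out

    def transform_array(self, X) -> np.ndarray:
        return self.standardization.apply(np.asarray(X, float)) @ self.phi

    def contribution_weights(self) -> pd.DataFrame:
        """Per-feature weights |phi_j| (and signed phi_j), descending;
        squared magnitudes sum to 1."""
        df = pd.DataFrame({
            "feature": self.feature_names,
            "phi": self.phi,
            "abs_weight": np.abs(self.phi),
            "squared_weight": self.phi ** 2,
        })
        return (df.sort_values("abs_weight", ascending=False)
                .reset_index(drop=True))

    def summary(self) -> str:
        lines = ["Linear discriminant (single direction)",
                 "=" * 46,
                 f"features retained : {len(self.feature_names)}",
                 f"excluded          : {self.excluded_features or 'none'}",
                 f"eigenvalue (between/within): {self.eigenvalue:.6g}",
                 "class mean scores:"]
        for c, m in sorted(self.class_means_projected.items()):
            lines.append(f"  {c:>12s} : {m:+.4f}")
        lines.append("top contribution weights:")
        top = self.contribution_weights().head(8)
        for _, r in top.iterrows():
            lines.append(f"  {r.feature:>14s} : phi={r.phi:+.4f} "
                         f"(squared weight {r.squared_weight:.3f})")
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = {
            "feature_names": self.feature_names,
            "excluded_features": self.excluded_features,
            "means": self.standardization.means.tolist(),
            "sds": self.standardization.sds.tolist(),
            "phi": self.phi.tolist(),
            "eigenvalue": self.eigenvalue,
            "class_means_projected": self.class_means_projected,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "LinearDiscriminantResults":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        params = StandardizationParams(
            payload["feature_names"],
            np.asarray(payload["means"], float),
            np.asarray(payload["sds"], float))
        res = cls(model=None, phi=payload["phi"],
                  eigenvalue=payload["eigenvalue"], standardization=params,
                  class_means_projected=payload["class_means_projected"])
        res.excluded_features = payload.get("excluded_features", [])
        return res
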