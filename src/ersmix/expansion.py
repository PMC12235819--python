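"""Candidate predictor expansion for mixture modelling.

Starting from a panel of P standardized log10 exposure columns, the candidate
set for variable selection contains every main effect, every quadratic term,
and every pairwise product: 2P + P(P-1)/2 columns (189 for the 18-metal
panel).  Products are formed *after* the main-effect columns are z-scored and
are deliberately not re-standardized, so that a coefficient on ``Sn^2`` or
``La:Ce`` multiplies an interpretable product of z-scores — the same quantity
the environmental risk score later sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Term", "Scaling", "TermSet", "standardize", "expand", "n_expanded_terms"]


@dataclass(frozen=True)
class Term:
    """A single candidate predictor: main effect, quadratic, or pairwise product.

    Interaction metal pairs are stored in panel order, so ``La:Ce`` and
    ``Ce:La`` denote the same term and only the canonical form is ever built.
    """

    kind: str  # "main" | "quadratic" | "interaction"
    metals: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind in ("main", "quadratic"):
            if len(self.metals) != 1:
                raise ValueError(f"{self.kind} term must reference exactly one metal")
        elif self.kind == "interaction":
            if len(self.metals) != 2 or self.metals[0] == self.metals[1]:
                raise ValueError("interaction term must reference two distinct metals")
        else:
            raise ValueError(f"unknown term kind {self.kind!r}")

    @property
    def label(self) -> str:
        if self.kind == "main":
            return self.metals[0]
        if self.kind == "quadratic":
            return f"{self.metals[0]}^2"
        return f"{self.metals[0]}:{self.metals[1]}"

    @classmethod
    def parse(cls, label: str, metal_names: list[str] | None = None) -> "Term":
        """Recover a Term from its canonical label.

        If ``metal_names`` is given, interaction pairs are re-canonicalized
        into panel order, so ``Ce:La`` parses to the same Term as ``La:Ce``.
        """
        if ":" in label:
            a, b = label.split(":")
            if metal_names is not None and a in metal_names and b in metal_names:
                if metal_names.index(a) > metal_names.index(b):
                    a, b = b, a
            return cls("interaction", (a, b))
        if label.endswith("^2"):
            return cls("quadratic", (label[:-2],))
        return cls("main", (label,))

    def evaluate(self, Z: pd.DataFrame) -> np.ndarray:
        """Column of term values from a standardized exposure matrix."""
        for m in self.metals:
            if m not in Z.columns:
                raise KeyError(f"metal {m!r} missing from standardized matrix")
        if self.kind == "main":
            return Z[self.metals[0]].to_numpy(dtype=float)
        if self.kind == "quadratic":
            z = Z[self.metals[0]].to_numpy(dtype=float)
            return z * z
        return Z[self.metals[0]].to_numpy(dtype=float) * Z[self.metals[1]].to_numpy(dtype=float)


@dataclass
class Scaling:
    """Per-exposure location/scale learned on training data (mean, SD with ddof=1)."""

    means: pd.Series
    sds: pd.Series

    def apply(self, log10_matrix: pd.DataFrame) -> pd.DataFrame:
        """Standardize new data with the stored training scaling (no re-fit)."""
        cols = list(self.means.index)
        missing = [c for c in cols if c not in log10_matrix.columns]
        if missing:
            raise KeyError(f"columns missing from input: {missing}")
        return (log10_matrix[cols] - self.means) / self.sds


@dataclass
class TermSet:
    """The expanded candidate design: ordered terms plus their value matrix."""

    terms: list[Term]
    values: pd.DataFrame
    scaling: Scaling
    metal_names: list[str] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.terms]

    def term_by_label(self, label: str) -> Term:
        return Term.parse(label, self.metal_names)


def standardize(log10_matrix: pd.DataFrame) -> tuple[pd.DataFrame, Scaling]:
    """Z-score each exposure column (mean 0, SD 1 with the n-1 denominator).

    Raises if any column is constant — a zero-variance exposure cannot be
    penalization-fair and would poison the design.
    """
    X = log10_matrix.astype(float)
    if len(X) < 2:
        raise ValueError("standardization needs at least 2 subjects")
    means = X.mean()
    sds = X.std(ddof=1)
    dead = sds.index[(sds == 0) | ~np.isfinite(sds)].tolist()
    if dead:
        raise ValueError(f"zero-variance exposure column(s): {dead}")
    scaling = Scaling(means=means, sds=sds)
    return (X - means) / sds, scaling


def n_expanded_terms(p: int) -> int:
    """Number of candidate columns for a panel of p exposures: 2p + C(p,2)."""
    return 2 * p + p * (p - 1) // 2


def expand(Z: pd.DataFrame, metal_names: list[str] | None = None,
           scaling: Scaling | None = None) -> TermSet:
    """Build the full candidate term set from a standardized exposure matrix.

    Column order is deterministic: all main effects in panel order, all
    quadratics in panel order, then all pairwise interactions lexicographic by
    panel index pair.  Quadratic and interaction columns are exact elementwise
    products of the main-effect columns.
    """
    if metal_names is None:
        metal_names = list(Z.columns)
    if len(set(metal_names)) != len(metal_names):
        dupes = sorted({m for m in metal_names if metal_names.count(m) > 1})
        raise ValueError(f"duplicate metal names: {dupes}")
    if len(metal_names) < 2:
        raise ValueError("need at least 2 exposures to expand")

    terms: list[Term] = [Term("main", (m,)) for m in metal_names]
    terms += [Term("quadratic", (m,)) for m in metal_names]
    for i in range(len(metal_names) - 1):
        for j in range(i + 1, len(metal_names)):
            terms.append(Term("interaction", (metal_names[i], metal_names[j])))

    cols = {t.label: t.evaluate(Z) for t in terms}
    values = pd.DataFrame(cols, index=Z.index)
    if scaling is None:
        # identity scaling placeholder when Z was standardized elsewhere
        scaling = Scaling(
            means=pd.Series(0.0, index=metal_names),
            sds=pd.Series(1.0, index=metal_names),
        )
    return TermSet(terms=terms, values=values, scaling=scaling, metal_names=list(metal_names))


def expand_terms_for(labels: list[str], Z: pd.DataFrame,
                     metal_names: list[str] | None = None) -> pd.DataFrame:
    """Evaluate a specific list of term labels on a standardized matrix."""
    out = {}
    for lab in labels:
        t = Term.parse(lab, metal_names)
        out[t.label] = t.evaluate(Z)
    return pd.DataFrame(out, index=Z.index)
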