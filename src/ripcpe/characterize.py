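"""Binder vs non-binder comparative statistics and the binder score.

Given per-transcript motif profiles and binder labels, this module
reproduces the comparative picture expected of a CPEB-family target set:

* a per-class 2x2 contingency of transcripts with element count > k vs
  <= k (default k = 3), tested with Fisher's exact test;
* Mann-Whitney rank-sum comparisons of per-kilobase CPEC/CPENC densities
  and of 3'-UTR length between binders and non-binders;
* an optional penalized logistic "binder score" on UTR features
  (log10 length plus the per-class densities), exposed statsmodels-style
  as :class:`BinderScore` / :class:`BinderScoreResults`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "ClassComparison",
    "RankSumResult",
    "ComparisonReport",
    "threshold_table",
    "fisher_exact",
    "rank_sum_test",
    "compare_binders",
    "BinderScore",
    "BinderScoreResults",
]

#: total sample size at or below which the rank-sum test is exact (untied)
EXACT_RANKSUM_N = 12


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: rows (binder, non-binder) x columns (count > k, count <= k)."""

    binder_high: int
    binder_low: int
    nonbinder_high: int
    nonbinder_low: int

    def __post_init__(self):
        if min(self.binder_high, self.binder_low, self.nonbinder_high, self.nonbinder_low) < 0:
            raise ValueError("contingency cells must be non-negative")

    def to_array(self) -> np.ndarray:
        return np.array(
            [[self.binder_high, self.binder_low], [self.nonbinder_high, self.nonbinder_low]]
        )


@dataclass
class ClassComparison:
    class_name: str
    table: ContingencyTable
    odds_ratio: float
    fisher_p: float


@dataclass
class RankSumResult:
    feature: str
    statistic: float
    pvalue: float
    median_binder: float
    median_nonbinder: float


@dataclass
class ComparisonReport:
    """All binder-vs-non-binder statistics for one labelled profile set."""

    k: int
    n_binders: int
    n_nonbinders: int
    fisher: Mapping[str, ClassComparison] = field(default_factory=dict)
    ranksum: Mapping[str, RankSumResult] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "n_binders": self.n_binders,
            "n_nonbinders": self.n_nonbinders,
            "fisher": {
                name: {
                    "table": c.table.to_array().tolist(),
                    "odds_ratio": c.odds_ratio,
                    "pvalue": c.fisher_p,
                }
                for name, c in self.fisher.items()
            },
            "ranksum": {
                name: {
                    "U": r.statistic,
                    "pvalue": r.pvalue,
                    "median_binder": r.median_binder,
                    "median_nonbinder": r.median_nonbinder,
                }
                for name, r in self.ranksum.items()
            },
        }


def _as_label_map(labels) -> dict:
    if hasattr(labels, "labels"):  # TruthLabels
        return dict(labels.labels)
    return dict(labels)


def threshold_table(profiles: pd.DataFrame, labels, class_name: str, k: int = 3) -> ContingencyTable:
    """Tally transcripts with element count > k (strict) per label group.

    ``profiles`` must carry a ``{class_name}_count`` column indexed by
    transcript id; every labelled transcript needs a profile row.
    """
    col = f"{class_name}_count"
    if col not in profiles.columns:
        raise ValueError(f"class {class_name!r} absent from profiles")
    lab = _as_label_map(labels)
    missing = set(lab) - set(profiles.index)
    if missing:
        raise ValueError(f"{len(missing)} labelled transcripts lack profiles")
    counts = profiles[col]
    cells = {True: [0, 0], False: [0, 0]}
    for tid, is_binder in lab.items():
        high = counts.loc[tid] > k
        cells[bool(is_binder)][0 if high else 1] += 1
    return ContingencyTable(cells[True][0], cells[True][1], cells[False][0], cells[False][1])


def fisher_exact(table: ContingencyTable) -> tuple:
    """Two-sided Fisher exact test with the minimum-likelihood rule.

    Returns ``(odds_ratio, pvalue)``. The odds ratio is the sample ratio
    a*d / (b*c), infinite when b*c = 0 with a*d > 0, and 1 by convention
    when both cross-products vanish.
    """
    a, b = table.binder_high, table.binder_low
    c, d = table.nonbinder_high, table.nonbinder_low
    ad, bc = a * d, b * c
    if bc == 0:
        odds = 1.0 if ad == 0 else float("inf")
    else:
        odds = ad / bc
    pvalue = float(stats.fisher_exact(table.to_array(), alternative="two-sided")[1])
    return odds, min(pvalue, 1.0)


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple:
    """Mann-Whitney U (midranks for ties), two-sided.

    Exact null enumeration when n_x + n_y <= 12 with no ties; otherwise a
    normal approximation with tie correction and continuity correction.
    Returns ``(U, pvalue)`` with U the statistic for ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank-sum test needs two nonempty samples")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if np.ptp(pooled) == 0:
        return float(x.size * y.size / 2.0), 1.0
    method = "exact" if (x.size + y.size <= EXACT_RANKSUM_N and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_binders(
    profiles: pd.DataFrame,
    labels,
    k: int = 3,
    classes: Sequence[str] = ("CPEC", "CPENC", "Hex", "PBE"),
    density_classes: Sequence[str] = ("CPEC", "CPENC"),
) -> ComparisonReport:
    """Full binder-vs-non-binder comparison report.

    Fisher's exact test on the count-> k contingency for every class in
    ``classes``; rank-sum tests on per-kb density for ``density_classes``
    and on UTR length.
    """
    lab = _as_label_map(labels)
    binder_ids = [t for t, b in lab.items() if b]
    nonbinder_ids = [t for t, b in lab.items() if not b]
    if not binder_ids or not nonbinder_ids:
        raise ValueError("compare_binders needs both binders and non-binders")

    report = ComparisonReport(k=k, n_binders=len(binder_ids), n_nonbinders=len(nonbinder_ids))
    fisher = {}
    for cls in classes:
        tab = threshold_table(profiles, lab, cls, k=k)
        odds, p = fisher_exact(tab)
        fisher[cls] = ClassComparison(cls, tab, odds, p)
    report.fisher = fisher

    ranksum = {}
    features = [(f"{cls}_density", f"{cls}_density") for cls in density_classes]
    features.append(("utr_length", "utr_length"))
    for name, col in features:
        if col not in profiles.columns:
            raise ValueError(f"feature column {col!r} absent from profiles")
        xb = profiles.loc[binder_ids, col].to_numpy(dtype=float)
        xn = profiles.loc[nonbinder_ids, col].to_numpy(dtype=float)
        u, p = rank_sum_test(xb, xn)
        ranksum[name] = RankSumResult(
            name, u, p, float(np.median(xb)), float(np.median(xn))
        )
    report.ranksum = ranksum
    return report


def _logistic_nll_grad(beta, X, y, lam):
    """Mean penalized negative log-likelihood and gradient (no intercept penalty)."""
    eta = X @ beta
    # log(1 + e^eta) computed stably
    log1pexp = np.logaddexp(0.0, eta)
    nll = float(np.mean(log1pexp - y * eta))
    p = 1.0 / (1.0 + np.exp(-eta))
    grad = X.T @ (p - y) / X.shape[0]
    pen = np.zeros_like(beta)
    pen[1:] = 2.0 * lam * beta[1:]
    return nll + lam * float(np.sum(beta[1:] ** 2)), grad + pen


class BinderScore:
    """Penalized logistic model of the binder flag on UTR features.

    Features are log10 UTR length plus the per-class per-kb densities.
    The loss is the mean log-loss plus an L2 penalty ``l2`` on the
    (standardized-scale) coefficients, so the fit is deterministic,
    immune to perfect separation, and invariant to duplicating records.
    This score operationalises the observation that UTR length and CPE
    abundance are predictive of binding; it is an explicit extension of
    the comparative statistics and is off by default in the pipeline.
    """

    def __init__(
        self,
        profiles: pd.DataFrame,
        labels,
        density_classes: Sequence[str] = ("CPEC", "CPENC", "Hex", "PBE"),
    ):
        lab = _as_label_map(labels)
        ids = [t for t in profiles.index if t in lab]
        if len(ids) != len(lab):
            raise ValueError("every labelled transcript needs a profile")
        y = np.array([float(lab[t]) for t in ids])
        if y.min() == y.max():
            raise ValueError("binder score needs both classes present")
        feats = {"log10_utr_length": np.log10(profiles.loc[ids, "utr_length"].to_numpy(float))}
        for cls in density_classes:
            feats[f"{cls}_density"] = profiles.loc[ids, f"{cls}_density"].to_numpy(float)
        X = pd.DataFrame(feats, index=ids)
        if not np.isfinite(X.to_numpy()).all():
            raise ValueError("binder score features must be finite")
        self.transcript_ids = ids
        self.endog = y
        self.exog = X

    def fit(self, l2: float = 1e-4, n_folds: int = 5) -> "BinderScoreResults":
        X = self.exog.to_numpy(float)
        y = self.endog
        mu, sd = X.mean(axis=0), X.std(axis=0)
        keep = sd > 0
        for name, ok in zip(self.exog.columns, keep):
            if not ok:
                warnings.warn(f"dropping constant feature {name!r}")
        Z = (X[:, keep] - mu[keep]) / sd[keep]
        names = [n for n, ok in zip(self.exog.columns, keep) if ok]

        def solve(Zs, ys):
            D = np.column_stack([np.ones(len(ys)), Zs])
            res = optimize.minimize(
                _logistic_nll_grad,
                np.zeros(D.shape[1]),
                args=(D, ys, l2),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
            )
            return res.x

        beta = solve(Z, y)
        prob = 1.0 / (1.0 + np.exp(-(np.column_stack([np.ones(len(y)), Z]) @ beta)))

        # deterministic round-robin folds by row order
        cv_prob = np.full(len(y), np.nan)
        folds = np.arange(len(y)) % n_folds
        for fold in range(n_folds):
            test = folds == fold
            train = ~test
            if y[train].min() == y[train].max():
                cv_prob[test] = float(y[train].mean())
                continue
            b = solve(Z[train], y[train])
            cv_prob[test] = 1.0 / (
                1.0 + np.exp(-(np.column_stack([np.ones(test.sum()), Z[test]]) @ b))
            )

        # back-transform to raw feature scale
        coef_std = beta[1:]
        coef_raw = coef_std / sd[keep]
        intercept_raw = beta[0] - float(np.sum(coef_std * mu[keep] / sd[keep]))
        params = pd.Series([intercept_raw] + list(coef_raw), index=["intercept"] + names)
        return BinderScoreResults(self, params, prob, cv_prob, l2, n_folds)


class BinderScoreResults:
    """Fitted binder-score model: coefficients and per-transcript probabilities."""

    def __init__(self, model, params, prob, cv_prob, l2, n_folds):
        self.model = model
        self.params = params
        self.fitted_prob = pd.Series(prob, index=model.transcript_ids, name="binder_prob")
        self.cv_prob = pd.Series(cv_prob, index=model.transcript_ids, name="binder_prob_cv")
        self.l2 = l2
        self.n_folds = n_folds

    def auroc(self, held_out: bool = True) -> float:
        """Rank-based AUROC of the (held-out by default) probabilities."""
        score = (self.cv_prob if held_out else self.fitted_prob).to_numpy()
        y = self.model.endog
        n1, n0 = int(y.sum()), int(len(y) - y.sum())
        ranks = stats.rankdata(score)
        return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "transcript_id": self.model.transcript_ids,
                "is_binder": self.model.endog.astype(bool),
                "binder_prob": self.fitted_prob.to_numpy(),
                "binder_prob_cv": self.cv_prob.to_numpy(),
            }
        )

    def summary(self) -> str:
        lines = [
            "Binder probability score (L2-penalized logistic)",
            "=" * 48,
            f"transcripts: {len(self.model.endog)}  "
            f"binders: {int(self.model.endog.sum())}",
            f"l2 penalty: {self.l2:g}   folds: {self.n_folds}",
            f"held-out AUROC: {self.auroc():.3f}",
            "",
            "coefficients (raw feature scale):",
        ]
        for name, val in self.params.items():
            lines.append(f"  {name:<18s} {val:+.4f}")
        return "\n".join(lines)
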