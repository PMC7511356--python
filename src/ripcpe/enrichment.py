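"""Negative-binomial enrichment testing of IP vs control RIP-Seq counts.

The binder-calling model: per-sample size factors by the median-of-ratios
method, per-transcript NB dispersion by within-group method of moments with
a conservative moderation floor, a Wald test on the log2 ratio of normalized
group means with a delta-method standard error, Benjamini-Hochberg FDR
adjustment, and threshold classification (binder iff log2(IP/control) >
``lfc_min`` and q < ``fdr_max``; defaults 0 and 0.01).

The model is exposed statsmodels-style::

    model = RIPEnrichment(counts, design)
    res = model.fit()
    res.table          # per-transcript EnrichmentRecord DataFrame
    res.n_binders
    print(res.summary())

The lower-level operations (:func:`size_factors`, :func:`estimate_dispersion`,
:func:`test_enrichment`, :func:`adjust_fdr`, :func:`call_binders`) are plain
functions usable on their own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SampleDesign",
    "RIPEnrichment",
    "RIPEnrichmentResults",
    "size_factors",
    "estimate_dispersion",
    "test_enrichment",
    "adjust_fdr",
    "call_binders",
]

#: dispersion floor for numerical stability of the variance formula
ALPHA_FLOOR = 1e-8

#: pseudocount (normalized counts) added to each group mean in the log-ratio
PSEUDOCOUNT = 0.5

GROUPS = ("IP", "control")


@dataclass(frozen=True)
class SampleDesign:
    """Assignment of each sample to the IP or control group."""

    groups: Mapping[str, str]

    def __post_init__(self):
        bad = {g for g in self.groups.values() if g not in GROUPS}
        if bad:
            raise ValueError(f"unknown group labels {bad}; expected {GROUPS}")
        for grp in GROUPS:
            if grp not in self.groups.values():
                raise ValueError(f"design has no {grp!r} samples")

    @property
    def ip_samples(self) -> list:
        return [s for s, g in self.groups.items() if g == "IP"]

    @property
    def control_samples(self) -> list:
        return [s for s, g in self.groups.items() if g == "control"]

    def validate_against(self, counts: pd.DataFrame) -> None:
        missing = set(counts.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group assignment: {sorted(missing)}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": list(self.groups), "group": list(self.groups.values())})


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Each sample's factor is the median, over transcripts with nonzero counts
    in every sample, of that sample's count divided by the transcript's
    geometric-mean count. When no transcript is nonzero everywhere the
    factors fall back to column totals (rescaled the same way).
    """
    arr = counts.to_numpy(dtype=float)
    if arr.size == 0 or not arr.any():
        raise ValueError("cannot normalize an all-zero count matrix")
    eligible = (arr > 0).all(axis=1)
    if eligible.any():
        logc = np.log(arr[eligible])
        ratios = logc - logc.mean(axis=1, keepdims=True)
        logf = np.median(ratios, axis=0)
    else:
        logf = np.log(arr.sum(axis=0))
    logf = logf - logf.mean()
    return pd.Series(np.exp(logf), index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    design: SampleDesign,
    factors: pd.Series,
    alpha_floor: float = ALPHA_FLOOR,
    moderate: bool = True,
) -> pd.Series:
    """Per-transcript NB dispersion alpha (var = mu + alpha mu^2).

    Method of moments on normalized counts, using within-group means and
    variances pooled across the two groups with df weights. Transcripts with
    zero mean get ``alpha_floor``.

    With ``moderate=True`` (default) each estimate is raised to at least the
    across-transcript median estimate. With a handful of replicates the raw
    moment estimator is extremely noisy and its downward errors make the
    Wald test anticonservative; flooring at the matrix-wide median removes
    that failure mode while leaving genuinely high dispersions untouched.
    """
    design.validate_against(counts)
    norm = counts.to_numpy(dtype=float) / factors.reindex(counts.columns).to_numpy()
    num = np.zeros(norm.shape[0])
    den = np.zeros(norm.shape[0])
    for grp_samples in (design.ip_samples, design.control_samples):
        idx = [counts.columns.get_loc(s) for s in grp_samples]
        if len(idx) < 2:
            continue
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        df = len(idx) - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (v - m) / np.square(m), alpha_floor)
        num += df * a
        den += df
    if not den.any():
        alpha = np.full(norm.shape[0], alpha_floor)
    else:
        alpha = np.maximum(alpha_floor, num / den)
    if moderate and np.isfinite(alpha).any():
        alpha = np.maximum(alpha, np.median(alpha))
    return pd.Series(alpha, index=counts.index, name="dispersion")


def test_enrichment(
    counts: pd.DataFrame,
    design: SampleDesign,
    factors: pd.Series,
    dispersions: pd.Series,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Wald test of IP-vs-control enrichment per transcript.

    log2fc = log2((mean_IP + c) / (mean_control + c)) on normalized counts;
    the standard error comes from the delta-method NB variance of the two
    group means, Var(mean_g) = n_g^-2 * sum_s (m_g / f_s + alpha m_g^2),
    propagated through the log ratio. Two-sided p from the standard normal.
    Transcripts with all-zero counts get p = NA (log2fc 0 by convention) and
    are excluded from the FDR batch downstream.
    """
    design.validate_against(counts)
    f = factors.reindex(counts.columns).to_numpy()
    norm = counts.to_numpy(dtype=float) / f
    ip_idx = [counts.columns.get_loc(s) for s in design.ip_samples]
    ct_idx = [counts.columns.get_loc(s) for s in design.control_samples]
    alpha = dispersions.reindex(counts.index).to_numpy()

    def group_stats(idx):
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        inv_f = float(np.sum(1.0 / f[idx]))
        var_mean = (m * inv_f + len(idx) * alpha * np.square(m)) / len(idx) ** 2
        return m, var_mean

    m_ip, v_ip = group_stats(ip_idx)
    m_ct, v_ct = group_stats(ct_idx)
    c = pseudocount
    log2fc = np.log2((m_ip + c) / (m_ct + c))
    ln2sq = np.log(2.0) ** 2
    se = np.sqrt((v_ip / np.square(m_ip + c) + v_ct / np.square(m_ct + c)) / ln2sq)

    all_zero = (counts.to_numpy() == 0).all(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    log2fc = np.where(all_zero, 0.0, log2fc)
    pvalue = np.where(all_zero, np.nan, pvalue)
    se = np.where(all_zero, np.nan, se)

    base_mean = norm.mean(axis=1)
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se_log2fc": se,
            "pvalue": pvalue,
        },
        index=counts.index,
    )


def adjust_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NA p-values stay NA."""
    p = np.asarray(pvalues, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def call_binders(records: pd.DataFrame, lfc_min: float = 0.0, fdr_max: float = 0.01) -> pd.DataFrame:
    """Attach q-values and the binder flag to an enrichment table.

    A transcript is a binder iff log2(IP/control) > ``lfc_min`` and its BH
    q-value is below ``fdr_max``; untestable transcripts (p = NA) are
    non-binders.
    """
    out = records.copy()
    out["qvalue"] = adjust_fdr(out["pvalue"].to_numpy())
    out["is_binder"] = (out["log2fc"] > lfc_min) & (out["qvalue"] < fdr_max)
    out.loc[out["qvalue"].isna(), "is_binder"] = False
    out["is_binder"] = out["is_binder"].astype(bool)
    return out


class RIPEnrichment:
    """NB enrichment model for a RIP-Seq count matrix.

    Parameters
    ----------
    counts : DataFrame
        Non-negative integer counts, transcripts x samples.
    design : SampleDesign or mapping
        sample_id -> group in {"IP", "control"}.
    """

    def __init__(self, counts: pd.DataFrame, design):
        if not isinstance(design, SampleDesign):
            design = SampleDesign(dict(design))
        design.validate_against(counts)
        if counts.isna().any().any():
            raise ValueError("count matrix has missing cells")
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts
        self.design = design

    @classmethod
    def from_dataframes(cls, counts: pd.DataFrame, design_frame: pd.DataFrame) -> "RIPEnrichment":
        """Build from a counts table and a (sample_id, group) sample sheet."""
        mapping = dict(zip(design_frame["sample_id"], design_frame["group"]))
        return cls(counts, SampleDesign(mapping))

    def fit(
        self,
        lfc_min: float = 0.0,
        fdr_max: float = 0.01,
        pseudocount: float = PSEUDOCOUNT,
        moderate_dispersion: bool = True,
    ) -> "RIPEnrichmentResults":
        factors = size_factors(self.counts)
        disp = estimate_dispersion(self.counts, self.design, factors, moderate=moderate_dispersion)
        table = test_enrichment(self.counts, self.design, factors, disp, pseudocount=pseudocount)
        table = call_binders(table, lfc_min=lfc_min, fdr_max=fdr_max)
        return RIPEnrichmentResults(self, table, factors, disp, lfc_min, fdr_max)


class RIPEnrichmentResults:
    """Fitted enrichment results: per-transcript estimates and binder calls."""

    def __init__(self, model, table, factors, dispersions, lfc_min, fdr_max):
        self.model = model
        self.table = table
        self.size_factors = factors
        self.dispersions = dispersions
        self.lfc_min = lfc_min
        self.fdr_max = fdr_max

    @property
    def binders(self) -> list:
        return self.table.index[self.table["is_binder"]].tolist()

    @property
    def n_binders(self) -> int:
        return int(self.table["is_binder"].sum())

    def binder_labels(self) -> dict:
        return self.table["is_binder"].to_dict()

    def summary(self) -> str:
        t = self.table
        tested = int(t["pvalue"].notna().sum())
        lines = [
            "RIP-Seq NB enrichment (Wald test, BH-adjusted)",
            "=" * 47,
            f"transcripts:        {len(t)}",
            f"tested (non-zero):  {tested}",
            f"IP / control reps:  {len(self.model.design.ip_samples)} / "
            f"{len(self.model.design.control_samples)}",
            f"binder rule:        log2fc > {self.lfc_min:g} and q < {self.fdr_max:g}",
            f"binders called:     {self.n_binders}",
            f"median dispersion:  {float(np.median(self.dispersions)):.4g}",
            f"median |log2fc|:    {float(t['log2fc'].abs().median()):.3f}",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return self.table.reset_index().rename(columns={"index": "transcript_id"})
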