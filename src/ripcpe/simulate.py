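"""Synthetic RIP-Seq data with ground-truth binder labels.

Emulates the statistical structure the downstream analysis assumes: a subset
of transcripts ("binders") is enriched in IP libraries relative to control
libraries, binders carry longer 3'-UTRs and higher CPE element densities,
and read counts are negative-binomially overdispersed.

Two generators, each consuming one documented random stream fully determined
by the configuration seed:

* :func:`generate_utr_set` - log-normal UTR lengths per label group, i.i.d.
  background composition, literal motif planting at a per-kilobase rate.
* :func:`generate_count_matrix` - NB counts with a log-normal expression
  profile scaled to the target depth, an IP fold-change multiplier on
  binders, and per-sample library-size jitter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .motifs import MotifClass, UTRRecord, motif_catalog

logger = logging.getLogger(__name__)

__all__ = ["GeneratorConfig", "TruthLabels", "generate_utr_set", "generate_count_matrix"]

#: group keys used in per-group parameter mappings
BINDER, NONBINDER = "binder", "nonbinder"

#: minimum UTR length (nt); avoids degenerate per-kb densities
MIN_UTR_LENGTH = 50

#: SD of the per-sample log-normal library-size jitter
LIBRARY_JITTER_SD = 0.15

#: max attempts to place one motif without overlapping a previous placement
MAX_PLANT_RETRIES = 100


def _default_length_log_mean():
    # non-binder median ~800 nt, binders 1.5x longer (median ~1200 nt)
    return {BINDER: math.log(1200.0), NONBINDER: math.log(800.0)}


def _default_length_log_sd():
    return {BINDER: 0.8, NONBINDER: 0.8}


def _default_motif_rates():
    # per-kb planting rates; binders carry twice the non-binder density
    return {
        BINDER: {"CPEC": 2.0, "CPENC": 1.0, "Hex": 2.0, "PBE": 0.6},
        NONBINDER: {"CPEC": 1.0, "CPENC": 0.5, "Hex": 1.0, "PBE": 0.3},
    }


def _default_composition():
    # AU-rich background typical of mammalian 3'-UTRs
    return {"A": 0.3, "C": 0.2, "G": 0.2, "U": 0.3}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic RIP-Seq study.

    Defaults describe the study conditions the package is tested under:
    5,000 transcripts, 10% binders, 4-fold IP enrichment, NB dispersion
    alpha = 0.1 (var = mu + alpha mu^2), 3 IP vs 3 control replicates at
    2e6 expected reads per library, binder UTRs 1.5x longer and carrying
    2x the element density of non-binders.
    """

    n_transcripts: int = 5000
    binder_fraction: float = 0.1
    ip_fold_change: float = 4.0
    dispersion: float = 0.1
    n_ip: int = 3
    n_control: int = 3
    depth: float = 2e6
    utr_length_log_mean: Mapping[str, float] = field(default_factory=_default_length_log_mean)
    utr_length_log_sd: Mapping[str, float] = field(default_factory=_default_length_log_sd)
    motif_rate_per_kb: Mapping[str, Mapping[str, float]] = field(default_factory=_default_motif_rates)
    base_composition: Mapping[str, float] = field(default_factory=_default_composition)
    seed: int = 0

    def __post_init__(self):
        if self.n_transcripts <= 0:
            raise ValueError("n_transcripts must be positive")
        if not 0.0 <= self.binder_fraction <= 1.0:
            raise ValueError("binder_fraction must be in [0, 1]")
        if self.ip_fold_change <= 0:
            raise ValueError("ip_fold_change must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_ip < 1 or self.n_control < 1:
            raise ValueError("need at least one replicate per group")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        comp = dict(self.base_composition)
        if set(comp) != set("ACGU"):
            raise ValueError("base_composition must have keys A, C, G, U")
        if any(v < 0 for v in comp.values()):
            raise ValueError("base_composition probabilities must be >= 0")
        if abs(sum(comp.values()) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        for grp in (BINDER, NONBINDER):
            if grp not in self.utr_length_log_mean or grp not in self.utr_length_log_sd:
                raise ValueError(f"missing UTR length parameters for group {grp!r}")
            if grp not in self.motif_rate_per_kb:
                raise ValueError(f"missing motif rates for group {grp!r}")
            if any(r < 0 for r in self.motif_rate_per_kb[grp].values()):
                raise ValueError("motif rates must be >= 0")


@dataclass
class TruthLabels:
    """Ground-truth binder flags, one per generated transcript."""

    labels: Mapping[str, bool]

    @property
    def transcript_ids(self) -> list:
        return list(self.labels)

    @property
    def binders(self) -> list:
        return [t for t, b in self.labels.items() if b]

    @property
    def n_binders(self) -> int:
        return sum(self.labels.values())

    def __getitem__(self, transcript_id: str) -> bool:
        return self.labels[transcript_id]

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"transcript_id": list(self.labels), "is_binder": list(self.labels.values())}
        )


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    # one stream per generator call, keyed on (seed, stream index)
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _plant_motifs(
    seq: np.ndarray,
    rng: np.random.Generator,
    catalog: list,
    rates: Mapping[str, float],
) -> dict:
    """Overwrite background bases with literal motifs at a per-kb rate.

    Placements never overwrite previously planted motifs (retry on
    collision, then skip); returns planted counts per class.
    """
    length = seq.size
    occupied = np.zeros(length, dtype=bool)
    planted = {}
    for cls in catalog:
        rate = rates.get(cls.name, 0.0)
        n_plant = rng.poisson(rate * length / 1000.0) if rate > 0 else 0
        patterns = sorted(cls.patterns)
        placed = 0
        for _ in range(n_plant):
            pat = patterns[rng.integers(len(patterns))]
            plen = len(pat)
            if plen > length:
                continue
            for _attempt in range(MAX_PLANT_RETRIES):
                start = int(rng.integers(0, length - plen + 1))
                if not occupied[start : start + plen].any():
                    seq[start : start + plen] = np.frombuffer(pat.encode(), dtype="S1")
                    occupied[start : start + plen] = True
                    placed += 1
                    break
            else:
                logger.warning(
                    "could not place %s motif after %d retries; skipping",
                    cls.name,
                    MAX_PLANT_RETRIES,
                )
        planted[cls.name] = placed
    return planted


def generate_utr_set(
    config: GeneratorConfig,
    catalog: list | None = None,
    return_planted: bool = False,
):
    """Generate labelled 3'-UTR sequences with planted CPE elements.

    Lengths are log-normal per label group (floored at 50 nt), background
    bases i.i.d. from ``base_composition``, and motifs planted as literal
    in-place substitutions at uniform positions at the configured per-kb
    rate per class. Deterministic given ``config.seed``.

    Returns ``(utrs, truth)``; with ``return_planted=True`` also a list of
    per-transcript planted-count dicts (planted counts are a lower bound on
    scanned counts, since the background can also spell motifs).
    """
    if catalog is None:
        catalog = motif_catalog()
    rng = _rng(config, 0)
    n = config.n_transcripts
    ids = [f"T{i + 1:06d}" for i in range(n)]
    n_binders = round(n * config.binder_fraction)
    is_binder = np.zeros(n, dtype=bool)
    is_binder[rng.permutation(n)[:n_binders]] = True

    bases = np.array([b.encode() for b in "ACGU"], dtype="S1")
    comp = np.array([config.base_composition[b] for b in "ACGU"])
    utrs, planted_all = [], []
    for i in range(n):
        grp = BINDER if is_binder[i] else NONBINDER
        length = max(
            MIN_UTR_LENGTH,
            int(round(rng.lognormal(config.utr_length_log_mean[grp], config.utr_length_log_sd[grp]))),
        )
        seq = rng.choice(bases, size=length, p=comp)
        planted = _plant_motifs(seq, rng, catalog, config.motif_rate_per_kb[grp])
        utrs.append(UTRRecord(ids[i], seq.tobytes().decode()))
        planted_all.append(planted)
    truth = TruthLabels(dict(zip(ids, is_binder.tolist())))
    if return_planted:
        return utrs, truth, planted_all
    return utrs, truth


def generate_count_matrix(labels: TruthLabels, config: GeneratorConfig):
    """Generate an NB RIP-Seq count matrix for the labelled transcripts.

    Per-transcript control means follow a log-normal expression profile
    normalized to ``depth`` expected reads per library; IP means multiply
    binder means by ``ip_fold_change``. Counts are NB with
    var = mu + dispersion * mu^2 (Poisson when dispersion is 0), with
    per-sample log-normal library-size jitter. Deterministic given seed.

    Returns ``(counts, design)``: a transcripts x samples integer DataFrame
    and a :class:`~ripcpe.enrichment.SampleDesign`.
    """
    from .enrichment import SampleDesign

    if len(labels) == 0:
        raise ValueError("labels must be nonempty")
    rng = _rng(config, 1)
    ids = labels.transcript_ids
    n = len(ids)
    is_binder = np.array([labels[t] for t in ids])

    expr = rng.lognormal(0.0, 1.0, size=n)
    control_mu = config.depth * expr / expr.sum()
    ip_mu = control_mu * np.where(is_binder, config.ip_fold_change, 1.0)

    sample_ids = [f"IP{j + 1}" for j in range(config.n_ip)] + [
        f"CTRL{j + 1}" for j in range(config.n_control)
    ]
    groups = ["IP"] * config.n_ip + ["control"] * config.n_control
    jitter = np.exp(rng.normal(0.0, LIBRARY_JITTER_SD, size=len(sample_ids)))

    counts = np.empty((n, len(sample_ids)), dtype=np.int64)
    for j, grp in enumerate(groups):
        mu = (ip_mu if grp == "IP" else control_mu) * jitter[j]
        if config.dispersion == 0:
            counts[:, j] = rng.poisson(mu)
        else:
            size = 1.0 / config.dispersion
            counts[:, j] = rng.negative_binomial(size, size / (size + mu))
    df = pd.DataFrame(counts, index=pd.Index(ids, name="transcript_id"), columns=sample_ids)
    design = SampleDesign(dict(zip(sample_ids, groups)))
    return df, design
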