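"""End-to-end orchestration: simulate/load -> call binders -> scan -> compare.

A :class:`RunConfig` (built directly or from a YAML file) names either real
inputs (FASTA + counts + sample sheet) or a synthetic-generator block, plus
the analysis thresholds. :func:`run_pipeline` executes all stages in order,
writes every output table and a manifest, and is byte-deterministic given
the same configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as rio
from .characterize import BinderScore, compare_binders
from .enrichment import RIPEnrichment, SampleDesign
from .motifs import motif_catalog, motif_map, read_utr_fasta, scan_utrs, write_utr_fasta
from .simulate import GeneratorConfig, generate_count_matrix, generate_utr_set

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "load_inputs", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Exactly one of ``generator`` (a :class:`GeneratorConfig`) or the three
    input paths (``fasta``, ``counts``, ``design``) must be set.
    """

    outdir: Path
    generator: GeneratorConfig | None = None
    fasta: Path | None = None
    counts: Path | None = None
    design: Path | None = None
    lfc_min: float = 0.0
    fdr_max: float = 0.01
    k: int = 3
    cluster_gap: int = 400
    score: bool = False
    seed: int = 0

    def __post_init__(self):
        have_files = any(p is not None for p in (self.fasta, self.counts, self.design))
        if (self.generator is None) == (not have_files):
            raise ValueError("config must set exactly one of: generator block, input paths")
        if have_files and None in (self.fasta, self.counts, self.design):
            raise ValueError("real-input mode needs fasta, counts and design paths")
        if not 0.0 < self.fdr_max <= 1.0:
            raise ValueError("fdr_max must be in (0, 1]")
        if self.cluster_gap <= 0:
            raise ValueError("cluster_gap must be positive")
        self.outdir = Path(self.outdir)

    @classmethod
    def from_yaml(cls, path, outdir=None, seed=None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen_block = raw.get("generator")
        inputs = raw.get("inputs", {})
        thresholds = raw.get("thresholds", {})
        cfg_seed = seed if seed is not None else int(raw.get("seed", 0))
        gen = None
        if gen_block is not None:
            gen = GeneratorConfig(**{**gen_block, "seed": cfg_seed})
        return cls(
            outdir=Path(outdir if outdir is not None else raw.get("outdir", "ripcpe_out")),
            generator=gen,
            fasta=inputs.get("fasta"),
            counts=inputs.get("counts"),
            design=inputs.get("design"),
            lfc_min=float(thresholds.get("lfc_min", 0.0)),
            fdr_max=float(thresholds.get("fdr_max", 0.01)),
            k=int(thresholds.get("k", 3)),
            cluster_gap=int(thresholds.get("cluster_gap", 400)),
            score=bool(raw.get("score", False)),
            seed=cfg_seed,
        )

    def echo(self) -> dict:
        d = {
            "lfc_min": self.lfc_min,
            "fdr_max": self.fdr_max,
            "k": self.k,
            "cluster_gap": self.cluster_gap,
            "score": self.score,
            "seed": self.seed,
        }
        if self.generator is not None:
            g = self.generator
            d["generator"] = {
                "n_transcripts": g.n_transcripts,
                "binder_fraction": g.binder_fraction,
                "ip_fold_change": g.ip_fold_change,
                "dispersion": g.dispersion,
                "n_ip": g.n_ip,
                "n_control": g.n_control,
                "depth": g.depth,
                "utr_length_log_mean": dict(g.utr_length_log_mean),
                "utr_length_log_sd": dict(g.utr_length_log_sd),
                "motif_rate_per_kb": {k: dict(v) for k, v in g.motif_rate_per_kb.items()},
                "base_composition": dict(g.base_composition),
                "seed": g.seed,
            }
        else:
            d["inputs"] = {
                "fasta": str(self.fasta),
                "counts": str(self.counts),
                "design": str(self.design),
            }
        return d


def load_inputs(config: RunConfig):
    """Produce (utrs, counts, design, truth-or-None) for a run.

    Generator mode synthesizes everything in memory (and `run_pipeline`
    also writes it to disk); file mode parses and reconciles the FASTA
    against the count matrix. Transcripts present in counts but absent from
    the FASTA stay in binder calling and are dropped from motif statistics
    (logged); an empty identifier intersection is fatal.
    """
    if config.generator is not None:
        gen = config.generator
        utrs, truth = generate_utr_set(gen)
        counts, design = generate_count_matrix(truth, gen)
        return utrs, counts, design, truth
    utrs = read_utr_fasta(config.fasta)
    counts = rio.read_counts(config.counts)
    design_frame = rio.read_design_frame(config.design)
    design = SampleDesign(dict(zip(design_frame["sample_id"], design_frame["group"])))
    fasta_ids = {u.transcript_id for u in utrs}
    count_ids = set(counts.index)
    inter = fasta_ids & count_ids
    if not inter:
        raise ValueError("no transcript identifiers shared between FASTA and count matrix")
    n_missing = len(count_ids - fasta_ids)
    if n_missing:
        logger.info(
            "%d transcripts in counts lack a UTR sequence; kept for binder "
            "calling, dropped from motif statistics",
            n_missing,
        )
    utrs = [u for u in utrs if u.transcript_id in count_ids]
    return utrs, counts, design, None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name):
    def wrap(fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001
            raise StageError(name, exc) from exc

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to disk).

    Outputs under ``config.outdir``: counts/design/truth/FASTA (generator
    mode), ``enrichment.tsv``, ``profiles.tsv``, ``motifs.bed``,
    ``comparison.json``, optionally ``scores.tsv``, and ``manifest.json``.
    Identical config + seed give byte-identical outputs.
    """
    from importlib.metadata import PackageNotFoundError, version

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts_stage = _stage("load_inputs")
    utrs, counts, design, truth = counts_stage(load_inputs, config)

    written = {}
    if config.generator is not None:
        write_utr_fasta(utrs, outdir / "utrs.fasta")
        rio.write_counts(counts, outdir / "counts.tsv")
        rio.write_design(design, outdir / "design.tsv")
        rio.write_truth(truth, outdir / "truth.tsv")
        written.update(
            {n: outdir / f for n, f in
             [("fasta", "utrs.fasta"), ("counts", "counts.tsv"),
              ("design", "design.tsv"), ("truth", "truth.tsv")]}
        )

    # binder calling on the full count matrix
    fit = _stage("call_binders")(
        lambda: RIPEnrichment(counts, design).fit(lfc_min=config.lfc_min, fdr_max=config.fdr_max)
    )
    rio.write_enrichment(fit.to_frame().set_index("transcript_id"), outdir / "enrichment.tsv")
    written["enrichment"] = outdir / "enrichment.tsv"

    # motif scanning on transcripts with a UTR sequence
    def do_scan():
        catalog = motif_catalog()
        profiles = scan_utrs(utrs, catalog)
        frame = rio.profiles_to_frame(profiles)
        tracks = {}
        for u in utrs:
            track, _clusters = motif_map(u, catalog, cluster_gap=config.cluster_gap)
            if track:
                tracks[u.transcript_id] = track
        return frame, tracks

    profile_frame, tracks = _stage("scan")(do_scan)
    rio.write_profiles(profile_frame, outdir / "profiles.tsv")
    rio.write_bed(tracks, outdir / "motifs.bed")
    written["profiles"] = outdir / "profiles.tsv"
    written["bed"] = outdir / "motifs.bed"

    # binder vs non-binder comparison, on the id intersection
    def do_compare():
        labels = {
            t: bool(b)
            for t, b in fit.table["is_binder"].items()
            if t in profile_frame.index
        }
        report = compare_binders(profile_frame.loc[list(labels)], labels, k=config.k)
        return labels, report

    labels, report = _stage("compare")(do_compare)
    with open(outdir / "comparison.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    written["comparison"] = outdir / "comparison.json"

    if config.score:
        def do_score():
            model = BinderScore(profile_frame.loc[list(labels)], labels)
            return model.fit()

        score_res = _stage("score")(do_score)
        score_res.to_frame().to_csv(outdir / "scores.tsv", sep="\t", index=False,
                                    float_format="%.6g")
        written["scores"] = outdir / "scores.tsv"

    try:
        pkg_version = version("ripcpe")
    except PackageNotFoundError:
        pkg_version = "unknown"
    config_echo = config.echo()
    manifest = {
        "package": "ripcpe",
        "version": pkg_version,
        "seed": config.seed,
        "config": config_echo,
        "config_sha256": hashlib.sha256(
            json.dumps(config_echo, sort_keys=True).encode()
        ).hexdigest(),
        "records": {
            "transcripts_in_counts": int(counts.shape[0]),
            "samples": int(counts.shape[1]),
            "transcripts_with_utr": len(utrs),
            "enrichment_rows": int(fit.table.shape[0]),
            "profile_rows": int(profile_frame.shape[0]),
            "binders_called": fit.n_binders,
            "compared": len(labels),
        },
        "outputs": {name: {"path": p.name, "sha256": _sha256(p)} for name, p in written.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
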