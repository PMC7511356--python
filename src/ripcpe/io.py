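"""Tab-separated and BED readers/writers for the pipeline's tables.

All TSVs carry a header row, UTF-8, and "." for missing values. BED output
is BED6 with 0-based half-open coordinates (internal coordinates are
1-based inclusive; the conversion happens here).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .motifs import MotifProfile

NA_REP = "."

__all__ = [
    "read_counts",
    "write_counts",
    "read_design_frame",
    "write_design",
    "read_truth",
    "write_truth",
    "profiles_to_frame",
    "write_profiles",
    "read_profiles",
    "write_enrichment",
    "read_enrichment",
    "write_bed",
]


def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", na_values=[NA_REP], keep_default_na=False, **kw)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"malformed TSV {path}: {exc}") from exc


def read_counts(path) -> pd.DataFrame:
    df = _read_tsv(path)
    if df.columns[0] != "transcript_id":
        raise ValueError(f"{path}: first column must be 'transcript_id'")
    df = df.set_index("transcript_id")
    if df.isna().any().any():
        raise ValueError(f"{path}: count matrix has missing cells")
    return df.astype(np.int64)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("transcript_id").to_csv(path, sep="\t", na_rep=NA_REP)


def read_design_frame(path) -> pd.DataFrame:
    df = _read_tsv(path)
    if not {"sample_id", "group"} <= set(df.columns):
        raise ValueError(f"{path}: sample sheet needs 'sample_id' and 'group' columns")
    return df


def write_design(design, path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_truth(path) -> dict:
    df = _read_tsv(path)
    return dict(zip(df["transcript_id"], df["is_binder"].astype(bool)))


def write_truth(truth, path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)


def profiles_to_frame(profiles: Iterable[MotifProfile]) -> pd.DataFrame:
    """Flatten motif profiles to a table: per-class count and per-kb density
    columns plus UTR length, indexed by transcript id."""
    rows = []
    for p in profiles:
        row = {"transcript_id": p.transcript_id, "utr_length": p.utr_length}
        dens = p.densities
        for cls, pos in p.positions.items():
            row[f"{cls}_count"] = len(pos)
            row[f"{cls}_density"] = dens[cls]
        rows.append(row)
    return pd.DataFrame(rows).set_index("transcript_id")


def write_profiles(frame: pd.DataFrame, path) -> None:
    frame.rename_axis("transcript_id").to_csv(path, sep="\t", na_rep=NA_REP, float_format="%.6g")


def read_profiles(path) -> pd.DataFrame:
    return _read_tsv(path).set_index("transcript_id")


def write_enrichment(frame: pd.DataFrame, path) -> None:
    frame.rename_axis("transcript_id").to_csv(path, sep="\t", na_rep=NA_REP, float_format="%.6g")


def read_enrichment(path) -> pd.DataFrame:
    df = _read_tsv(path).set_index("transcript_id")
    if "is_binder" in df.columns:
        df["is_binder"] = df["is_binder"].astype(bool)
    return df


def write_bed(tracks: Mapping[str, list], path) -> None:
    """Write motif matches as BED6; keys are sequence names, values lists of
    :class:`~ripcpe.motifs.MotifMatch` (1-based inclusive -> 0-based half-open)."""
    with open(path, "w") as fh:
        for seq_name, matches in tracks.items():
            for m in matches:
                fh.write(
                    f"{seq_name}\t{m.start - 1}\t{m.end}\t{m.class_name}:{m.pattern}\t0\t+\n"
                )
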