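"""Batch entropy-loss screening of many replicons.

Each input FASTA file is scored as one replicon (a chromosome or
plasmid) at a set of platform-representative read lengths — by default
125 bp (short-read), 500 bp (pyrosequencing) and 3000 bp (single
molecule).  The per-replicon losses are then summarized as a quartile
distribution and ranked to surface the most repeat-laden outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .entropy_core import assess
from .errors import ReadEntropyError
from .fasta_io import read_fasta, write_tsv

DEFAULT_READ_LENGTHS: tuple[int, ...] = (125, 500, 3000)
ZERO_TOLERANCE = 1e-15


@dataclass(frozen=True)
class SurveyRow:
    replicon_id: str
    length: int
    delta_H_by_k: Mapping[int, float]
    status: str  # "ok" | "degenerate" | "error"
    detail: str = ""


@dataclass(frozen=True)
class DistributionSummary:
    """Quartile summary of dH across replicons at one read length.

    Quartiles use linear interpolation between order statistics.
    n_above_threshold counts dH >= threshold; n_nonzero counts dH > 0
    (beyond 1e-15).
    """

    read_length: int
    n: int
    mean: float
    quartile_1: float
    median: float
    quartile_3: float
    minimum: float
    maximum: float
    n_above_threshold: int
    n_nonzero: int
    threshold: float = 0.01


def survey(
    paths: Sequence[str | Path],
    read_lengths: Sequence[int] = DEFAULT_READ_LENGTHS,
    prefix_length: int = 0,
) -> list[SurveyRow]:
    """Score each FASTA file as one replicon at every requested read length.

    Failures are isolated per file: an unreadable file or a replicon
    shorter than every read length yields a row with a non-ok status and
    the survey continues.  Row order matches input order.
    """
    if not paths:
        raise ValueError("at least one input path required")
    read_lengths = sorted(set(int(k) for k in read_lengths))
    if not read_lengths:
        raise ValueError("at least one read length required")

    rows: list[SurveyRow] = []
    for path in paths:
        path = Path(path)
        try:
            records = read_fasta(path)
        except (OSError, ReadEntropyError) as exc:
            rows.append(SurveyRow(path.stem, 0, {}, "error", str(exc)))
            continue
        length = sum(r.length for r in records)
        losses: dict[int, float] = {}
        status = "ok"
        detail = ""
        for k in read_lengths:
            try:
                losses[k] = assess(records, k, prefix_length).delta_H
            except ReadEntropyError as exc:
                status = "degenerate"
                detail = f"k={k}: {exc}"
                losses = {}
                break
        rows.append(SurveyRow(records[0].identifier, length, losses, status, detail))
    return rows


def summarize(
    rows: Sequence[SurveyRow],
    read_length: int,
    threshold: float = 0.01,
) -> DistributionSummary:
    """Distribution summary of dH over the ok rows at one read length."""
    values = np.array(
        [row.delta_H_by_k[read_length] for row in rows
         if row.status == "ok" and read_length in row.delta_H_by_k],
        dtype=np.float64,
    )
    if values.size == 0:
        raise ValueError(f"no ok rows carry read length {read_length}")
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    return DistributionSummary(
        read_length=read_length,
        n=int(values.size),
        mean=float(values.mean()),
        quartile_1=float(q1),
        median=float(med),
        quartile_3=float(q3),
        minimum=float(values.min()),
        maximum=float(values.max()),
        n_above_threshold=int(np.sum(values >= threshold)),
        n_nonzero=int(np.sum(values > ZERO_TOLERANCE)),
        threshold=threshold,
    )


def rank_outliers(
    rows: Sequence[SurveyRow],
    read_length: int,
    top_n: int = 10,
) -> list[SurveyRow]:
    """The top_n ok rows by descending dH at one read length.

    Ties are broken by replicon_id ascending.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    eligible = [r for r in rows if r.status == "ok" and read_length in r.delta_H_by_k]
    ranked = sorted(eligible, key=lambda r: (-r.delta_H_by_k[read_length], r.replicon_id))
    return ranked[:top_n]


def write_survey_tsv(rows: Sequence[SurveyRow], path: str | Path) -> None:
    read_lengths = sorted({k for r in rows for k in r.delta_H_by_k})
    cols = ["replicon_id", "length_bp"] + [f"dH_k{k}" for k in read_lengths] + ["status"]
    out_rows = []
    for r in rows:
        row: dict[str, object] = {"replicon_id": r.replicon_id, "length_bp": r.length,
                                  "status": r.status}
        for k in read_lengths:
            row[f"dH_k{k}"] = r.delta_H_by_k.get(k, float("nan"))
        out_rows.append(row)
    write_tsv(out_rows, path, cols,
              percent_columns=[f"dH_k{k}" for k in read_lengths],
              percent_decimals=6)


def write_summary_tsv(summaries: Sequence[DistributionSummary], path: str | Path) -> None:
    cols = ["read_length", "n", "mean", "quartile_1", "median", "quartile_3",
            "minimum", "maximum", "n_above_threshold", "n_nonzero", "quartile_method"]
    rows = [
        {"read_length": s.read_length, "n": s.n, "mean": s.mean,
         "quartile_1": s.quartile_1, "median": s.median, "quartile_3": s.quartile_3,
         "minimum": s.minimum, "maximum": s.maximum,
         "n_above_threshold": s.n_above_threshold, "n_nonzero": s.n_nonzero,
         "quartile_method": "linear-interpolation"}
        for s in summaries
    ]
    write_tsv(rows, path, cols,
              percent_columns=["mean", "quartile_1", "median", "quartile_3",
                               "minimum", "maximum"],
              percent_decimals=6)
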