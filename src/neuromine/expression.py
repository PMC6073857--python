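"""Read assignment, FPKM normalisation and tissue/stage expression calls.

Expression of mined transcripts is profiled by mapping reads back to the
coding sequences with a gapless matcher honouring two thresholds — the
fraction of the read that must align and the identity required over that
overlap — normalising counts to FPKM (fragments per kilobase of
transcript per million mapped fragments), binning FPKM values by
empirical percentile for heat-map display, and contrasting immature
versus mature stages of paired tissues (ovary, hepatopancreas) to flag
stage-switched transcripts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MappingParams:
    min_length_fraction: float = 0.75
    min_similarity_fraction: float = 0.85

    def __post_init__(self) -> None:
        for v in (self.min_length_fraction, self.min_similarity_fraction):
            if not 0 < v <= 1:
                raise ValueError("mapping fractions must lie in (0, 1]")


def _best_gapless_match(read: str, transcript: str, min_overlap: int) -> tuple[int, int]:
    """(matches, overlap) of the best gapless placement of read on
    transcript, allowing read overhangs as long as the overlap is at
    least ``min_overlap``."""
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    t = np.frombuffer(transcript.encode(), dtype=np.uint8)
    lr, lt = len(r), len(t)
    best = (0, 0)
    for off in range(-(lr - min_overlap), lt - min_overlap + 1):
        r0 = max(0, -off)
        t0 = max(0, off)
        ov = min(lr - r0, lt - t0)
        if ov < min_overlap:
            continue
        matches = int((r[r0 : r0 + ov] == t[t0 : t0 + ov]).sum())
        if matches > best[0]:
            best = (matches, ov)
    return best


def assign_reads(
    reads: list[tuple[str, str]],
    transcripts: dict[str, str],
    params: MappingParams | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Assign each read to its best-matching transcript(s).

    A placement qualifies when its gapless overlap covers at least
    ``min_length_fraction`` of the read at ``min_similarity_fraction``
    identity over the overlap. Reads tying across several transcripts are
    split equally (fractional counts). Returns (counts per transcript,
    per-read assignment table). Deterministic.
    """
    if not reads or not transcripts:
        raise ValueError("reads and transcripts must be non-empty")
    params = params or MappingParams()
    tids = list(transcripts)
    counts = pd.Series(0.0, index=tids)
    rows = []
    for rid, rseq in reads:
        min_overlap = math.ceil(params.min_length_fraction * len(rseq))
        best_score, hits = 0, []
        for tid in tids:
            matches, ov = _best_gapless_match(rseq, transcripts[tid], min_overlap)
            if ov == 0 or matches / ov < params.min_similarity_fraction:
                continue
            if matches > best_score:
                best_score, hits = matches, [tid]
            elif matches == best_score and best_score > 0:
                hits.append(tid)
        if hits:
            frac = 1.0 / len(hits)
            for tid in hits:
                counts[tid] += frac
            if len(hits) > 1:
                logger.info("read %s multi-maps to %s (split equally)", rid, hits)
        rows.append(dict(read_id=rid, n_hits=len(hits), assigned=";".join(hits)))
    return counts, pd.DataFrame(rows)


def fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """FPKM = counts x 1e9 / (transcript length in nt x library size).

    ``library_sizes`` defaults to per-tissue column sums (mapped
    fragments per library).
    """
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("all transcript lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any() or library_sizes.isna().any():
        raise ValueError("library sizes must be positive")
    return counts.mul(1e9).div(lengths, axis=0).div(library_sizes, axis=1)


ABSENT_BIN = "absent"


def percentile_bins(values: pd.DataFrame, n_bins: int = 4) -> pd.DataFrame:
    """Percentile-of-distribution bins for heat-map colour coding.

    Zero cells get the dedicated "absent" bin; nonzero cells are binned
    by empirical percentile over all nonzero values in the matrix
    (default quartiles, labels Q1..Q4). A value equal to a bin edge falls
    into the lower bin.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    arr = values.to_numpy(float)
    nonzero = arr[arr > 0]
    labels = np.full(arr.shape, ABSENT_BIN, dtype=object)
    if nonzero.size:
        edges = np.percentile(nonzero, [100 * k / n_bins for k in range(1, n_bins)])
        pos = arr > 0
        bin_idx = np.ones(arr.shape, dtype=int)
        for e in edges:
            bin_idx += (arr > e) & pos
        labels[pos] = np.char.add("Q", bin_idx[pos].astype(str))
    return pd.DataFrame(labels, index=values.index, columns=values.columns)


def stage_contrast(
    fpkm_matrix: pd.DataFrame, presence_threshold: float = 1.0
) -> tuple[pd.DataFrame, pd.Series]:
    """Immature/mature presence switches for paired tissue columns.

    Columns must be named ``tissue_stage`` with stages immature/mature.
    Presence means FPKM >= threshold. Calls per transcript and tissue:
    "immature-only", "mature-only", "both", or "absent"; tissues missing
    a stage are skipped with a warning. Also returns summary counts of
    each call.
    """
    tissues: dict[str, dict[str, str]] = {}
    for col in fpkm_matrix.columns:
        tissue, _, stage = col.rpartition("_")
        if stage in ("immature", "mature") and tissue:
            tissues.setdefault(tissue, {})[stage] = col
    calls = {}
    for tissue, stages in sorted(tissues.items()):
        if set(stages) != {"immature", "mature"}:
            logger.warning("tissue %s lacks a stage pair; skipped", tissue)
            continue
        imm = fpkm_matrix[stages["immature"]] >= presence_threshold
        mat = fpkm_matrix[stages["mature"]] >= presence_threshold
        call = pd.Series("absent", index=fpkm_matrix.index)
        call[imm & mat] = "both"
        call[imm & ~mat] = "immature-only"
        call[~imm & mat] = "mature-only"
        calls[tissue] = call
    table = pd.DataFrame(calls)
    summary = (
        table.stack().value_counts().rename("n")
        if not table.empty
        else pd.Series(dtype=int, name="n")
    )
    return table, summary
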