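"""Gene-level event calling, discovery and validation over regions of interest.

A sample is positive for an event in a gene/region when strictly more than
half of its non-missing probes inside the locus carry the event. The
discovery step Fisher-tests every (gene, event, variant) triple at a nominal
alpha of 0.05; the validation step re-applies the same gene-level method on
an independent cohort, skipping regions covered by two or fewer probes on
the validation manifest.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .association import fisher_one_sided
from .model import (
    AnalysisParams,
    EventMatrix,
    EventType,
    GeneRegion,
    GroupSplit,
    NoProbeCoverageError,
    ProbeManifest,
)

__all__ = [
    "gene_event_call",
    "goi_discovery",
    "validate_shortlist",
    "event_overlap",
]

logger = logging.getLogger(__name__)

_GOI_COLUMNS = [
    "variant_id",
    "name",
    "chrom",
    "start",
    "end",
    "event",
    "a",
    "b",
    "c",
    "d",
    "p",
    "shortlisted",
]


def gene_event_call(
    matrix: EventMatrix,
    region: GeneRegion,
    manifest: ProbeManifest,
    params: AnalysisParams | None = None,
) -> pd.Series:
    """Per-sample positive/negative/missing call for an event in a region.

    Positive iff the positive fraction among the sample's non-missing probes
    in [start, end] exceeds ``params.goi_fraction`` (strictly); NaN when the
    sample has no non-missing probe in the locus.
    """
    params = params or AnalysisParams()
    idx = manifest.probes_in_region(region.chrom, region.start, region.end)
    if idx.size == 0:
        raise NoProbeCoverageError(
            f"region {region.name} ({region.label}) has no probe coverage"
        )
    sub = matrix.values[:, idx]
    pos = np.nansum(sub, axis=1)
    n = np.sum(~np.isnan(sub), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = pos / n
    call = (frac > params.goi_fraction).astype(float)
    call[n == 0] = np.nan
    return pd.Series(call, index=matrix.sample_ids, name=region.name)


def _two_by_two(calls: pd.Series, split: GroupSplit):
    """2x2 counts from per-sample calls, dropping missing samples."""
    risk = calls.reindex(list(split.risk_group)).dropna()
    other = calls.reindex(list(split.other_group)).dropna()
    a = int(risk.sum())
    b = len(risk) - a
    c = int(other.sum())
    d = len(other) - c
    return a, b, c, d, len(risk), len(other)


def goi_discovery(
    matrices: dict[EventType, EventMatrix],
    regions: list[GeneRegion],
    splits: dict[str, GroupSplit],
    manifest: ProbeManifest,
    params: AnalysisParams | None = None,
) -> pd.DataFrame:
    """Fisher-test every (gene, event, variant) triple at the gene level.

    Rows with a degenerate table (one group entirely missing in the locus)
    carry a NaN p and are logged. ``shortlisted`` marks p < goi_alpha.
    """
    params = params or AnalysisParams()
    rows = []
    for region in regions:
        idx = manifest.probes_in_region(region.chrom, region.start, region.end)
        if idx.size == 0:
            logger.warning("region %s has no probe coverage; skipped", region.name)
            continue
        for event, matrix in matrices.items():
            calls = gene_event_call(matrix, region, manifest, params)
            for variant_id, split in splits.items():
                a, b, c, d, n_risk, n_other = _two_by_two(calls, split)
                if n_risk == 0 or n_other == 0:
                    logger.warning(
                        "degenerate table for %s / %s / %s (empty group after drops)",
                        region.name,
                        event.name,
                        variant_id,
                    )
                    p = np.nan
                else:
                    p = fisher_one_sided(a, b, c, d)
                rows.append(
                    {
                        "variant_id": variant_id,
                        "name": region.name,
                        "chrom": region.chrom,
                        "start": region.start,
                        "end": region.end,
                        "event": event.name,
                        "a": a,
                        "b": b,
                        "c": c,
                        "d": d,
                        "p": p,
                        "shortlisted": bool(p < params.goi_alpha)
                        if not np.isnan(p)
                        else False,
                    }
                )
    return pd.DataFrame(rows, columns=_GOI_COLUMNS)


def validate_shortlist(
    shortlist: pd.DataFrame,
    matrices: dict[EventType, EventMatrix],
    splits: dict[str, GroupSplit],
    manifest: ProbeManifest,
    params: AnalysisParams | None = None,
) -> pd.DataFrame:
    """Re-test shortlisted (region, event, variant) triples on a new cohort.

    Regions covered by fewer than ``params.min_validation_probes`` probes on
    the validation manifest (i.e. <= 2 at the default) are marked untestable.
    The gene-level (> 50% of probes) method is used for every row, including
    regions discovered by the global probe scan.
    """
    params = params or AnalysisParams()
    out = []
    for _, row in shortlist.iterrows():
        region = GeneRegion(
            name=row["name"], chrom=row["chrom"], start=int(row["start"]), end=int(row["end"])
        )
        event = EventType.from_label(row["event"])
        rec = {
            "variant_id": row["variant_id"],
            "name": region.name,
            "chrom": region.chrom,
            "start": region.start,
            "end": region.end,
            "event": event.name,
        }
        idx = manifest.probes_in_region(region.chrom, region.start, region.end)
        rec["n_probes_validation"] = int(idx.size)
        if idx.size < params.min_validation_probes:
            rec.update(
                untestable=True,
                a=np.nan, b=np.nan, c=np.nan, d=np.nan,
                p=np.nan,
                validated=False,
            )
            out.append(rec)
            continue
        split = splits[row["variant_id"]]
        calls = gene_event_call(matrices[event], region, manifest, params)
        a, b, c, d, n_risk, n_other = _two_by_two(calls, split)
        if n_risk == 0 or n_other == 0:
            p = np.nan
        else:
            p = fisher_one_sided(a, b, c, d)
        rec.update(
            untestable=False,
            a=a, b=b, c=c, d=d,
            p=p,
            validated=bool(p < params.goi_alpha) if not np.isnan(p) else False,
        )
        out.append(rec)
    return pd.DataFrame(
        out,
        columns=[
            "variant_id", "name", "chrom", "start", "end", "event",
            "n_probes_validation", "untestable", "a", "b", "c", "d", "p", "validated",
        ],
    )


def event_overlap(
    calls_a: pd.Series, calls_b: pd.Series, samples: list[str] | None = None
) -> tuple[int, int, int, int]:
    """Co-occurrence counts of two per-sample event calls.

    Returns (only A, only B, both, neither) over ``samples`` (default: the
    common index); the four counts sum to the subset size. Calls must be
    non-missing booleans over the subset.
    """
    if samples is None:
        if set(calls_a.index) != set(calls_b.index):
            raise ValueError("call series cover different sample sets")
        samples = list(calls_a.index)
    a = calls_a.reindex(samples)
    b = calls_b.reindex(samples)
    if a.isna().any() or b.isna().any():
        raise ValueError("calls missing for some samples in the subset")
    a = a.astype(bool).to_numpy()
    b = b.astype(bool).to_numpy()
    both = int((a & b).sum())
    only_a = int((a & ~b).sum())
    only_b = int((~a & b).sum())
    neither = int((~a & ~b).sum())
    return only_a, only_b, both, neither
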