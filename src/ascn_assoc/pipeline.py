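"""End-to-end discovery and validation orchestration.

Discovery runs two complementary routes on one cohort:

* the **global** route — per-event frequency cutoffs by position
  permutation, a one-sided Fisher scan over recurrent probes for each
  (variant, event) pair, a label-permutation genome-wide p cutoff and the
  resulting significant regions;
* the **genes-of-interest (GOI)** route — gene-level (> 50%-of-probes)
  event calls over declared regions, Fisher-tested at a nominal alpha.

Both shortlists merge into one report; validation re-tests every row with
the gene-level method on an independent cohort, skipping regions with too
few probes on the validation manifest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import (
    p_cutoff_by_permutation,
    probe_scan,
    significant_regions,
    split_groups,
    fisher_one_sided,
)
from .events import EVENT_ORDER, build_event_matrices, classify_ploidy, rescale_profile
from .genes import gene_event_call, goi_discovery, validate_shortlist, _two_by_two
from .model import (
    AnalysisParams,
    ASCNProfile,
    DegenerateSplitError,
    EventMatrix,
    EventType,
    GeneRegion,
    GenotypeTable,
    GroupSplit,
    ProbeManifest,
    RiskVariantSpec,
)
from .recurrence import frequency_cutoff

__all__ = ["DiscoveryReport", "run_discovery", "run_validation", "prepare_matrices"]

logger = logging.getLogger(__name__)

_SHORTLIST_COLUMNS = [
    "approach",
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
    "freq_cutoff",
    "p_cutoff",
    "n_probes",
    "min_p",
]


@dataclass
class GlobalScanRecord:
    variant_id: str
    event: EventType
    freq_cutoff: float
    p_cutoff: float
    scan: pd.DataFrame = field(repr=False)
    regions: pd.DataFrame = field(repr=False)


@dataclass
class DiscoveryReport:
    params: AnalysisParams
    ploidy_classes: pd.Series
    freq_cutoffs: dict[EventType, float]
    global_records: list[GlobalScanRecord]
    goi_table: pd.DataFrame
    shortlist: pd.DataFrame


def prepare_matrices(
    profiles: list[ASCNProfile],
    manifest: ProbeManifest,
    params: AnalysisParams,
) -> tuple[dict[EventType, EventMatrix], pd.Series]:
    """Ploidy-classify, rescale and build the eight event matrices."""
    classes = {
        p.sample_id: classify_ploidy(p.ploidy, params.ploidy_cutoff) for p in profiles
    }
    rescaled = [
        rescale_profile(p, classes[p.sample_id], params.ploidy_cutoff)
        for p in profiles
    ]
    matrices = build_event_matrices(rescaled, manifest, params)
    return matrices, pd.Series({s: c.value for s, c in classes.items()})


def _make_splits(
    genotypes: GenotypeTable, variants: list[RiskVariantSpec]
) -> dict[str, GroupSplit]:
    splits = {}
    for spec in variants:
        try:
            splits[spec.variant_id] = split_groups(genotypes, spec)
        except (KeyError, DegenerateSplitError) as exc:
            logger.warning("skipping %s: %s", spec.variant_id, exc)
    if not splits:
        raise ValueError("no risk variant produced a usable genotype split")
    return splits


def run_discovery(
    profiles: list[ASCNProfile],
    genotypes: GenotypeTable,
    manifest: ProbeManifest,
    variants: list[RiskVariantSpec],
    regions: list[GeneRegion],
    params: AnalysisParams | None = None,
    events: list[EventType] | None = None,
    seed: int | None = None,
) -> DiscoveryReport:
    """Run the full discovery phase (global + genes-of-interest routes).

    ``events`` restricts the global scan to selected event types (default:
    all eight). ``seed`` overrides ``params.rng_seed`` for the permutation
    procedures.
    """
    params = params or AnalysisParams()
    if seed is None:
        seed = params.rng_seed
    rng = np.random.default_rng(seed)
    events = list(events) if events is not None else list(EVENT_ORDER)

    try:
        matrices, classes = prepare_matrices(profiles, manifest, params)
    except ValueError as exc:
        raise ValueError(f"[stage: event matrices] {exc}") from exc
    splits = _make_splits(genotypes, variants)

    freq_cutoffs = {
        ev: frequency_cutoff(matrices[ev], manifest, params, rng) for ev in events
    }

    global_records: list[GlobalScanRecord] = []
    shortlist_rows: list[dict] = []
    for spec_id, split in splits.items():
        for ev in events:
            cutoff = freq_cutoffs[ev]
            scan = probe_scan(matrices[ev], split, cutoff, manifest, params)
            p_cut = p_cutoff_by_permutation(matrices[ev], split, cutoff, params, rng)
            regs = significant_regions(scan, p_cut, manifest)
            global_records.append(
                GlobalScanRecord(spec_id, ev, cutoff, p_cut, scan, regs)
            )
            for _, reg in regs.iterrows():
                region = GeneRegion(
                    name=f"{reg['chrom']}:{reg['start']}-{reg['end']}",
                    chrom=reg["chrom"],
                    start=int(reg["start"]),
                    end=int(reg["end"]),
                )
                # gene-level 2x2 on the discovered region, for reporting and
                # for the validation step (which uses the gene-level method)
                calls = gene_event_call(matrices[ev], region, manifest, params)
                a, b, c, d, n_risk, n_other = _two_by_two(calls, split)
                p = (
                    fisher_one_sided(a, b, c, d)
                    if n_risk > 0 and n_other > 0
                    else np.nan
                )
                shortlist_rows.append(
                    {
                        "approach": "global",
                        "variant_id": spec_id,
                        "name": region.name,
                        "chrom": region.chrom,
                        "start": region.start,
                        "end": region.end,
                        "event": ev.name,
                        "a": a,
                        "b": b,
                        "c": c,
                        "d": d,
                        "p": p,
                        "freq_cutoff": cutoff,
                        "p_cutoff": p_cut,
                        "n_probes": int(reg["n_probes"]),
                        "min_p": float(reg["min_p"]),
                    }
                )

    goi_table = goi_discovery(matrices, regions, splits, manifest, params)
    for _, row in goi_table.loc[goi_table["shortlisted"]].iterrows():
        shortlist_rows.append(
            {
                "approach": "GOI",
                "variant_id": row["variant_id"],
                "name": row["name"],
                "chrom": row["chrom"],
                "start": int(row["start"]),
                "end": int(row["end"]),
                "event": row["event"],
                "a": row["a"],
                "b": row["b"],
                "c": row["c"],
                "d": row["d"],
                "p": row["p"],
                "freq_cutoff": np.nan,
                "p_cutoff": np.nan,
                "n_probes": np.nan,
                "min_p": np.nan,
            }
        )

    shortlist = pd.DataFrame(shortlist_rows, columns=_SHORTLIST_COLUMNS)
    shortlist.attrs["discovery_sample_ids"] = sorted(p.sample_id for p in profiles)
    return DiscoveryReport(
        params=params,
        ploidy_classes=classes,
        freq_cutoffs=freq_cutoffs,
        global_records=global_records,
        goi_table=goi_table,
        shortlist=shortlist,
    )


def run_validation(
    shortlist: pd.DataFrame,
    profiles: list[ASCNProfile],
    genotypes: GenotypeTable,
    manifest: ProbeManifest,
    variants: list[RiskVariantSpec],
    params: AnalysisParams | None = None,
) -> pd.DataFrame:
    """Re-test a discovery shortlist on an independent validation cohort.

    The two cohorts must be disjoint sample sets (enforced by id). The
    output pairs each row's discovery and validation counts/p-values with
    an untestable flag for regions of insufficient probe coverage.
    """
    params = params or AnalysisParams()
    if shortlist.empty:
        return pd.DataFrame()
    val_ids = {p.sample_id for p in profiles}
    overlap = val_ids & set(shortlist.attrs.get("discovery_sample_ids", ()))
    if overlap:
        raise ValueError(
            f"validation cohort shares sample ids with discovery: {sorted(overlap)[:3]}"
        )
    matrices, _ = prepare_matrices(profiles, manifest, params)
    splits = _make_splits(genotypes, variants)
    result = validate_shortlist(shortlist, matrices, splits, manifest, params)
    merged = shortlist.reset_index(drop=True).join(
        result[["n_probes_validation", "untestable", "a", "b", "c", "d", "p", "validated"]]
        .reset_index(drop=True)
        .add_suffix("_validation")
    )
    return merged.rename(columns={"untestable_validation": "untestable",
                                  "validated_validation": "validated"})
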