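"""Genotype splits, the one-sided Fisher primitive and the global probe scan.

The cohort is split per risk variant into samples homozygous for the major
allele versus heterozygotes plus rare homozygotes; the risk group is
whichever of the two carries the risk allele. At every probe inside a
recurrent region (risk-group event frequency above the frequency cutoff) a
one-sided Fisher's exact test asks whether the risk group shows the event
more often. Genome-wide significance uses a label-permutation cutoff: group
labels are reshuffled (group sizes fixed), the whole scan is re-run and the
minimum p per permutation is stored; the cutoff is placed so that 95% of
the stored minima lie above it, i.e. only ~5% of null relabelings produce
any probe below the cutoff (familywise control over the genome).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .model import (
    AnalysisParams,
    DegenerateSplitError,
    EventMatrix,
    GenotypeTable,
    Genotype,
    GroupSplit,
    ProbeManifest,
    RiskVariantSpec,
)

__all__ = [
    "split_groups",
    "fisher_one_sided",
    "probe_scan",
    "p_cutoff_by_permutation",
    "significant_regions",
]


def split_groups(genotypes: GenotypeTable, spec: RiskVariantSpec) -> GroupSplit:
    """Split samples into risk and other genotype groups for one variant.

    Uses the variant's own genotypes when assayed, else the surrogate
    marker's. Samples with missing genotype join neither group; an empty
    group raises :class:`DegenerateSplitError`.
    """
    if genotypes.has_variant(spec.variant_id):
        col = genotypes.column(spec.variant_id)
    elif spec.surrogate_id is not None and genotypes.has_variant(spec.surrogate_id):
        col = genotypes.column(spec.surrogate_id)
    else:
        raise KeyError(
            f"neither {spec.variant_id!r} nor its surrogate is genotyped"
        )
    major = col.index[col == Genotype.MAJOR_HOM.value]
    carrier = col.index[col.isin([Genotype.HET.value, Genotype.RARE_HOM.value])]
    if spec.risk_is_major:
        risk, other = major, carrier
    else:
        risk, other = carrier, major
    if len(risk) == 0 or len(other) == 0:
        raise DegenerateSplitError(
            f"degenerate split for {spec.variant_id}: "
            f"{len(risk)} risk vs {len(other)} other samples"
        )
    return GroupSplit(
        variant_id=spec.variant_id,
        risk_group=tuple(risk),
        other_group=tuple(other),
        risk_is_major=spec.risk_is_major,
    )


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """Upper-tail Fisher's exact p for a 2x2 table (risk group rows first).

    P(X >= a) with X ~ Hypergeometric(N = a+b+c+d, K = a+c successes,
    n = a+b draws): the probability that the risk group shows at least the
    observed number of events under fixed margins.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    n_total = a + b + c + d
    if n_total == 0:
        return 1.0
    return float(hypergeom.sf(a - 1, n_total, a + c, a + b))


def _fisher_upper_tail_vec(a, b, c, d) -> np.ndarray:
    a = np.asarray(a, dtype=np.int64)
    n_total = a + b + c + d
    with np.errstate(invalid="ignore"):
        p = hypergeom.sf(a - 1, n_total, a + c, a + b)
    return np.where(n_total == 0, 1.0, p)


def _group_counts(data: np.ndarray, rows: np.ndarray):
    sub = data[rows]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        pos = np.nansum(sub, axis=0)
    n = np.sum(~np.isnan(sub), axis=0)
    return pos.astype(np.int64), n.astype(np.int64)


def _scan_pvalues(
    data: np.ndarray,
    risk_rows: np.ndarray,
    other_rows: np.ndarray,
    cutoff: float,
    fixed_mask: np.ndarray | None = None,
):
    """Per-probe one-sided p on masked probes; returns (a, b, c, d, mask, p).

    The mask is the risk group's event frequency strictly above ``cutoff``
    (per-probe denominators exclude missing samples) unless ``fixed_mask``
    is supplied.
    """
    a, n_risk = _group_counts(data, risk_rows)
    c, n_other = _group_counts(data, other_rows)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_risk = np.where(n_risk > 0, a / np.maximum(n_risk, 1), np.nan)
    if fixed_mask is None:
        mask = (n_risk > 0) & (freq_risk > cutoff)
    else:
        mask = fixed_mask & (n_risk > 0)
    b = n_risk - a
    d = n_other - c
    p = np.full(data.shape[1], np.nan)
    if mask.any():
        p[mask] = _fisher_upper_tail_vec(a[mask], b[mask], c[mask], d[mask])
    return a, b, c, d, mask, p


def probe_scan(
    matrix: EventMatrix,
    split: GroupSplit,
    cutoff: float,
    manifest: ProbeManifest,
    params: AnalysisParams | None = None,
) -> pd.DataFrame:
    """One-sided Fisher p per probe inside recurrent regions of the risk group.

    Returns a frame in manifest order with the per-probe 2x2 counts
    (samples missing at a probe are dropped from that probe's table), the
    recurrence mask and the p-value (NaN off-mask).
    """
    data = matrix.values
    index = pd.Index(matrix.sample_ids)
    risk_rows = index.get_indexer(list(split.risk_group))
    other_rows = index.get_indexer(list(split.other_group))
    if (risk_rows < 0).any() or (other_rows < 0).any():
        raise ValueError("split names samples absent from the event matrix")
    a, b, c, d, mask, p = _scan_pvalues(data, risk_rows, other_rows, cutoff)
    if not mask.any():
        warnings.warn(
            f"no probe exceeds the frequency cutoff for {split.variant_id} "
            f"/ {matrix.event.name}"
        )
    return pd.DataFrame(
        {
            "probe_id": matrix.probe_ids,
            "chrom": manifest.chrom,
            "pos": manifest.pos,
            "a": a,
            "b": b,
            "c": c,
            "d": d,
            "masked": mask,
            "p": p,
        }
    )


def p_cutoff_by_permutation(
    matrix: EventMatrix,
    split: GroupSplit,
    cutoff: float,
    params: AnalysisParams | None = None,
    rng: np.random.Generator | int | None = None,
    fixed_mask: np.ndarray | None = None,
) -> float:
    """Genome-wide p-value cutoff from random group-label reassignment.

    For each of ``params.n_perm_p`` permutations the samples are reassigned
    to the two groups at the observed sizes, the recurrence mask and the
    per-probe p-values are recomputed exactly as in :func:`probe_scan`, and
    the minimum p is stored (1.0 when the permuted mask is empty). The
    cutoff is set so that ``params.p_cutoff_percentile`` percent of the
    stored minima lie above it — genome-wide familywise control: only ~5%
    of label-permuted cohorts produce any probe below the cutoff. Pass
    ``fixed_mask`` to keep the observed mask instead of recomputing it per
    permutation.
    """
    params = params or AnalysisParams()
    rng = np.random.default_rng(rng)
    data = matrix.values
    index = pd.Index(matrix.sample_ids)
    pool = np.concatenate(
        [
            index.get_indexer(list(split.risk_group)),
            index.get_indexer(list(split.other_group)),
        ]
    )
    if (pool < 0).any():
        raise ValueError("split names samples absent from the event matrix")
    n_risk = split.n_risk
    minima = np.empty(params.n_perm_p)
    for i in range(params.n_perm_p):
        perm = rng.permutation(pool)
        _, _, _, _, mask, p = _scan_pvalues(
            data, perm[:n_risk], perm[n_risk:], cutoff, fixed_mask=fixed_mask
        )
        valid = p[~np.isnan(p)]
        minima[i] = valid.min() if valid.size else 1.0
    return float(np.quantile(minima, 1.0 - params.p_cutoff_percentile / 100.0))


def significant_regions(
    scan: pd.DataFrame, p_cutoff: float, manifest: ProbeManifest
) -> pd.DataFrame:
    """Maximal runs of consecutive masked probes with p below the cutoff.

    Runs never cross a chromosome boundary or a probe that is unmasked or
    non-significant. Returns chrom, start/end positions (1-based, probe
    coordinates), probe count and the run's minimum p.
    """
    p = scan["p"].to_numpy(dtype=float)
    hit = scan["masked"].to_numpy(dtype=bool) & (p < p_cutoff)
    hit &= ~np.isnan(p)
    chroms = scan["chrom"].to_numpy()
    pos = scan["pos"].to_numpy()
    records = []
    i, n = 0, len(scan)
    while i < n:
        if not hit[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and hit[j + 1] and chroms[j + 1] == chroms[i]:
            j += 1
        records.append(
            {
                "chrom": chroms[i],
                "start": int(pos[i]),
                "end": int(pos[j]),
                "n_probes": j - i + 1,
                "min_p": float(np.nanmin(p[i : j + 1])),
            }
        )
        i = j + 1
    return pd.DataFrame(
        records, columns=["chrom", "start", "end", "n_probes", "min_p"]
    )
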