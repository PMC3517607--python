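"""Ploidy classification, copy-number rescaling and event calling.

Tumors that have undergone whole-genome duplication (endoreduplication) sit
near ploidy 4 and would otherwise be called "gained" everywhere. To make copy
numbers comparable across samples, samples with ploidy above a cutoff
(default 2.8) are classed tetraploid-like and their allele-specific copy
numbers are divided by two before event classification. Halved values are
kept as exact half-integers and the event predicates are evaluated literally
on them (e.g. (3,1)/2 = (1.5, 0.5) is a copy-number-neutral event because
nA != 1, nB != 1 and nTot = 2); an optional rounding mode is available.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import AnalysisParams, ASCNProfile, EventMatrix, EventType, PloidyClass, ProbeManifest

__all__ = [
    "classify_ploidy",
    "rescale_profile",
    "classify_probe",
    "event_flags",
    "build_event_matrices",
    "EVENT_ORDER",
]

#: Canonical event order used for matrix dictionaries and TSV output.
EVENT_ORDER: tuple[EventType, ...] = (
    EventType.NORMAL,
    EventType.LOSS,
    EventType.ICN,
    EventType.LOH,
    EventType.CNNE,
    EventType.HD,
    EventType.AMP,
    EventType.LOH_ICN,
)


def classify_ploidy(sample_ploidy: float, cutoff: float = 2.8) -> PloidyClass:
    """Class a sample diploid-like or tetraploid-like from its mean ploidy.

    Tetraploid-like iff ploidy > cutoff; the boundary value itself is
    diploid-like.
    """
    if not sample_ploidy > 0:
        raise ValueError(f"sample ploidy must be positive, got {sample_ploidy}")
    if sample_ploidy > cutoff:
        return PloidyClass.TETRAPLOID_LIKE
    return PloidyClass.DIPLOID_LIKE


def rescale_profile(
    profile: ASCNProfile,
    cls: PloidyClass | None = None,
    cutoff: float = 2.8,
    rounding: str = "exact",
) -> ASCNProfile:
    """Halve tetraploid-like copy numbers; identity for diploid-like samples.

    Parameters
    ----------
    cls
        Ploidy class; derived from ``profile.ploidy`` when omitted.
    rounding
        ``"exact"`` keeps half-integers exactly (default); ``"nearest"``
        rounds halved values to the nearest integer (ties to even).
    """
    if rounding not in ("exact", "nearest"):
        raise ValueError(f"unknown rounding mode: {rounding!r}")
    if cls is None:
        cls = classify_ploidy(profile.ploidy, cutoff)
    if cls is PloidyClass.DIPLOID_LIKE:
        return profile.copy_with(rescaled=True)
    n_a = profile.n_a / 2.0
    n_b = profile.n_b / 2.0
    if rounding == "nearest":
        n_a = np.rint(n_a)
        n_b = np.rint(n_b)
    return profile.copy_with(n_a=n_a, n_b=n_b, rescaled=True)


def event_flags(
    n_a: np.ndarray, n_b: np.ndarray
) -> Mapping[EventType, np.ndarray]:
    """Vectorized event predicates on (possibly half-integer) copy numbers.

    Returns one float array per event type: 1.0 where the predicate holds,
    0.0 where it does not, NaN where the input is missing. The arithmetic is
    exact because all values are multiples of 0.5, which is representable in
    binary floating point.
    """
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    n_tot = n_a + n_b
    loh = (n_a == 0) | (n_b == 0)
    flags = {
        EventType.NORMAL: (n_a == 1) & (n_b == 1),
        EventType.LOSS: n_tot < 2,
        EventType.ICN: n_tot > 2,
        EventType.LOH: loh,
        EventType.CNNE: (n_a != 1) & (n_b != 1) & (n_tot == 2),
        EventType.HD: n_tot == 0,
        EventType.AMP: n_tot >= 8,
        EventType.LOH_ICN: loh & (n_tot > 2),
    }
    missing = np.isnan(n_tot)
    out = {}
    for ev, flag in flags.items():
        arr = flag.astype(float)
        arr[missing] = np.nan
        out[ev] = arr
    return out


def classify_probe(n_a: float, n_b: float) -> frozenset[EventType] | None:
    """Event types whose predicate holds at one probe; None if input missing.

    Inputs must be non-negative multiples of 0.5 (post-rescaling scale).
    """
    if np.isnan(n_a) or np.isnan(n_b):
        return None
    for v, name in ((n_a, "nA"), (n_b, "nB")):
        if v < 0 or (v * 2) % 1 != 0:
            raise ValueError(f"{name} must be a non-negative multiple of 0.5, got {v}")
    flags = event_flags(np.array([n_a]), np.array([n_b]))
    return frozenset(ev for ev, arr in flags.items() if arr[0] == 1.0)


def build_event_matrices(
    profiles: Sequence[ASCNProfile],
    manifest: ProbeManifest,
    params: AnalysisParams | None = None,
) -> dict[EventType, EventMatrix]:
    """One samples x probes call matrix per event type, in manifest order.

    Profiles must already be rescaled; missing (nA, nB) propagates to NaN in
    all eight matrices.
    """
    if not profiles:
        raise ValueError("no profiles given")
    sample_ids = [p.sample_id for p in profiles]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids among profiles")
    for p in profiles:
        if not p.rescaled:
            raise ValueError(f"profile {p.sample_id!r} has not been rescaled")
        if p.n_probes != manifest.n_probes:
            raise ValueError(
                f"profile {p.sample_id!r} has {p.n_probes} probes, "
                f"manifest has {manifest.n_probes}"
            )
    n_a = np.vstack([p.n_a for p in profiles])
    n_b = np.vstack([p.n_b for p in profiles])
    flags = event_flags(n_a, n_b)
    cols = manifest.probe_ids
    return {
        ev: EventMatrix(ev, pd.DataFrame(flags[ev], index=sample_ids, columns=cols))
        for ev in EVENT_ORDER
    }
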