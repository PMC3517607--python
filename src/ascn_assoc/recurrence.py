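"""Event-frequency tracks and the permutation-derived recurrence cutoff.

A somatic event is "significantly recurring" at a probe when its cohort
frequency exceeds a null cutoff obtained by permuting genomic positions:
each sample's probe-level event calls are shuffled independently across the
autosomal probes, destroying the shared segment structure while conserving
each sample's event load. The cutoff is the (1 - FPR) empirical quantile of
the resulting per-probe null frequencies, averaged over repetitions
(defaults: FPR 0.5%, 100 repetitions). X-chromosome probes are excluded from
the permutation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .model import AnalysisParams, EventMatrix, ProbeManifest

__all__ = ["event_frequency", "frequency_cutoff", "recurrent_mask"]


def event_frequency(matrix: EventMatrix) -> pd.Series:
    """Per-probe event frequency: positives / non-missing samples.

    A probe with no non-missing call is NaN.
    """
    vals = matrix.values
    if vals.shape[0] < 1 or vals.size == 0:
        raise ValueError("event matrix must contain at least one sample and probe")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        freq = np.nanmean(vals, axis=0)
    return pd.Series(freq, index=matrix.probe_ids, name=matrix.event.name)


def _permute_sample_calls(
    data: np.ndarray, rng: np.random.Generator, method: str = "shuffle"
) -> np.ndarray:
    """One null draw: permute every sample's calls across positions.

    ``shuffle`` reorders each row uniformly; ``circular`` rolls each row by a
    random offset, preserving run lengths. Either way each sample's event and
    missing counts are conserved exactly.
    """
    n_samples, n_probes = data.shape
    perm = np.empty_like(data)
    if method == "shuffle":
        for i in range(n_samples):
            perm[i] = data[i, rng.permutation(n_probes)]
    else:
        for i in range(n_samples):
            perm[i] = np.roll(data[i], int(rng.integers(n_probes)))
    return perm


def frequency_cutoff(
    matrix: EventMatrix,
    manifest: ProbeManifest,
    params: AnalysisParams | None = None,
    rng: np.random.Generator | int | None = None,
    method: str = "shuffle",
) -> float:
    """Permutation-derived event-frequency cutoff for recurrent regions.

    For each of ``params.n_perm_freq`` repetitions, every sample's autosomal
    event calls are permuted across positions (``method="shuffle"``, the
    default) or circularly shifted by a random offset (``method="circular"``,
    preserving segment lengths under the null); per-probe null frequencies
    are computed and their empirical ``1 - params.freq_fpr`` quantile (linear
    interpolation) is the repetition's intermediate cutoff. The returned
    cutoff is the mean of the intermediates.
    """
    params = params or AnalysisParams()
    if method not in ("shuffle", "circular"):
        raise ValueError(f"unknown permutation method: {method!r}")
    rng = np.random.default_rng(rng)
    auto = manifest.autosomal_mask
    if int(auto.sum()) < 2:
        raise ValueError("need at least 2 autosomal probes")
    data = matrix.values[:, auto]
    n_samples, n_probes = data.shape
    total_events = np.nansum(data)
    if total_events == 0:
        warnings.warn("event matrix has no events; frequency cutoff is 0")
        return 0.0
    q = 1.0 - params.freq_fpr
    cuts = np.empty(params.n_perm_freq)
    for rep in range(params.n_perm_freq):
        perm = _permute_sample_calls(data, rng, method)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            freq = np.nanmean(perm, axis=0)
        freq = freq[~np.isnan(freq)]
        cuts[rep] = np.quantile(freq, q)
    return float(cuts.mean())


def recurrent_mask(freq: pd.Series | np.ndarray, cutoff: float) -> np.ndarray:
    """Probes whose frequency lies strictly above the cutoff.

    Missing frequencies are never recurrent.
    """
    vals = np.asarray(freq, dtype=float)
    mask = vals > cutoff
    mask[np.isnan(vals)] = False
    return mask
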