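"""Readers and writers for the pipeline's tabular formats.

All tables are plain TSV with a leading ``#`` comment carrying the package
version (and seed, when one applies); regions additionally support BED.
Internal coordinates are 1-based inclusive; BED (0-based half-open) is
converted at the boundary, and the conversion is an involution.
"""

from __future__ import annotations

import importlib.resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import (
    AnalysisParams,
    ASCNProfile,
    GeneRegion,
    GenotypeTable,
    ProbeManifest,
    RiskVariantSpec,
    normalize_chrom,
)

__all__ = [
    "read_manifest",
    "write_manifest",
    "read_profiles",
    "write_profiles",
    "read_genotypes",
    "write_genotypes",
    "read_regions",
    "write_regions",
    "read_params",
    "write_params",
    "select_surrogate",
    "write_bedgraph",
    "write_event_matrix",
    "read_event_matrix",
    "read_variants",
    "load_gene_regions",
    "load_risk_variants",
    "load_reported_associations",
    "load_fixture_config_path",
]

_PROFILE_COLS = ["sample_id", "probe_id", "nA", "nB"]


def _header(seed: int | None = None) -> str:
    line = f"# ascn-assoc v{__version__}"
    if seed is not None:
        line += f" seed={seed}"
    return line + "\n"


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})


def read_manifest(path) -> ProbeManifest:
    df = _read_tsv(path)
    return ProbeManifest(df)


def write_manifest(manifest: ProbeManifest, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed))
        manifest.table.to_csv(fh, sep="\t", index=False)


def read_profiles(path, manifest: ProbeManifest, ploidy_path=None) -> list[ASCNProfile]:
    """Read per-probe (nA, nB) rows plus per-sample ploidy into profiles.

    The main table needs columns ``sample_id, probe_id, nA, nB`` and either a
    ``ploidy`` column (constant per sample, ``aberrant_fraction`` optional) or
    a sidecar table at ``ploidy_path`` with ``sample_id, ploidy``. Probes not
    named for a sample are missing; probe ids absent from the manifest are
    rejected.
    """
    df = _read_tsv(path)
    missing_cols = [c for c in _PROFILE_COLS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"profile table missing columns: {missing_cols}")
    for col in ("nA", "nB"):
        vals = df[col].to_numpy(dtype=float)
        if (vals[~np.isnan(vals)] < 0).any():
            raise ValueError(f"negative copy number in column {col}")
    unknown = set(df["probe_id"].astype(str)) - set(manifest.probe_ids)
    if unknown:
        some = sorted(unknown)[:3]
        raise ValueError(f"unknown probe ids (not in manifest): {some}")

    if ploidy_path is not None:
        sidecar = _read_tsv(ploidy_path).set_index("sample_id")
    elif "ploidy" in df.columns:
        sidecar = (
            df.groupby("sample_id")[
                ["ploidy"]
                + (["aberrant_fraction"] if "aberrant_fraction" in df.columns else [])
            ]
            .first()
        )
    else:
        raise ValueError("no ploidy column and no ploidy sidecar given")

    profiles = []
    n = manifest.n_probes
    for sample_id, grp in df.groupby("sample_id", sort=True):
        idx = manifest.indexer(grp["probe_id"].astype(str).tolist())
        n_a = np.full(n, np.nan)
        n_b = np.full(n, np.nan)
        n_a[idx] = grp["nA"].to_numpy(dtype=float)
        n_b[idx] = grp["nB"].to_numpy(dtype=float)
        # a probe given with one allele missing is treated as wholly missing
        half = np.isnan(n_a) != np.isnan(n_b)
        n_a[half] = np.nan
        n_b[half] = np.nan
        if sample_id not in sidecar.index:
            raise ValueError(f"no ploidy recorded for sample {sample_id!r}")
        row = sidecar.loc[sample_id]
        af = (
            float(row["aberrant_fraction"])
            if "aberrant_fraction" in sidecar.columns
            and not pd.isna(row.get("aberrant_fraction"))
            else None
        )
        profiles.append(
            ASCNProfile(
                sample_id=str(sample_id),
                n_a=n_a,
                n_b=n_b,
                ploidy=float(row["ploidy"]),
                aberrant_fraction=af,
            )
        )
    return profiles


def write_profiles(
    profiles: Sequence[ASCNProfile],
    manifest: ProbeManifest,
    path,
    seed: int | None = None,
) -> None:
    probe_ids = manifest.probe_ids
    frames = []
    for p in sorted(profiles, key=lambda q: q.sample_id):
        frame = pd.DataFrame(
            {
                "sample_id": p.sample_id,
                "probe_id": probe_ids,
                "nA": p.n_a,
                "nB": p.n_b,
                "ploidy": p.ploidy,
                "aberrant_fraction": np.nan
                if p.aberrant_fraction is None
                else p.aberrant_fraction,
            }
        )
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(_header(seed))
        out.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format="%g")


def read_genotypes(path) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="sample_id")
    return GenotypeTable(df)


def write_genotypes(genotypes: GenotypeTable, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed))
        genotypes.table.to_csv(fh, sep="\t", index_label="sample_id", na_rep="NA")


def read_regions(path, coords: str | None = None) -> list[GeneRegion]:
    """Read named regions from TSV (1-based inclusive) or BED (0-based).

    ``coords`` is ``"one-based"`` or ``"bed"``; when omitted it is taken from
    a ``# coords=...`` header comment if present, else inferred from a
    ``.bed`` suffix (default one-based TSV with header
    ``name, chrom, start, end``).
    """
    declared = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "coords=" in first:
        declared = first.split("coords=")[1].split()[0].strip()
    if coords is None:
        coords = declared or ("bed" if str(path).endswith(".bed") else "one-based")
    if coords not in ("bed", "one-based"):
        raise ValueError(f"unknown coordinate convention: {coords!r}")

    if coords == "bed":
        df = pd.read_csv(
            path,
            sep=r"\s+",
            comment="#",
            header=None,
            names=["chrom", "start", "end", "name"],
            dtype={"chrom": str},
        )
        if df.empty:
            return []
        return [
            GeneRegion(
                name=str(r["name"]),
                chrom=r["chrom"],
                start=int(r["start"]) + 1,
                end=int(r["end"]),
            )
            for _, r in df.iterrows()
        ]
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    if df.empty:
        return []
    name_col = "name" if "name" in df.columns else "gene"
    return [
        GeneRegion(
            name=str(r[name_col]),
            chrom=r["chrom"],
            start=int(r["start"]),
            end=int(r["end"]),
        )
        for _, r in df.iterrows()
    ]


def write_regions(
    regions: Iterable[GeneRegion], path, coords: str = "one-based", seed: int | None = None
) -> None:
    regions = list(regions)
    if coords == "bed":
        with open(path, "w") as fh:
            for r in regions:
                fh.write(f"chr{r.chrom}\t{r.start - 1}\t{r.end}\t{r.name}\n")
        return
    if coords != "one-based":
        raise ValueError(f"unknown coordinate convention: {coords!r}")
    df = pd.DataFrame(
        {
            "name": [r.name for r in regions],
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
        }
    )
    with open(path, "w") as fh:
        fh.write(_header(seed).rstrip("\n") + " coords=one-based\n")
        df.to_csv(fh, sep="\t", index=False)


def read_params(path) -> AnalysisParams:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return AnalysisParams.from_dict(data)


def write_params(params: AnalysisParams, path) -> None:
    with open(path, "w") as fh:
        fh.write(_header())
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def select_surrogate(
    target: RiskVariantSpec,
    candidates: Sequence[str],
    ld: pd.DataFrame,
) -> str:
    """Pick the surrogate marker with the largest r2 to the target variant.

    ``ld`` needs columns ``variant_id, r2`` and optionally ``pos``; ties on
    r2 break by smallest genomic distance to the target, then lexicographic
    id, so the choice is reproducible.
    """
    if len(candidates) == 0:
        raise ValueError(f"no surrogate candidates for {target.variant_id}")
    tbl = ld.loc[ld["variant_id"].isin(list(candidates))].copy()
    if tbl.empty:
        raise ValueError(
            f"LD table has no r2 for any candidate of {target.variant_id}"
        )
    if "pos" in tbl.columns:
        dist = (tbl["pos"].astype(float) - float(target.pos)).abs()
    else:
        dist = pd.Series(np.inf, index=tbl.index)
    tbl = tbl.assign(_dist=dist).sort_values(
        by=["r2", "_dist", "variant_id"], ascending=[False, True, True], kind="stable"
    )
    return str(tbl.iloc[0]["variant_id"])


def write_bedgraph(manifest: ProbeManifest, values, path, name: str = "track") -> None:
    """Export a per-probe track (frequencies, -log10 p, ...) as bedGraph."""
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        for chrom, pos, val in zip(manifest.chrom, manifest.pos, values):
            if np.isnan(val):
                continue
            fh.write(f"chr{chrom}\t{pos - 1}\t{pos}\t{val:g}\n")


def write_event_matrix(matrix, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed).rstrip("\n") + f" event={matrix.event.name}\n")
        matrix.data.to_csv(
            fh, sep="\t", index_label="sample_id", na_rep="NA", float_format="%g"
        )


def read_event_matrix(path, event) -> "EventMatrix":
    from .model import EventMatrix, EventType

    if not isinstance(event, EventType):
        event = EventType.from_label(event)
    df = pd.read_csv(path, sep="\t", comment="#", index_col="sample_id")
    return EventMatrix(event, df)


# ---------------------------------------------------------------------------
# Packaged reference tables
# ---------------------------------------------------------------------------


def _data_path(name: str):
    return importlib.resources.files("ascn_assoc.data").joinpath(name)


def load_gene_regions() -> list[GeneRegion]:
    """The 27 glioma genes of interest as named 1-based intervals."""
    with importlib.resources.as_file(_data_path("genes_of_interest.tsv")) as p:
        return read_regions(p, coords="one-based")


def load_risk_variants() -> list[RiskVariantSpec]:
    """The 13 published glioma risk variants with their discovery surrogates."""
    return read_variants(_data_path("risk_variants.tsv"))


def read_variants(path) -> list[RiskVariantSpec]:
    """Read risk-variant specs from TSV (see ``risk_variants.tsv`` columns)."""
    df = _read_tsv(path)
    out = []
    for _, r in df.iterrows():
        out.append(
            RiskVariantSpec(
                variant_id=r["variant_id"],
                chrom=normalize_chrom(r["chrom"]),
                pos=int(r["pos"]),
                gene=r["gene"],
                major_allele=r["major_allele"],
                risk_allele=r["risk_allele"],
                surrogate_id=None if pd.isna(r["surrogate_id"]) else r["surrogate_id"],
                surrogate_pos=None
                if pd.isna(r["surrogate_pos"])
                else int(r["surrogate_pos"]),
                surrogate_r2=None
                if pd.isna(r["surrogate_r2"])
                else float(r["surrogate_r2"]),
            )
        )
    return out


def load_reported_associations() -> pd.DataFrame:
    """Published 2x2 counts for the validated germline-somatic associations.

    One row per (association, cohort) with risk/other group sizes and event
    counts; inputs for recomputing the one-sided Fisher p-values.
    """
    return _read_tsv(_data_path("reported_associations.tsv"))


def load_fixture_config_path():
    """Path to the packaged small-cohort simulation config."""
    return _data_path("fixture_config.yaml")
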