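"""Core domain types for allele-specific copy-number (ASCN) association analysis.

The pipeline links germline risk-variant genotypes to somatic allele-specific
copy-number events in tumor cohorts. Its substrate is the output contract of an
ASCAT-style caller: for every sample, per-probe allele-specific copy numbers
(nA, nB) plus a sample-level ploidy estimate. Everything downstream — event
classification, recurrence cutoffs, Fisher association tests — operates on the
types defined here.

Coordinates are 1-based inclusive throughout; BED import/export converts
explicitly at the boundary (:mod:`ascn_assoc.io`).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EventType",
    "PloidyClass",
    "Genotype",
    "ProbeManifest",
    "ASCNProfile",
    "GenotypeTable",
    "RiskVariantSpec",
    "GeneRegion",
    "AnalysisParams",
    "AssociationResult",
    "GroupSplit",
    "EventMatrix",
    "DegenerateSplitError",
    "NoProbeCoverageError",
    "normalize_chrom",
    "is_autosome",
]


class DegenerateSplitError(ValueError):
    """Raised when a genotype split leaves one group empty."""


class NoProbeCoverageError(ValueError):
    """Raised when a region contains no manifest probes."""


def normalize_chrom(label: str) -> str:
    """Normalize a chromosome label: strip a ``chr`` prefix, uppercase X/Y/MT."""
    lab = str(label).strip()
    if lab.lower().startswith("chr"):
        lab = lab[3:]
    if lab.lower() in ("x", "y", "mt", "m"):
        return lab.upper()
    return lab


def is_autosome(label: str) -> bool:
    """True for any chromosome that is not X, Y or mitochondrial.

    The permutation procedure behind the event-frequency cutoff runs on
    autosomes only; X-chromosome probes are classified but excluded there.
    """
    return normalize_chrom(label) not in ("X", "Y", "MT", "M")


def _chrom_sort_key(label: str) -> tuple[int, int, str]:
    lab = normalize_chrom(label)
    if lab.isdigit():
        return (0, int(lab), "")
    order = {"X": 0, "Y": 1, "MT": 2, "M": 2}
    return (1, order.get(lab, 9), lab)


class EventType(enum.Enum):
    """The eight somatic genomic event types, defined on rescaled (nA, nB).

    With ``nTot = nA + nB``:

    ==========  =====================================
    NORMAL      nA = 1 and nB = 1
    LOSS        nTot < 2
    ICN         nTot > 2 (increased copy number)
    LOH         nA = 0 or nB = 0
    CNNE        nA != 1 and nB != 1 and nTot = 2
    HD          nTot = 0 (homozygous deletion)
    AMP         nTot >= 8 (amplification)
    LOH_ICN     (nA = 0 or nB = 0) and nTot > 2
    ==========  =====================================

    A probe belongs to at least one type; NORMAL/LOSS/ICN/CNNE partition the
    non-missing probes, while LOH, HD, AMP and LOH_ICN overlay them.
    """

    NORMAL = "normal"
    LOSS = "loss"
    ICN = "increased_copy_number"
    LOH = "loh"
    CNNE = "cnne"
    HD = "homozygous_deletion"
    AMP = "amplification"
    LOH_ICN = "loh_icn"

    @classmethod
    def from_label(cls, label: str) -> "EventType":
        lab = str(label).strip().lower()
        for ev in cls:
            if lab in (ev.value, ev.name.lower()):
                return ev
        raise ValueError(f"unknown event type: {label!r}")


class PloidyClass(enum.Enum):
    DIPLOID_LIKE = "diploid_like"
    TETRAPLOID_LIKE = "tetraploid_like"


class Genotype(str, enum.Enum):
    """Germline genotype categories at a risk variant."""

    MAJOR_HOM = "major_hom"
    HET = "het"
    RARE_HOM = "rare_hom"


_GENOTYPE_LABELS = {g.value for g in Genotype}


class ProbeManifest:
    """Ordered array manifest: probe id, chromosome, 1-based position.

    Probes are sorted by (chromosome, position) on construction with the
    natural chromosome order (1..22, X, Y, MT). Positions must be strictly
    increasing within a chromosome and probe ids unique.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"probe_id", "chrom", "pos"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        df = table.loc[:, ["probe_id", "chrom", "pos"]].copy()
        df["probe_id"] = df["probe_id"].astype(str)
        df["chrom"] = df["chrom"].map(normalize_chrom)
        df["pos"] = df["pos"].astype(np.int64)
        if (df["pos"] < 1).any():
            raise ValueError("probe positions must be 1-based (>= 1)")
        if df["probe_id"].duplicated().any():
            dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValueError(f"duplicate probe id: {dup!r}")
        df = df.sort_values(
            by=["chrom", "pos"],
            key=lambda s: s.map(_chrom_sort_key) if s.name == "chrom" else s,
            kind="stable",
        ).reset_index(drop=True)
        for chrom, grp in df.groupby("chrom", sort=False):
            if (np.diff(grp["pos"].to_numpy()) <= 0).any():
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )
        self._df = df
        self._index = pd.Index(df["probe_id"])

    @classmethod
    def from_arrays(
        cls, probe_ids: Sequence[str], chroms: Sequence[str], pos: Sequence[int]
    ) -> "ProbeManifest":
        return cls(pd.DataFrame({"probe_id": probe_ids, "chrom": chroms, "pos": pos}))

    def __len__(self) -> int:
        return len(self._df)

    @property
    def n_probes(self) -> int:
        return len(self._df)

    @property
    def table(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def probe_ids(self) -> np.ndarray:
        return self._df["probe_id"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self._df["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self._df["pos"].to_numpy()

    @property
    def autosomal_mask(self) -> np.ndarray:
        return np.array([is_autosome(c) for c in self._df["chrom"]], dtype=bool)

    def contains(self, probe_ids: Iterable[str]) -> np.ndarray:
        return self._index.isin(list(probe_ids))

    def indexer(self, probe_ids: Sequence[str]) -> np.ndarray:
        """Positions of the given probe ids in manifest order; -1 if absent."""
        return self._index.get_indexer(probe_ids)

    def probes_in_region(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of probes with ``start <= pos <= end`` on ``chrom`` (1-based)."""
        chrom = normalize_chrom(chrom)
        on_chrom = np.flatnonzero(self._df["chrom"].to_numpy() == chrom)
        if on_chrom.size == 0:
            return on_chrom
        pos = self._df["pos"].to_numpy()[on_chrom]
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="right")
        return on_chrom[lo:hi]


def _check_copy_values(values: np.ndarray, rescaled: bool, name: str) -> None:
    finite = values[~np.isnan(values)]
    if (finite < 0).any():
        raise ValueError(f"negative copy number in {name}")
    step = 0.5 if rescaled else 1.0
    if not np.allclose(finite % step, 0.0, atol=1e-9):
        kind = "multiples of 0.5" if rescaled else "non-negative integers"
        raise ValueError(f"{name} must contain {kind}")


@dataclass
class ASCNProfile:
    """One sample's allele-specific copy-number profile, aligned to a manifest.

    ``n_a``/``n_b`` are float arrays with NaN for missing probes (missing is
    explicit and never encoded as 0, since 0 means a deleted allele). Before
    ploidy rescaling the values are non-negative integers; after rescaling of a
    tetraploid-like sample they are exact multiples of 0.5.
    """

    sample_id: str
    n_a: np.ndarray
    n_b: np.ndarray
    ploidy: float
    aberrant_fraction: float | None = None
    rescaled: bool = False

    def __post_init__(self) -> None:
        self.n_a = np.asarray(self.n_a, dtype=float)
        self.n_b = np.asarray(self.n_b, dtype=float)
        if self.n_a.shape != self.n_b.shape:
            raise ValueError("n_a and n_b must have identical shape")
        if not np.array_equal(np.isnan(self.n_a), np.isnan(self.n_b)):
            raise ValueError("missingness must be paired: nA is NaN iff nB is NaN")
        if not (self.ploidy > 0 and math.isfinite(self.ploidy)):
            raise ValueError(f"sample ploidy must be positive, got {self.ploidy}")
        if self.aberrant_fraction is not None and not (
            0.0 <= self.aberrant_fraction <= 1.0
        ):
            raise ValueError("aberrant_fraction must lie in [0, 1]")
        _check_copy_values(self.n_a, self.rescaled, "nA")
        _check_copy_values(self.n_b, self.rescaled, "nB")

    @property
    def n_tot(self) -> np.ndarray:
        return self.n_a + self.n_b

    @property
    def n_probes(self) -> int:
        return self.n_a.size

    def copy_with(self, **kwargs) -> "ASCNProfile":
        return replace(self, **kwargs)


class GenotypeTable:
    """Wide samples x variants table of genotype categories.

    Values are ``major_hom`` / ``het`` / ``rare_hom`` or NaN for missing.
    """

    def __init__(self, table: pd.DataFrame):
        df = table.copy()
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            raise ValueError("duplicate sample ids in genotype table")
        bad = set(df.stack().unique()) - _GENOTYPE_LABELS
        if bad:
            raise ValueError(f"unknown genotype labels: {sorted(bad)}")
        self._df = df

    @property
    def table(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def variant_ids(self) -> list[str]:
        return list(self._df.columns)

    def column(self, variant_id: str) -> pd.Series:
        if variant_id not in self._df.columns:
            raise KeyError(f"variant {variant_id!r} not genotyped")
        return self._df[variant_id]

    def has_variant(self, variant_id: str) -> bool:
        return variant_id in self._df.columns


@dataclass(frozen=True)
class RiskVariantSpec:
    """A germline risk variant: alleles, optional surrogate marker, position.

    ``risk_allele`` may equal the major allele (the risk group is then the
    major-homozygous group) or the rare allele (risk group = heterozygotes
    plus rare homozygotes). When the variant itself is not assayed on an
    array, ``surrogate_id`` names a genotyped marker in LD (``surrogate_r2``).
    """

    variant_id: str
    chrom: str
    pos: int
    gene: str
    major_allele: str
    risk_allele: str
    surrogate_id: str | None = None
    surrogate_pos: int | None = None
    surrogate_r2: float | None = None

    def __post_init__(self) -> None:
        if self.surrogate_r2 is not None and not (0.0 <= self.surrogate_r2 <= 1.0):
            raise ValueError("surrogate r2 must lie in [0, 1]")

    @property
    def risk_is_major(self) -> bool:
        return self.risk_allele == self.major_allele


@dataclass(frozen=True)
class GeneRegion:
    """A named genomic interval, 1-based inclusive on both ends."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start > self.end:
            raise ValueError(
                f"region {self.name}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValueError(f"region {self.name}: 1-based start must be >= 1")

    @property
    def label(self) -> str:
        return f"chr{self.chrom}:{self.start}-{self.end}"


@dataclass
class AnalysisParams:
    """Tunable thresholds of the association pipeline (study defaults).

    ploidy_cutoff
        Samples with ploidy above this are tetraploid-like and halved (2.8).
    n_perm_freq, freq_fpr
        Position-permutation repetitions and false-positive rate defining the
        event-frequency cutoff (100 reps, 0.5%).
    n_perm_p, p_cutoff_percentile
        Label permutations defining the genome-wide p cutoff (100 reps); the
        cutoff is placed so this percent of the stored per-permutation
        minimum p-values lie above it (95, i.e. genome-wide alpha of 5%).
    goi_fraction, goi_alpha
        Gene-level positivity rule (> 50% of probes) and nominal significance
        level (0.05) of the genes-of-interest approach.
    min_validation_probes
        Regions with fewer probes than this on the validation manifest are
        untestable (3, i.e. "<= 2 probes" is excluded).
    """

    ploidy_cutoff: float = 2.8
    n_perm_freq: int = 100
    freq_fpr: float = 0.005
    n_perm_p: int = 100
    p_cutoff_percentile: float = 95.0
    goi_fraction: float = 0.5
    goi_alpha: float = 0.05
    min_validation_probes: int = 3
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.ploidy_cutoff <= 0:
            raise ValueError("ploidy_cutoff must be positive")
        if self.n_perm_freq < 1 or self.n_perm_p < 1:
            raise ValueError("permutation counts must be >= 1")
        if not 0.0 < self.freq_fpr < 1.0:
            raise ValueError("freq_fpr must lie in (0, 1)")
        if not 0.0 <= self.p_cutoff_percentile <= 100.0:
            raise ValueError("p_cutoff_percentile must lie in [0, 100]")
        if not 0.0 <= self.goi_fraction < 1.0:
            raise ValueError("goi_fraction must lie in [0, 1)")
        if not 0.0 < self.goi_alpha <= 1.0:
            raise ValueError("goi_alpha must lie in (0, 1]")
        if self.min_validation_probes < 1:
            raise ValueError("min_validation_probes must be >= 1")

    def to_dict(self) -> dict:
        return {
            "ploidy_cutoff": self.ploidy_cutoff,
            "n_perm_freq": self.n_perm_freq,
            "freq_fpr": self.freq_fpr,
            "n_perm_p": self.n_perm_p,
            "p_cutoff_percentile": self.p_cutoff_percentile,
            "goi_fraction": self.goi_fraction,
            "goi_alpha": self.goi_alpha,
            "min_validation_probes": self.min_validation_probes,
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisParams":
        return cls(**d)


@dataclass(frozen=True)
class GroupSplit:
    """Two disjoint genotype groups for one risk variant.

    ``risk_group`` carries the risk allele: the major-homozygous samples when
    the risk allele is the major allele, otherwise heterozygotes plus rare
    homozygotes. Samples with a missing genotype belong to neither group.
    """

    variant_id: str
    risk_group: tuple[str, ...]
    other_group: tuple[str, ...]
    risk_is_major: bool

    def __post_init__(self) -> None:
        if set(self.risk_group) & set(self.other_group):
            raise ValueError("risk and other groups must be disjoint")

    @property
    def n_risk(self) -> int:
        return len(self.risk_group)

    @property
    def n_other(self) -> int:
        return len(self.other_group)


@dataclass
class AssociationResult:
    """One 2x2 association: (variant, region/gene, event) with a one-sided p.

    Counts: ``a`` risk-group samples with the event, ``b`` without, ``c``/``d``
    likewise for the other group.
    """

    variant_id: str
    target: str
    event: EventType
    a: int
    b: int
    c: int
    d: int
    p: float
    cohort: str = ""
    approach: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if not (math.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")

    def as_dict(self) -> dict:
        return {
            "variant_id": self.variant_id,
            "target": self.target,
            "event": self.event.name,
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "d": self.d,
            "p": self.p,
            "cohort": self.cohort,
            "approach": self.approach,
        }


@dataclass
class EventMatrix:
    """Samples x probes boolean calls for one event type.

    Stored as floats: 1.0 (event), 0.0 (no event), NaN (missing wherever the
    underlying (nA, nB) was missing).
    """

    event: EventType
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if not np.isin(finite, (0.0, 1.0)).all():
            raise ValueError("event matrix cells must be 0, 1 or NaN")
        self.data = pd.DataFrame(
            vals, index=self.data.index.astype(str), columns=self.data.columns
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)
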